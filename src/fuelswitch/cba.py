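"""Constraint-based flux estimation from measured boundary fluxes.

At each protocol time point the steady-state balance ``S . J = 0`` is solved
for all 87 reaction fluxes with the six exchange columns pinned to the
measured boundary values (O2 and CO2 gas exchange, carbohydrate and
fatty-acid uptake; lactate and water output are left free and non-negative
by default), maximizing mitochondrial ATP production — the flux through ATP
synthase — as the objective.  Ties among alternate optima are broken by
minimizing the total flux magnitude at fixed objective, which also strips
any sign-consistent internal cycle from the solution (thermodynamic
loop-law); an ll-FBA MILP with binary direction indicators is available for
networks whose direction-bounded null space still contains internal cycles.

Because the network stores no fuel (no glycogen or triglyceride pools), the
exchange fluxes must satisfy exact elemental closure (for example
``JO2 = JCO2 + 7 * J_FA``).  Measured or noisy inputs never do, so exchange
columns are pinned within a small tolerance band (relative, or +-2 sigma when
per-point variances are supplied) rather than as strict equalities; the band
is inactive for exactly consistent inputs.

Fluxes are whole-body rates in mol min^-1 (kg body mass)^-1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, sparse
from scipy.linalg import null_space

from .network import MetabolicNetwork, stoichiometric_matrix

__all__ = [
    "BoundaryFluxSeries",
    "FluxSolution",
    "InfeasibleBoundaryError",
    "solve_timepoint",
    "solve_series",
    "flux_envelope",
    "atpase_demand_curve",
    "find_internal_cycles",
]

#: default cap on any single flux, mol/min/kg (far above physiological scale)
BIG = 10.0

#: id of the objective reaction: mitochondrial ATP production
OBJECTIVE_REACTION = "ATPS"

#: map exchange reaction id -> boundary series field
EXCHANGE_FIELDS = {
    "EX_O2": "jo2",
    "EX_CO2": "jco2",
    "EX_GLC": "carb",
    "EX_FA": "fa",
}


class InfeasibleBoundaryError(RuntimeError):
    """The supplied boundary fluxes admit no steady-state flux distribution."""


@dataclass
class BoundaryFluxSeries:
    """Measured exchange-flux time courses (mol/min/kg body mass).

    ``jo2``/``carb``/``fa`` are uptakes, ``jco2`` is output; all non-negative.
    ``lactate`` optionally pins the lactate output column; otherwise lactate
    export is free and non-negative at solve time.  ``variance`` maps a field
    name to per-point variances used for the exchange tolerance band.
    """

    times: np.ndarray
    jo2: np.ndarray
    jco2: np.ndarray
    carb: np.ndarray
    fa: np.ndarray
    lactate: np.ndarray | None = None
    variance: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("jo2", "jco2", "carb", "fa"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} must match times in length")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, arr)
        if self.lactate is not None:
            self.lactate = np.asarray(self.lactate, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def rq(self) -> np.ndarray:
        """Respiratory quotient of the measured gas exchange."""
        return self.jco2 / self.jo2

    def row(self, i: int) -> dict[str, float]:
        out = {"time": self.times[i], "jo2": self.jo2[i], "jco2": self.jco2[i],
               "carb": self.carb[i], "fa": self.fa[i]}
        if self.lactate is not None:
            out["lactate"] = self.lactate[i]
        return out

    def to_frame(self):
        import pandas as pd

        data = {"time_min": self.times, "JO2": self.jo2, "JCO2": self.jco2,
                "carb": self.carb, "fa": self.fa}
        if self.lactate is not None:
            data["lactate"] = self.lactate
        return pd.DataFrame(data)


@dataclass
class FluxSolution:
    """Internal fluxes per time point with objective values and envelopes."""

    reaction_ids: list[str]
    times: np.ndarray
    J: np.ndarray  # (n_times, n_reactions)
    objective_value: np.ndarray  # (n_times,)
    status: list[str]
    envelope_min: np.ndarray | None = None
    envelope_max: np.ndarray | None = None

    def flux(self, rid: str) -> np.ndarray:
        return self.J[:, self.reaction_ids.index(rid)]

    @property
    def ok(self) -> np.ndarray:
        return np.array([s == "optimal" for s in self.status])

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.J, columns=self.reaction_ids)
        df.insert(0, "time_min", self.times)
        return df


def _exchange_bounds(
    net: MetabolicNetwork,
    boundary: dict[str, float],
    tolerance: float,
    variance: dict[str, float] | None,
    lactate_fixed: bool,
) -> dict[str, tuple[float, float]]:
    out: dict[str, tuple[float, float]] = {}
    for rid, fieldname in EXCHANGE_FIELDS.items():
        b = float(boundary[fieldname])
        if variance and fieldname in variance:
            half = 2.0 * float(np.sqrt(variance[fieldname]))
        else:
            half = tolerance * max(abs(b), 1e-12)
        out[rid] = (max(0.0, b - half), b + half)
    if lactate_fixed:
        if "lactate" not in boundary:
            raise ValueError("lactate_fixed=True requires a lactate boundary value")
        b = float(boundary["lactate"])
        half = tolerance * max(abs(b), 1e-12)
        out["EX_LAC"] = (max(0.0, b - half), b + half)
    else:
        out["EX_LAC"] = (0.0, BIG)
    out["EX_H2O"] = (0.0, BIG)
    return out


def _solve_lp(
    S: np.ndarray,
    cost: np.ndarray,
    bounds: list[tuple[float, float]],
    extra_eq: tuple[np.ndarray, float] | None = None,
):
    A_eq = sparse.csr_matrix(S)
    b_eq = np.zeros(S.shape[0])
    if extra_eq is not None:
        row, val = extra_eq
        A_eq = sparse.vstack([A_eq, sparse.csr_matrix(row)])
        b_eq = np.append(b_eq, val)
    return optimize.linprog(
        cost, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs",
        options={"primal_feasibility_tolerance": 1e-10,
                 "dual_feasibility_tolerance": 1e-9},
    )


def find_internal_cycles(net: MetabolicNetwork, atol: float = 1e-9) -> list[np.ndarray]:
    """Null-space basis vectors supported entirely on non-boundary reactions.

    These are the stoichiometric cycles the loop-law forbids from carrying
    net flux.  The canonical network has none; constructed toys may.
    """
    S = stoichiometric_matrix(net).astype(float)
    N = null_space(S)
    boundary_rows = [k for k, r in enumerate(net.reactions) if r.is_boundary]
    if N.size == 0:
        return []
    if boundary_rows:
        # rotate the basis so exchange components are concentrated in few vectors
        B = N[boundary_rows, :]
        _, _, vt = np.linalg.svd(B, full_matrices=True)
        N = N @ vt.T
    cycles = []
    for j in range(N.shape[1]):
        v = N[:, j]
        if np.max(np.abs(v)) < atol:
            continue
        if boundary_rows and np.max(np.abs(v[boundary_rows])) < atol * np.max(np.abs(v)):
            cycles.append(v / np.max(np.abs(v)))
    return cycles


def _has_active_cycle(net: MetabolicNetwork, J: np.ndarray, rel_tol: float = 1e-6) -> bool:
    """Post-hoc loop scan: is some internal cycle sign-consistent with J?"""
    scale = np.max(np.abs(J)) or 1.0
    for v in find_internal_cycles(net):
        sup = np.abs(v) > 1e-9
        if np.all(np.abs(J[sup]) > rel_tol * scale) and (
            np.all(np.sign(J[sup]) == np.sign(v[sup]))
            or np.all(np.sign(J[sup]) == -np.sign(v[sup]))
        ):
            return True
    return False


def _solve_loopless_milp(
    S: np.ndarray,
    net: MetabolicNetwork,
    cost: np.ndarray,
    bounds: list[tuple[float, float]],
) -> np.ndarray | None:
    """ll-FBA: big-M MILP with binary direction indicators (Schellenberger-style)."""
    n = S.shape[1]
    internal = [k for k, r in enumerate(net.reactions) if not r.is_boundary]
    Nint = null_space(S[:, internal].astype(float)) if internal else np.zeros((0, 0))
    ni = len(internal)
    M = BIG
    K = 1e3
    # variables: J (n), a (ni, binary), G (ni)
    nvar = n + 2 * ni
    c = np.zeros(nvar)
    c[:n] = cost
    rows, lb_con, ub_con = [], [], []

    def add(row, lo, hi):
        rows.append(row)
        lb_con.append(lo)
        ub_con.append(hi)

    for i, k in enumerate(internal):
        r = np.zeros(nvar)
        r[k] = 1.0
        r[n + i] = -M
        add(r, -np.inf, 0.0)  # J_k - M a_k <= 0
        r = np.zeros(nvar)
        r[k] = 1.0
        r[n + i] = -M
        add(r, -M, np.inf)  # J_k - M a_k >= -M
        r = np.zeros(nvar)
        r[n + ni + i] = 1.0
        r[n + i] = K + 1
        add(r, -np.inf, K)  # G_k + (K+1) a_k <= K  -> a=1 => G <= -1
        add(r, 1.0, np.inf)  # a=0 => G >= 1
    if Nint.size:
        for j in range(Nint.shape[1]):
            r = np.zeros(nvar)
            r[n + ni:] = Nint[:, j]
            add(r, 0.0, 0.0)
    Aeq = np.zeros((S.shape[0], nvar))
    Aeq[:, :n] = S
    for row in Aeq:
        add(row, 0.0, 0.0)
    lo = np.array([b[0] for b in bounds] + [0.0] * ni + [-K] * ni)
    hi = np.array([b[1] for b in bounds] + [1.0] * ni + [K] * ni)
    integrality = np.concatenate([np.zeros(n), np.ones(ni), np.zeros(ni)])
    res = optimize.milp(
        c=c,
        constraints=optimize.LinearConstraint(np.array(rows), lb_con, ub_con),
        bounds=optimize.Bounds(lo, hi),
        integrality=integrality,
    )
    if not res.success:
        return None
    return res.x[:n]


def solve_timepoint(
    net: MetabolicNetwork,
    boundary: dict[str, float],
    direction_policy: dict[str, tuple[float, float]] | None = None,
    boundary_tolerance: float = 0.02,
    variance: dict[str, float] | None = None,
    lactate_fixed: bool = False,
    loopless: str = "auto",
    leak_fraction: float = 0.0,
) -> tuple[np.ndarray, float, str]:
    """Solve one time point; returns (J, objective, status).

    Parameters
    ----------
    boundary
        Mapping with keys ``jo2``, ``jco2``, ``carb``, ``fa`` (and optionally
        ``lactate``), mol/min/kg.
    direction_policy
        Per-reaction (lb, ub) overrides; by default every non-boundary
        reaction is bounded to its written (thermodynamically assigned)
        forward direction, [0, BIG].
    loopless
        ``"auto"`` — LP plus post-hoc cycle scan, escalating to the ll-FBA
        MILP only if an active cycle is found; ``"milp"`` — always MILP;
        ``"off"`` — plain LP.
    leak_fraction
        Fraction of the pumped protonmotive charge dissipated by the
        inner-membrane leak.  Implemented as a virtual flux on the pmf
        pseudo-species coupled to the pumping reactions, so the measured O2
        uptake covers both phosphorylating and leak respiration.  The leak
        flux equals ``leak_fraction * (4 J_C1 + 12 J_C34)`` in the returned
        solution.
    """
    S = stoichiometric_matrix(net).astype(float)
    n = net.n_reactions
    bounds: list[tuple[float, float]] = []
    ex_bounds = _exchange_bounds(net, boundary, boundary_tolerance, variance, lactate_fixed)
    for rxn in net.reactions:
        if rxn.id in ex_bounds:
            bounds.append(ex_bounds[rxn.id])
        elif direction_policy and rxn.id in direction_policy:
            bounds.append(direction_policy[rxn.id])
        else:
            bounds.append((0.0, BIG))
    n_var = n
    if leak_fraction > 0.0 and "dpsi_m" in net.species_ids:
        # augment with a leak variable on the pmf row plus the coupling row
        # f*(4 J_C1 + 12 J_C34) - L = 0; strip the column before returning
        i_psi = net.species_index("dpsi_m")
        leak_col = np.zeros((S.shape[0], 1))
        leak_col[i_psi, 0] = -1.0
        coupling = np.zeros((1, n + 1))
        for rid in ("C1", "C34"):
            k = net.reaction_index(rid)
            coupling[0, k] = leak_fraction * abs(S[i_psi, k])
        coupling[0, n] = -1.0
        S = np.vstack([np.hstack([S, leak_col]), coupling])
        bounds.append((0.0, BIG))
        n_var = n + 1
    cost = np.zeros(n_var)
    k_obj = net.reaction_index(OBJECTIVE_REACTION) if OBJECTIVE_REACTION in net.reaction_ids else None
    if k_obj is not None:
        cost[k_obj] = -1.0  # maximize ATP synthase flux

    if loopless == "milp":
        if n_var != n:
            raise ValueError("loopless='milp' does not support leak_fraction > 0")
        J = _solve_loopless_milp(S, net, cost, bounds)
        if J is None:
            raise InfeasibleBoundaryError(_diagnose(net, boundary))
        return J[:n], (J[k_obj] if k_obj is not None else 0.0), "optimal"

    res = _solve_lp(S, cost, bounds)
    if res.status != 0:
        raise InfeasibleBoundaryError(_diagnose(net, boundary))
    obj = res.x[k_obj] if k_obj is not None else 0.0
    # parsimonious tie-break: minimize total |J| at fixed objective.  All
    # non-boundary fluxes are sign-constrained by their bounds, so the L1
    # norm is linear on the feasible box.
    signs = np.array([1.0 if lo >= 0 else (-1.0 if hi <= 0 else 0.0) for lo, hi in bounds])
    l1_cost = np.where(signs == 0.0, 0.0, signs)
    extra = None
    if k_obj is not None:
        row = np.zeros(n_var)
        row[k_obj] = 1.0
        extra = (row, obj)
    res2 = _solve_lp(S, l1_cost, bounds, extra_eq=extra)
    J = res2.x if res2.status == 0 else res.x
    if loopless == "auto" and n_var == n and _has_active_cycle(net, J):
        J_milp = _solve_loopless_milp(S, net, cost, bounds)
        if J_milp is not None:
            J = J_milp
    residual = np.max(np.abs(S @ J))
    if residual > 1e-9 * max(np.max(np.abs(J)), 1.0):
        return J[:n], obj, "residual"
    return J[:n], obj, "optimal"


def leak_flux_of(net: MetabolicNetwork, J: np.ndarray, leak_fraction: float) -> float:
    """Protonmotive leak flux implied by a solution of :func:`solve_timepoint`."""
    S = stoichiometric_matrix(net)
    i_psi = net.species_index("dpsi_m")
    pumping = sum(
        abs(S[i_psi, net.reaction_index(rid)]) * J[net.reaction_index(rid)]
        for rid in ("C1", "C34")
    )
    return float(leak_fraction * pumping)


def _diagnose(net: MetabolicNetwork, boundary: dict[str, float]) -> str:
    carbon_in = 6.0 * boundary["carb"] + 16.0 * boundary["fa"]
    msg = [f"no steady-state flux distribution for boundary {boundary}"]
    if boundary["jco2"] > carbon_in * 1.05:
        msg.append(
            f"CO2 output ({boundary['jco2']:.3g}) exceeds carbon uptake ({carbon_in:.3g})"
        )
    o2_pred = boundary["jco2"] + 7.0 * boundary["fa"]
    msg.append(
        f"elemental closure requires JO2 ~= JCO2 + 7*J_FA = {o2_pred:.3g} "
        f"(supplied JO2 = {boundary['jo2']:.3g})"
    )
    return "; ".join(msg)


def solve_series(
    net: MetabolicNetwork,
    boundary: BoundaryFluxSeries,
    **kwargs,
) -> FluxSolution:
    """Apply :func:`solve_timepoint` to every row, tolerating per-point failures."""
    n = net.n_reactions
    J = np.full((len(boundary), n), np.nan)
    obj = np.full(len(boundary), np.nan)
    status: list[str] = []
    for i in range(len(boundary)):
        row = boundary.row(i)
        var = {k: v[i] for k, v in boundary.variance.items()} or None
        try:
            Ji, oi, st = solve_timepoint(net, row, variance=var, **kwargs)
            J[i] = Ji
            obj[i] = oi
            status.append(st)
        except InfeasibleBoundaryError:
            status.append("infeasible")
    return FluxSolution(
        reaction_ids=list(net.reaction_ids),
        times=boundary.times.copy(),
        J=J,
        objective_value=obj,
        status=status,
    )


def flux_envelope(
    net: MetabolicNetwork,
    boundary: dict[str, float],
    n_starts: int = 100,
    flux_magnitude_range: tuple[float, float] = (1e-9, 1e9),
    seed: int = 0,
    mode: str = "variability",
    **kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-reaction min/max envelope of alternate optimal solutions.

    ``mode="variability"`` (default, deterministic) minimizes and maximizes
    each reaction flux subject to the objective held at its optimum — the
    exact hull that the multi-start procedure samples.  ``mode="multistart"``
    replicates the stochastic protocol: ``n_starts`` random tie-break cost
    vectors (log-magnitudes drawn over ``flux_magnitude_range``) each select
    one alternate optimum; the envelope is the elementwise min/max.
    """
    if n_starts < 2:
        raise ValueError("n_starts must be >= 2")
    S = stoichiometric_matrix(net).astype(float)
    n = net.n_reactions
    J0, obj, _ = solve_timepoint(net, boundary, **kwargs)
    bounds = _bounds_for(net, boundary, kwargs)
    extra = None
    if OBJECTIVE_REACTION in net.reaction_ids:
        row = np.zeros(n)
        row[net.reaction_index(OBJECTIVE_REACTION)] = 1.0
        extra = (row, obj)
    if mode == "variability":
        lo = J0.copy()
        hi = J0.copy()
        for k in range(n):
            c = np.zeros(n)
            c[k] = 1.0
            rmin = _solve_lp(S, c, bounds, extra_eq=extra)
            rmax = _solve_lp(S, -c, bounds, extra_eq=extra)
            if rmin.status == 0:
                lo[k] = rmin.x[k]
            if rmax.status == 0:
                hi[k] = rmax.x[k]
        return lo, hi
    if mode == "multistart":
        rng = np.random.default_rng(seed)
        lo = np.full(n, np.inf)
        hi = np.full(n, -np.inf)
        lmin, lmax = np.log10(flux_magnitude_range[0]), np.log10(flux_magnitude_range[1])
        for _ in range(n_starts):
            mag = 10.0 ** rng.uniform(lmin, lmax, size=n)
            c = rng.choice([-1.0, 1.0], size=n) * mag / np.max(mag)
            res = _solve_lp(S, c, bounds, extra_eq=extra)
            if res.status == 0:
                lo = np.minimum(lo, res.x)
                hi = np.maximum(hi, res.x)
        return lo, hi
    raise ValueError(f"unknown envelope mode {mode!r}")


def _bounds_for(net: MetabolicNetwork, boundary: dict[str, float], kwargs: dict) -> list[tuple[float, float]]:
    ex_bounds = _exchange_bounds(
        net,
        boundary,
        kwargs.get("boundary_tolerance", 0.02),
        kwargs.get("variance"),
        kwargs.get("lactate_fixed", False),
    )
    policy = kwargs.get("direction_policy") or {}
    out = []
    for rxn in net.reactions:
        if rxn.id in ex_bounds:
            out.append(ex_bounds[rxn.id])
        elif rxn.id in policy:
            out.append(policy[rxn.id])
        else:
            out.append((0.0, BIG))
    return out


def atpase_demand_curve(
    sol: FluxSolution, degree: int = 3, reaction: str = "ATPASE"
) -> Callable[[np.ndarray], np.ndarray]:
    """Least-squares polynomial through the ATP-demand fluxes, clamped to >= 0.

    The returned interpolant drives the kinetic model as the imposed work
    rate.  Only successfully solved time points enter the fit.
    """
    ok = sol.ok
    t = sol.times[ok]
    y = sol.flux(reaction)[ok]
    if len(t) < 3:
        raise ValueError("need at least 3 solved time points")
    if degree >= len(t):
        raise ValueError(f"polynomial degree {degree} >= number of points {len(t)}")
    coeffs = np.polyfit(t, y, degree)

    def demand(times: np.ndarray | float) -> np.ndarray | float:
        return np.maximum(np.polyval(coeffs, times), 0.0)

    demand.coefficients = coeffs  # type: ignore[attr-defined]
    return demand
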