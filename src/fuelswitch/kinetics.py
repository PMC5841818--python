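"""Compartmentalized kinetic model driven by an ATP-demand protocol.

The state is the 98-entry concentration vector C (molar).  Its dynamics are

    dC/dt = P^-1 . S . J_calc(C),

where P is the diagonal partition matrix of effective compartment water
volumes (0.755 L water per kg muscle times the compartment volume fraction)
and every reaction flux follows the generalized thermodynamic rate law

    J_k = X_k * Ct_k * (1 - exp(dG'_k / RT)) / (1 + exp((dG'_k - dG'0_k) / RT)),
    Ct_k = prod(C_i^mu_i) + prod(C_i^nu_i)          (unitless, 1 M reference),

whose sign is always opposite to dG'_k — mass balance plus the second law
are the only kinetic assumptions (no saturation constants, no allostery).
X_k is the enzyme activity; the ATP-demand reaction is not given a rate law
but is driven directly at the protocol's demanded hydrolysis rate,
attenuated smoothly to zero when cytosolic ATP approaches a floor so that an
unmeetable demand produces a detectable collapse instead of a solver abort.

Boundary supply/sink species (plasma glucose, fatty acid, O2, CO2 and the
waters) are clamped; plasma lactate is a free state whose export step acts
as clearance, so it accumulates when glycolytic output exceeds disposal.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .constants import RQ_FAT, WATER_VOLUME_L_PER_KG
from .network import MetabolicNetwork, stoichiometric_matrix
from .thermo import ThermoContext

__all__ = [
    "ActivitySchedule",
    "DemandProtocol",
    "SolverOptions",
    "TransitionSpec",
    "KineticModel",
    "Trajectory",
    "activities_to_array",
    "initial_activities",
    "equilibrate_side_pools",
    "reaction_flux",
    "transition_activities",
    "fuel_fractions",
    "run_normalized_protocol",
    "simulate",
]

#: species clamped during integration: external supplies/sinks and the waters
DEFAULT_CLAMPED = ("glc_e", "fa_e", "o2_e", "co2_e", "h2o_e", "h2o", "h2o_m")

#: demand reaction driven directly by the protocol
DEMAND_REACTION = "ATPASE"

#: effective capacitance scale of the protonmotive pseudo-species: its pool
#: is made small so the potential equilibrates within seconds, fast relative
#: to metabolite dynamics, as a membrane potential does
PSI_CAPACITANCE = 1e-4

#: proton-leak exponent: the inner-membrane leak grows superlinearly with
#: the potential (the classic non-ohmic leak), modeled as g * dpsi**LEAK_EXPONENT
LEAK_EXPONENT = 3.0

#: fraction of resting charge pumping dissipated by the leak (state-4
#: respiration is roughly a fifth of resting oxygen consumption)
RESTING_LEAK_FRACTION = 0.15

_EXP_CLIP = 500.0


@dataclass(frozen=True)
class SolverOptions:
    """Stiff-integrator settings (BDF with a stoichiometry-derived Jacobian sparsity)."""

    reltol: float = 1e-10
    abstol: float = 1e-12
    max_step: float = np.inf
    conc_floor: float = 1e-12
    atp_floor: float = 1e-6
    n_save: int = 201

    @classmethod
    def fast(cls) -> "SolverOptions":
        """Looser tolerances for fitting loops and scans."""
        return cls(reltol=1e-6, abstol=1e-9)


@dataclass
class DemandProtocol:
    """ATP-hydrolysis demand as a function of time (mol/min/kg, always >= 0).

    Modes: ``constant`` (level), ``linear_ramp`` (level + slope * t),
    ``interpolated_curve`` (arbitrary callable, e.g. the polynomial fitted to
    the constraint-based ATPase fluxes), ``stepped`` (piecewise-constant
    (duration_min, rate) steps).
    """

    mode: str = "constant"
    level: float = 0.0
    slope: float = 0.0
    curve: Callable[[float], float] | None = None
    steps: Sequence[tuple[float, float]] = ()

    def rate(self, t: float) -> float:
        if self.mode == "constant":
            r = self.level
        elif self.mode == "linear_ramp":
            r = self.level + self.slope * t
        elif self.mode == "interpolated_curve":
            if self.curve is None:
                raise ValueError("interpolated_curve mode requires a curve")
            r = float(self.curve(t))
        elif self.mode == "stepped":
            r, elapsed = 0.0, 0.0
            for dur, rate in self.steps:
                if t < elapsed + dur:
                    r = rate
                    break
                elapsed += dur
            else:
                r = self.steps[-1][1] if self.steps else 0.0
        else:
            raise ValueError(f"unknown demand mode {self.mode!r}")
        return max(float(r), 0.0)


@dataclass
class TransitionSpec:
    """Monoexponential rest-to-exercise activity transition.

    X(%VO2max) = X_exercise + (X_rest - X_exercise) * exp(-(%VO2max - %VO2rest) * Tc)

    ``Tc`` is the transition constant per %VO2max (multiplicative convention:
    larger Tc means a faster switch to the exercise activities).
    """

    X_rest: dict[str, float]
    X_exercise: dict[str, float]
    Tc: float
    vo2_rest: float = 0.0

    def __post_init__(self) -> None:
        if self.Tc <= 0:
            raise ValueError("Tc must be > 0")


@dataclass
class ActivitySchedule:
    """Enzyme activities mobilized with the imposed work rate.

    At rest every activity equals its ``X_rest`` entry; as the demanded
    ATPase rate rises, catalytic capacity is mobilized in proportion to the
    work rate — the common mobilization scale is ``s(d) = clip(1 + gamma *
    (d / demand_rest - 1), 1, headroom)``, exactly 1 at the resting demand —
    up to a per-reaction capacity ceiling:

        X_k(d) = X_rest_k * min(s(d), headroom * f_k).

    ``f_k`` is the reaction's capacity factor (default 1).  The schedule is
    the time-domain counterpart of the %VO2max-driven monoexponential
    transition used by the normalized-exercise protocols: muscle mobilizes
    catalytic capacity (calcium activation, covalent modification) on the
    timescale of the work-rate change, and a resting muscle does not hold
    its full exercise capacity in the active state.

    The two knobs separate cleanly: ``X_rest`` holds the 86 adjustable base
    activities (sensitivity analysis and ensemble perturbations act here and
    rescale the whole schedule), while genotype transforms and hypothesis
    fits act on the capacity factors ``f_k`` — resting metabolism is shared
    between phenotypes (resting oxygen uptake of high- and low-capacity
    runners is alike), and a capacity deficit only binds at the workloads
    that exceed the reduced ceiling.
    """

    X_rest: dict[str, float]
    demand_rest: float
    gamma: float = 1.02
    headroom: float = 10.0
    factors: dict[str, float] = field(default_factory=dict)
    #: minimum mobilization (pre-activation), used by experiments that
    #: deliberately hold part of the machinery above its resting share
    floor: float = 1.0

    def scale(self, demand_rate: float) -> float:
        if self.demand_rest <= 0:
            return 1.0
        s = 1.0 + self.gamma * (demand_rate / self.demand_rest - 1.0)
        return float(np.clip(max(s, self.floor), 1.0, self.headroom))

    def activities(self, demand_rate: float) -> dict[str, float]:
        s = self.scale(demand_rate)
        return {
            rid: x * min(s, self.headroom * self.factors.get(rid, 1.0))
            for rid, x in self.X_rest.items()
        }

    def recruitment(self, demand_rate: float, order: Sequence[str]) -> np.ndarray:
        """Per-reaction activity multipliers at a demand rate, in ``order``."""
        s = self.scale(demand_rate)
        return np.array(
            [min(s, self.headroom * self.factors.get(rid, 1.0)) for rid in order]
        )

    def scaled(self, factors: Mapping[str, float]) -> "ActivitySchedule":
        """New schedule with per-reaction recruitment factors multiplied in."""
        merged = dict(self.factors)
        for rid, f in factors.items():
            merged[rid] = merged.get(rid, 1.0) * f
        return ActivitySchedule(
            X_rest=dict(self.X_rest),
            demand_rest=self.demand_rest,
            gamma=self.gamma,
            headroom=self.headroom,
            factors=merged,
        )


def transition_activities(spec: TransitionSpec, vo2: float) -> dict[str, float]:
    """Interpolated activities at an exercise intensity (%VO2max)."""
    if vo2 < spec.vo2_rest:
        raise ValueError("vo2 must be >= vo2_rest")
    w = np.exp(-(vo2 - spec.vo2_rest) * spec.Tc)
    return {
        rid: spec.X_exercise[rid] + (spec.X_rest[rid] - spec.X_exercise[rid]) * w
        for rid in spec.X_rest
    }


def fuel_fractions(rq: float) -> tuple[float, float]:
    """(%FA, %carbohydrate) from the respiratory quotient.

    %FA = 100 * (1 - RQ) / (1 - 0.7), clipped to [0, 100]; carbohydrate is
    the complement.  RQ outside [0.6, 1.1] is clipped with a warning.
    """
    if not (0.6 <= rq <= 1.1):
        import warnings

        warnings.warn(f"RQ {rq:.3f} outside [0.6, 1.1]; clipping", stacklevel=2)
        rq = float(np.clip(rq, 0.6, 1.1))
    fa = float(np.clip(100.0 * (1.0 - rq) / (1.0 - RQ_FAT), 0.0, 100.0))
    return fa, 100.0 - fa


# ----------------------------------------------------------------------
# Model assembly
# ----------------------------------------------------------------------


class KineticModel:
    """Precompiled rate-law evaluator and ODE right-hand side for one network."""

    def __init__(
        self,
        net: MetabolicNetwork,
        ctx: ThermoContext | None = None,
        clamped: Sequence[str] = DEFAULT_CLAMPED,
        leak_conductance: float = 0.0,
        leak_exponent: float = LEAK_EXPONENT,
    ):
        self.net = net
        # inner-membrane proton leak: charge flux g * dpsi**nl (mol/min/kg),
        # a membrane property of the pmf pseudo-species (like its capacitance)
        self.leak_conductance = leak_conductance
        self.leak_exponent = leak_exponent
        self.ctx = ctx or ThermoContext()
        self.S = stoichiometric_matrix(net).astype(float)
        n_sp, n_rx = self.S.shape
        sub = np.zeros((n_rx, n_sp))
        prod = np.zeros((n_rx, n_sp))
        for k, rxn in enumerate(net.reactions):
            for sid, coeff in rxn.stoichiometry.items():
                i = net.species_index(sid)
                if coeff < 0:
                    sub[k, i] = -coeff
                else:
                    prod[k, i] = coeff
        self.A_sub = sparse.csr_matrix(sub)
        self.A_prod = sparse.csr_matrix(prod)
        self.dg0 = np.array([r.dG0_prime for r in net.reactions])
        self.k_demand = net.reaction_index(DEMAND_REACTION) if DEMAND_REACTION in net.reaction_ids else None
        self.i_atp = net.species_index("atp") if "atp" in net.species_ids else None
        self.i_dpsi = net.species_index("dpsi_m") if "dpsi_m" in net.species_ids else None
        vf = {c.id: c.volume_fraction for c in net.compartments}
        self.volumes = np.array(
            [WATER_VOLUME_L_PER_KG * vf[s.compartment] for s in net.species]
        )
        if "dpsi_m" in net.species_ids:
            self.volumes[net.species_index("dpsi_m")] *= PSI_CAPACITANCE
        self.clamped_mask = np.array([s.id in set(clamped) for s in net.species])
        self.S_sparse = sparse.csr_matrix(self.S)
        # Jacobian sparsity: dC_i/dC_j nonzero when i and j share a reaction
        participates = (np.abs(sub) + np.abs(prod)) > 0  # (rx, sp)
        touched = (np.abs(self.S) > 0)  # (sp, rx)
        pattern = (touched @ participates) > 0
        pattern |= np.eye(n_sp, dtype=bool)
        pattern[self.clamped_mask, :] = False
        self.jac_sparsity = sparse.csr_matrix(pattern)

    # -- rate law ------------------------------------------------------
    def fluxes(
        self,
        conc: np.ndarray,
        X: np.ndarray,
        demand_rate: float | None = None,
        conc_floor: float = 1e-12,
        atp_floor: float = 1e-6,
    ) -> np.ndarray:
        """Rate-law fluxes for a concentration vector (demand overrides ATPase)."""
        c = np.maximum(conc, conc_floor)
        ln_c = np.log(c / self.ctx.reference_conc)
        ln_sub = self.A_sub @ ln_c
        ln_prod = self.A_prod @ ln_c
        ln_q = ln_prod - ln_sub
        ct = np.exp(np.clip(ln_sub, -_EXP_CLIP, _EXP_CLIP)) + np.exp(
            np.clip(ln_prod, -_EXP_CLIP, _EXP_CLIP)
        )
        rt = self.ctx.RT
        e_g = np.exp(np.clip(self.dg0 / rt + ln_q, -_EXP_CLIP, _EXP_CLIP))
        e_q = np.exp(np.clip(ln_q, -_EXP_CLIP, _EXP_CLIP))
        J = X * ct * (1.0 - e_g) / (1.0 + e_q)
        if demand_rate is not None and self.k_demand is not None:
            atp = c[self.i_atp] if self.i_atp is not None else 1.0
            J[self.k_demand] = demand_rate * atp / (atp + atp_floor)
        return J

    def rhs(
        self,
        t: float,
        conc: np.ndarray,
        X: np.ndarray,
        demand: Callable[[float], float] | None,
        opts: SolverOptions,
        schedule=None,
    ) -> np.ndarray:
        rate = demand(t) if demand is not None else None
        if schedule is not None and rate is not None:
            f_arr = getattr(schedule, "_f_arr", None)
            if f_arr is None:
                f_arr = np.array(
                    [schedule.factors.get(r.id, 1.0) for r in self.net.reactions]
                )
                schedule._f_arr = f_arr
            X = X * np.minimum(schedule.scale(rate), schedule.headroom * f_arr)
        J = self.fluxes(conc, X, rate, opts.conc_floor, opts.atp_floor)
        dC = (self.S_sparse @ J) / self.volumes
        if self.leak_conductance > 0.0 and self.i_dpsi is not None:
            leak = self.leak_conductance * max(conc[self.i_dpsi], 0.0) ** self.leak_exponent
            dC[self.i_dpsi] -= leak / self.volumes[self.i_dpsi]
        dC[self.clamped_mask] = 0.0
        return dC

    def rhs_log(
        self,
        t: float,
        z: np.ndarray,
        X: np.ndarray,
        demand: Callable[[float], float] | None,
        opts: SolverOptions,
        schedule=None,
    ) -> np.ndarray:
        """RHS in log-concentration coordinates (dz/dt = (dC/dt) / C).

        Integrating z = ln C keeps every state strictly positive — the
        structural equivalent of a non-negativity option — and equalizes the
        relative error control across pools spanning ten orders of magnitude.
        """
        conc = np.exp(np.clip(z, -80.0, 80.0))
        return self.rhs(t, conc, X, demand, opts, schedule) / conc

    def conc_array(self, conc: Mapping[str, float]) -> np.ndarray:
        return np.array([conc[s.id] for s in self.net.species], dtype=float)

    def conc_dict(self, arr: np.ndarray) -> dict[str, float]:
        return {s.id: float(v) for s, v in zip(self.net.species, arr)}


def activities_to_array(net: MetabolicNetwork, X: Mapping[str, float]) -> np.ndarray:
    """Dense activity array in network reaction order; the demand reaction gets 0."""
    arr = np.zeros(net.n_reactions)
    for rid, val in X.items():
        if rid == DEMAND_REACTION:
            continue
        arr[net.reaction_index(rid)] = val
    return arr


def reaction_flux(
    net: MetabolicNetwork,
    conc: Mapping[str, float],
    X: Mapping[str, float],
    ctx: ThermoContext | None = None,
) -> dict[str, float]:
    """Generalized rate-law flux of every reaction at one state (no demand override)."""
    model = KineticModel(net, ctx)
    J = model.fluxes(model.conc_array(conc), activities_to_array(net, X))
    return {rid: float(j) for rid, j in zip(net.reaction_ids, J)}


#: sarcolemmal substrate-supply steps get their own (lower) headroom: their
#: influx must track demand through thermodynamic back-pressure, not enzyme
#: excess, or substrate floods the intracellular carrier pools
SUPPLY_REACTIONS = {"FAT": 1.0, "GLUT": 1.0}


def initial_activities(
    net: MetabolicNetwork,
    conc0: Mapping[str, float],
    resting_fluxes: Mapping[str, float],
    headroom: float = 10.0,
    supply_headroom: Mapping[str, float] | None = None,
    ctx: ThermoContext | None = None,
    flux_tol_frac: float = 1e-9,
) -> dict[str, float]:
    """Solve the rate law algebraically for X at the resting state.

    ``X_k = J_k / (Ct_k * thermo_term_k)`` reproduces the resting
    constraint-based fluxes exactly at ``conc0``.  Reactions carrying no
    resting flux (creatine kinase, the acyl-carnitine side pools, ...) have
    an indeterminate activity and receive the median of the determined ones.
    All activities are then scaled by ``headroom`` (>= 1) so the enzymes can
    sustain demands above the resting rate; the substrate-supply transport
    steps use the (small) per-reaction factors in ``supply_headroom``
    (default :data:`SUPPLY_REACTIONS`) and the demand reaction is excluded.
    """
    model = KineticModel(net, ctx)
    c = model.conc_array(dict(conc0))
    unit = model.fluxes(c, np.ones(net.n_reactions))
    j_ref = np.array([resting_fluxes.get(r, 0.0) for r in net.reaction_ids])
    scale = np.max(np.abs(j_ref))
    if scale == 0:
        raise ValueError("resting fluxes are all zero")
    X = np.zeros(net.n_reactions)
    determined = (np.abs(j_ref) > flux_tol_frac * scale) & (np.abs(unit) > 0)
    X[determined] = j_ref[determined] / unit[determined]
    if np.any(X[determined] < 0):
        bad = [net.reaction_ids[k] for k in np.where(determined & (X < 0))[0]]
        raise ValueError(
            f"resting flux runs against its free-energy gradient for {bad}; "
            "the concentration vector is thermodynamically infeasible for these fluxes"
        )
    fallback = float(np.median(X[determined & (X > 0)]))
    X[~determined] = fallback
    # the near-equilibrium buffering enzymes (creatine kinase, carnitine
    # acetyltransferase and its translocase) are among the most active in
    # muscle; give them capacity well above the pathway scale so the PCr and
    # acetyl-carnitine pools actually buffer transients
    for rid in ("CK", "CRAT", "CACT_AC"):
        k = net.reaction_index(rid) if rid in net.reaction_ids else None
        if k is not None and not determined[k]:
            X[k] = fallback * 20.0
    supply = dict(SUPPLY_REACTIONS if supply_headroom is None else supply_headroom)
    out = {}
    for rid, x in zip(net.reaction_ids, X):
        if rid == DEMAND_REACTION:
            continue
        out[rid] = float(x * supply.get(rid, headroom))
    return out


#: (reaction, species-to-adjust) pairs used to equilibrate resting side pools
_SIDE_POOL_ADJUSTMENTS = (
    ("CK", "pcr"),
    ("CRAT", "acarn_m"),
    ("CACT_AC", "acarn"),
    ("ACT_C14", "c14carn_m"),
    ("CACT_C14", "c14carn"),
    ("ACT_C8", "c8carn_m"),
    ("CACT_C8", "c8carn"),
    ("ACT_C4", "c4carn_m"),
    ("CACT_C4", "c4carn"),
)


def equilibrate_side_pools(
    net: MetabolicNetwork,
    conc: Mapping[str, float],
    ctx: ThermoContext | None = None,
    adjustments: Sequence[tuple[str, str]] = _SIDE_POOL_ADJUSTMENTS,
) -> dict[str, float]:
    """Analytically set side-pool species so their zero-flux reactions start at dG' = 0.

    At rest the buffering reactions (creatine kinase, the acyl-carnitine
    transferases and translocases) carry no net flux, so their
    pools must sit at equilibrium; for each (reaction, species) pair the
    species' concentration is solved from dG' = 0, clipped to its bounds.
    Order matters: upstream pools are equilibrated before the pools fed by
    them.
    """
    ctx = ctx or ThermoContext()
    out = dict(conc)
    for rid, sid in adjustments:
        if rid not in net.reaction_ids or sid not in net.species_ids:
            continue
        rxn = net.get_reaction(rid)
        coeff = rxn.stoichiometry[sid]
        ln_rest = sum(
            co * np.log(out[s] / ctx.reference_conc)
            for s, co in rxn.stoichiometry.items()
            if s != sid
        )
        # dG0 + RT (ln_rest + coeff * ln c) = 0
        ln_c = (-rxn.dG0_prime / ctx.RT - ln_rest) / coeff
        sp = net.get_species(sid)
        out[sid] = float(np.clip(np.exp(ln_c), sp.conc_lower, sp.conc_upper))
    return out


# ----------------------------------------------------------------------
# Simulation
# ----------------------------------------------------------------------


@dataclass
class Trajectory:
    """Integrated kinetic trajectory with derived fuel-selection observables."""

    model: KineticModel
    times: np.ndarray  # minutes
    conc: np.ndarray  # (n_times, n_species)
    X: np.ndarray  # resting activity array used
    demand: np.ndarray  # demanded ATPase rate at save times
    status: str = "ok"  # ok | demand_not_met | integration_error
    failure_time: float | None = None
    message: str = ""
    schedule: "ActivitySchedule | None" = None
    _fluxes: np.ndarray | None = field(default=None, repr=False)

    def conc_of(self, sid: str) -> np.ndarray:
        return self.conc[:, self.model.net.species_index(sid)]

    def fluxes(self) -> np.ndarray:
        """(n_times, n_reactions) rate-law fluxes along the trajectory."""
        if self._fluxes is None:
            out = np.empty((len(self.times), self.model.S.shape[1]))
            rids = self.model.net.reaction_ids
            for i in range(len(self.times)):
                X = self.X
                if self.schedule is not None:
                    X = X * self.schedule.recruitment(self.demand[i], rids)
                out[i] = self.model.fluxes(self.conc[i], X, self.demand[i])
            self._fluxes = out
        return self._fluxes

    def flux_of(self, rid: str) -> np.ndarray:
        return self.fluxes()[:, self.model.net.reaction_index(rid)]

    def delta_g(self) -> np.ndarray:
        """(n_times, n_reactions) transformed reaction free energies."""
        from .thermo import delta_g_prime

        net = self.model.net
        return np.array(
            [
                delta_g_prime(net, self.model.conc_dict(np.maximum(c, 1e-30)), self.model.ctx)
                for c in self.conc
            ]
        )

    # -- fuel-selection observables -----------------------------------
    @property
    def jo2(self) -> np.ndarray:
        return self.flux_of("O2T")

    @property
    def jco2(self) -> np.ndarray:
        return self.flux_of("CO2T")

    @property
    def rq(self) -> np.ndarray:
        return self.jco2 / np.maximum(self.jo2, 1e-30)

    @property
    def plasma_lactate(self) -> np.ndarray:
        return self.conc_of("lac_e")

    def carnitine_pools(self) -> dict[str, np.ndarray]:
        """Volume-weighted total acyl-carnitine pools (mol per L tissue water)."""
        net = self.model.net
        vf = {c.id: c.volume_fraction for c in net.compartments}

        def pool(*sids: str) -> np.ndarray:
            tot = np.zeros(len(self.times))
            for sid in sids:
                tot += vf[net.get_species(sid).compartment] * self.conc_of(sid)
            return tot

        return {
            "C16": pool("c16carn", "c16carn_m"),
            "C14": pool("c14carn", "c14carn_m"),
            "C8": pool("c8carn", "c8carn_m"),
            "C4": pool("c4carn", "c4carn_m"),
            "acetyl": pool("acarn", "acarn_m"),
            "free": pool("carn", "carn_m"),
        }

    def observables(self):
        """Tidy frame of the measured/derived readouts along the trajectory."""
        import pandas as pd

        rt = self.model.ctx.RT
        data = {
            "time_min": self.times,
            "JO2": self.jo2,
            "JCO2": self.jco2,
            "RQ": self.rq,
            "lactate": self.plasma_lactate,
            "atp": self.conc_of("atp"),
            "nad_ratio_cyt": self.conc_of("nad") / self.conc_of("nadh"),
            "nad_ratio_mito": self.conc_of("nad_m") / self.conc_of("nadh_m"),
            "dpsi_proxy": rt * np.log(np.maximum(self.conc_of("dpsi_m"), 1e-30)),
            "accoa_coa_mito": self.conc_of("accoa_m") / self.conc_of("coa_m"),
        }
        dg = self.model.dg0[self.model.net.reaction_index("ATPASE")]
        q = (self.conc_of("adp") * self.conc_of("pi")) / self.conc_of("atp")
        data["dG_atp_hydrolysis"] = dg + rt * np.log(np.maximum(q, 1e-30))
        for name, v in self.carnitine_pools().items():
            data[f"carn_{name}"] = v
        return pd.DataFrame(data)


def simulate(
    net: MetabolicNetwork,
    conc0: Mapping[str, float],
    X: Mapping[str, float],
    protocol: DemandProtocol,
    t_span: tuple[float, float],
    solver_opts: SolverOptions | None = None,
    model: KineticModel | None = None,
    atp_fail_fraction: float = 0.25,
) -> Trajectory:
    """Integrate the stiff ODE system over ``t_span`` (minutes).

    An unmeetable ATP demand is a reportable outcome, not an exception: when
    cytosolic ATP drops below ``atp_fail_fraction`` of its initial value the
    trajectory is flagged ``demand_not_met`` with the collapse time, and the
    integration continues on the attenuated demand as far as it can.
    """
    opts = solver_opts or SolverOptions()
    model = model or KineticModel(net)
    c0 = model.conc_array(dict(conc0))
    schedule = None
    if isinstance(X, ActivitySchedule):
        schedule = X
        X_arr = activities_to_array(net, X.X_rest)
    elif isinstance(X, np.ndarray):
        X_arr = X
    else:
        X_arr = activities_to_array(net, X)
    t_eval = np.linspace(t_span[0], t_span[1], opts.n_save)

    # integrate in log-concentration space: positivity is structural and the
    # tolerances act on relative concentration errors
    z0 = np.log(np.maximum(c0, opts.conc_floor))
    sol = solve_ivp(
        model.rhs_log,
        t_span,
        z0,
        method="BDF",
        t_eval=t_eval,
        args=(X_arr, protocol.rate, opts, schedule),
        rtol=opts.reltol,
        atol=max(opts.reltol, opts.abstol),
        max_step=opts.max_step,
        jac_sparsity=model.jac_sparsity,
    )
    times = sol.t
    conc = np.exp(sol.y.T)
    demand = np.array([protocol.rate(t) for t in times])
    traj = Trajectory(
        model=model, times=times, conc=conc, X=X_arr, demand=demand, schedule=schedule
    )
    if not sol.success:
        traj.status = "integration_error"
        traj.message = sol.message
        traj.failure_time = float(times[-1]) if len(times) else float(t_span[0])
    if model.i_atp is not None and len(times):
        # a demand failure is a *sustained* collapse: brief dips with full
        # recovery (relaxation oscillations of the acetyl buffers) are not
        # flagged, a terminal or > 2 min excursion below the floor is
        atp = conc[:, model.i_atp]
        low = atp < atp_fail_fraction * atp[0]
        if np.any(low):
            run_start = None
            dt = times[1] - times[0] if len(times) > 1 else 0.0
            fail_at = None
            count = 0
            for i, flag in enumerate(low):
                if flag:
                    if run_start is None:
                        run_start = i
                    count += 1
                    if low[-1] and i == len(low) - 1:
                        fail_at = run_start
                        break
                    if count * dt > 2.0:
                        fail_at = run_start
                        break
                else:
                    run_start, count = None, 0
            if fail_at is not None:
                traj.status = "demand_not_met"
                traj.failure_time = float(times[fail_at])
                traj.message = (
                    f"cytosolic ATP fell below {atp_fail_fraction:.0%} of its "
                    f"initial value at t = {traj.failure_time:.2f} min and did "
                    "not recover"
                )
    if np.any(~np.isfinite(conc)):
        traj.status = "integration_error"
        traj.message = traj.message or "non-finite state encountered"
    return traj


def run_normalized_protocol(
    net: MetabolicNetwork,
    conc0: Mapping[str, float],
    spec: TransitionSpec,
    steps: Sequence[float],
    dwell: float,
    demand_at_max: float,
    solver_opts: SolverOptions | None = None,
    model: KineticModel | None = None,
):
    """RQ versus %VO2max under a stepped, intensity-normalized exercise protocol.

    Each step holds the ATP demand at ``demand_at_max * vo2 / 100`` for
    ``dwell`` minutes with activities interpolated by the transition spec at
    that intensity; the concentration state carries over between steps.
    Dwell 2 min mimics a graded (transient) protocol, 60 min a steady-state
    one.  Failed steps are marked and do not abort the scan.

    Returns a DataFrame with columns vo2, rq, fa_pct, cho_pct, status.
    """
    import pandas as pd

    model = model or KineticModel(net)
    opts = solver_opts or SolverOptions()
    state = dict(conc0)
    records = []
    for vo2 in steps:
        X = transition_activities(spec, vo2)
        protocol = DemandProtocol(mode="constant", level=demand_at_max * vo2 / 100.0)
        traj = simulate(net, state, X, protocol, (0.0, dwell), opts, model=model)
        rq = float(traj.rq[-1])
        ok = traj.status == "ok"
        fa = cho = np.nan
        if ok and np.isfinite(rq):
            fa, cho = fuel_fractions(rq)
        records.append(
            {"vo2": vo2, "rq": rq if ok else np.nan, "fa_pct": fa, "cho_pct": cho,
             "status": traj.status}
        )
        if len(traj.times):
            state = model.conc_dict(traj.conc[-1])
    return pd.DataFrame(records)
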