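"""Transformed reaction free energies and feasible concentration sampling.

The actual transformed free energy of reaction ``k`` is

    dG'_k = dG'0_k + R*T*ln(Q_k),

with the mass-action ratio ``Q_k = prod(products^nu) / prod(substrates^mu)``
(each concentration divided by the 1 M reference).  A concentration vector is
thermodynamically feasible for a reference flux pattern J when every reaction
carrying flux dissipates free energy: ``dG'_k * J_k < 0`` (the second law,
evaluated reaction-by-reaction).

Feasible resting vectors are drawn by Monte Carlo: species are sampled
log-uniformly between their literature bounds and a candidate is accepted
only if the full vector passes the second-law check.  A coordinate repair
mode resamples only the species participating in violated reactions, which
keeps the search desk-scale on the 98-species network; acceptance is still
an all-or-nothing re-check of the complete vector.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import REFERENCE_CONC, R_KJ, T_KELVIN
from .network import MetabolicNetwork

__all__ = [
    "ThermoContext",
    "InfeasibleSampleError",
    "delta_g_prime",
    "mass_action_ln_q",
    "second_law_violations",
    "sample_feasible_concentrations",
    "save_concentrations",
    "load_concentrations",
]

#: strictness margin for the second-law inequality, kJ/mol
EPSILON_KJ = 1e-9


@dataclass(frozen=True)
class ThermoContext:
    """Fixed thermodynamic conditions (25 degC, pH 7, 1 M reference)."""

    R: float = R_KJ
    T: float = T_KELVIN
    reference_conc: float = REFERENCE_CONC

    @property
    def RT(self) -> float:
        return self.R * self.T


class InfeasibleSampleError(RuntimeError):
    """Monte Carlo search exhausted; carries the most-violated reactions."""

    def __init__(self, message: str, violation_counts: dict[str, int]):
        super().__init__(message)
        self.violation_counts = violation_counts


def _conc_array(net: MetabolicNetwork, conc: dict[str, float]) -> np.ndarray:
    try:
        values = np.array([conc[s.id] for s in net.species], dtype=float)
    except KeyError as exc:
        raise KeyError(f"concentration vector missing species {exc.args[0]!r}") from exc
    if np.any(~np.isfinite(values)) or np.any(values <= 0.0):
        bad = [s.id for s, v in zip(net.species, values) if not (np.isfinite(v) and v > 0)]
        raise ValueError(f"concentrations must be finite and > 0; offending species: {bad}")
    return values


def mass_action_ln_q(net: MetabolicNetwork, conc: dict[str, float], ctx: ThermoContext | None = None) -> np.ndarray:
    """ln(Q) per reaction, computed in log space for numerical safety."""
    ctx = ctx or ThermoContext()
    values = _conc_array(net, conc)
    ln_c = np.log(values / ctx.reference_conc)
    ln_q = np.zeros(net.n_reactions)
    for k, rxn in enumerate(net.reactions):
        ln_q[k] = sum(coeff * ln_c[net.species_index(sid)] for sid, coeff in rxn.stoichiometry.items())
    return ln_q


def delta_g_prime(
    net: MetabolicNetwork, conc: dict[str, float], ctx: ThermoContext | None = None
) -> np.ndarray:
    """Transformed reaction free energies, kJ/mol, in network reaction order."""
    ctx = ctx or ThermoContext()
    dg0 = np.array([r.dG0_prime for r in net.reactions])
    return dg0 + ctx.RT * mass_action_ln_q(net, conc, ctx)


def second_law_violations(
    net: MetabolicNetwork,
    conc: dict[str, float],
    reference_fluxes: dict[str, float],
    ctx: ThermoContext | None = None,
    flux_tol: float = 0.0,
) -> list[str]:
    """Reactions with |J| > flux_tol whose flux runs against its free-energy gradient."""
    dg = delta_g_prime(net, conc, ctx)
    bad = []
    for k, rxn in enumerate(net.reactions):
        j = reference_fluxes.get(rxn.id, 0.0)
        if abs(j) > flux_tol and dg[k] * j > -EPSILON_KJ:
            bad.append(rxn.id)
    return bad


def save_concentrations(conc: dict[str, float], path) -> None:
    """Two-column CSV (species_id, molar)."""
    import pandas as pd

    pd.DataFrame(
        {"species_id": list(conc), "molar": list(conc.values())}
    ).to_csv(path, index=False)


def load_concentrations(path) -> dict[str, float]:
    import pandas as pd

    df = pd.read_csv(path)
    return dict(zip(df["species_id"], df["molar"].astype(float)))


@dataclass
class SampleReport:
    seed: int
    attempts: int
    repaired: bool
    violation_counts: dict[str, int] = field(default_factory=dict)


def sample_feasible_concentrations(
    net: MetabolicNetwork,
    resting_fluxes: dict[str, float],
    ctx: ThermoContext | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    max_tries: int = 20000,
    repair: bool = True,
    flux_tol: float = 0.0,
) -> tuple[dict[str, float], SampleReport]:
    """Draw a concentration vector satisfying the second law for a flux pattern.

    Parameters
    ----------
    resting_fluxes
        Reference flux per reaction id (typically the resting constraint-based
        solution); reactions with zero flux impose no sign constraint.
    bounds
        Per-species (lower, upper) molar bounds; defaults to the network's.
    repair
        After a failed full draw, resample only species participating in
        violated reactions instead of the whole vector.  The returned vector
        is always re-checked in full.

    Returns
    -------
    (concentrations, report)
        A feasible vector and a provenance record (seed, attempt count).

    Raises
    ------
    InfeasibleSampleError
        when ``max_tries`` is exhausted; its ``violation_counts`` lists the
        reactions violated most often.
    """
    ctx = ctx or ThermoContext()
    bounds = bounds or net.concentration_bounds()
    rng = np.random.default_rng(seed)
    log_lb = {s.id: np.log(bounds[s.id][0]) for s in net.species}
    log_ub = {s.id: np.log(bounds[s.id][1]) for s in net.species}

    def draw(sids: list[str], conc: dict[str, float]) -> dict[str, float]:
        conc = dict(conc)
        for sid in sids:
            conc[sid] = float(np.exp(rng.uniform(log_lb[sid], log_ub[sid])))
        return conc

    all_ids = net.species_ids
    conc = draw(all_ids, {})
    counts: dict[str, int] = {}
    repaired = False
    for attempt in range(1, max_tries + 1):
        bad = second_law_violations(net, conc, resting_fluxes, ctx, flux_tol=flux_tol)
        if not bad:
            return conc, SampleReport(seed=seed, attempts=attempt, repaired=repaired,
                                      violation_counts=counts)
        for rid in bad:
            counts[rid] = counts.get(rid, 0) + 1
        if repair:
            involved = sorted({sid for rid in bad for sid in net.get_reaction(rid).stoichiometry})
            conc = draw(involved, conc)
            repaired = True
        else:
            conc = draw(all_ids, {})
    worst = dict(sorted(counts.items(), key=lambda kv: -kv[1])[:10])
    raise InfeasibleSampleError(
        f"no feasible concentration vector in {max_tries} tries; "
        f"most-violated reactions: {worst}",
        violation_counts=counts,
    )
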