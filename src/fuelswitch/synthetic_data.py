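"""Synthetic graded-treadmill experiment with known ground truth.

The original whole-body calorimetry measurements behind this analysis (rat
graded treadmill running, speed increments every 2 minutes to exhaustion —
high-capacity runners lasting ~50 min, low-capacity runners ~14 min) are not
redistributable, so every input the pipeline needs is generated here from a
prescribed physiology with a known parameterization:

* **boundary fluxes** — O2 uptake and CO2 output as saturating ramps, with
  carbohydrate and fatty-acid uptakes derived from a prescribed respiratory
  quotient trajectory through indirect-calorimetry stoichiometry (glucose:
  6 O2 -> 6 CO2; palmitate: 23 O2 -> 16 CO2; glycolytic lactate export is
  O2-neutral), so the four series close elementally when noise is zero;
* **ground-truth activity pairs** — the low-capacity phenotype is the
  high-capacity activity vector with all mitochondrial activities halved and
  the fatty-acid transport steps (CD36/FAT, CPT1, the translocase, CPT2)
  reduced a further 5-fold;
* **observation sets** — gas fluxes, plasma lactate and RQ at step times plus
  the six total acyl-carnitine pools at biopsy times (0 and 10 min for both
  phenotypes, plus 45 min for the high-capacity one), with seeded Gaussian
  noise and attached variances.

Flux magnitudes are whole-body molar rates for a running rat: resting O2
uptake ~0.9 mmol/min/kg rising ~5-fold at peak.  Every generator output is a
pure function of its specification and seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cba import BoundaryFluxSeries
from .kinetics import SolverOptions
from .network import MetabolicNetwork, fa_transport_members, mitochondrial_members

__all__ = [
    "ProtocolSpec",
    "GroundTruth",
    "HCR_LIKE",
    "LCR_LIKE",
    "resting_boundary",
    "make_boundary_series",
    "genotype_factor_map",
    "make_ground_truth_pair",
    "make_observations",
]

#: resting whole-body O2 uptake, mol/min/kg body mass
RESTING_JO2 = 9.0e-4

#: resting respiratory quotient (mixed fuel)
RESTING_RQ = 0.80

#: fraction of glucose uptake routed to lactate export at rest
RESTING_LACTATE_FRACTION = 0.10


@dataclass(frozen=True)
class ProtocolSpec:
    """Graded-treadmill protocol shape and noise model.

    The exhaustion time and peak intensity are the genotype-dependent knobs;
    speed (and therefore demand) steps every ``step_interval`` minutes.
    Relative noise SDs default to 3% on gas fluxes, 10% on lactate and 15%
    on carnitine pools, consistent with the spread of repeated whole-animal
    measurements.
    """

    duration: float = 50.0
    step_interval: float = 2.0
    exhaustion_time: float = 50.0
    peak_jo2: float = 4.5e-3
    rest_jo2: float = RESTING_JO2
    rq_rest: float = RESTING_RQ
    rq_peak: float = 0.87
    lactate_fraction_rest: float = RESTING_LACTATE_FRACTION
    lactate_fraction_peak: float = 0.25
    noise_gas: float = 0.03
    noise_lactate: float = 0.10
    noise_carnitine: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.duration / self.step_interval
        if abs(n - round(n)) > 1e-9:
            raise ValueError("step_interval must divide duration")
        for name in ("noise_gas", "noise_lactate", "noise_carnitine"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: canonical protocol shapes: high-capacity runners sustain ~50 min with RQ
#: held in the 0.8-0.9 band; low-capacity runners exhaust at ~14 min with RQ
#: driven toward 1 (carbohydrate-dominated) and a larger anaerobic fraction.
HCR_LIKE = ProtocolSpec(
    duration=50.0, exhaustion_time=50.0, peak_jo2=4.5e-3,
    rq_rest=RESTING_RQ, rq_peak=0.87, lactate_fraction_peak=0.25,
)
LCR_LIKE = ProtocolSpec(
    duration=14.0, exhaustion_time=14.0, peak_jo2=2.7e-3,
    rq_rest=RESTING_RQ, rq_peak=0.995, lactate_fraction_peak=0.45,
)

_SPECS = {"HCR_like": HCR_LIKE, "LCR_like": LCR_LIKE}


def _fuel_split(jo2: np.ndarray, rq: np.ndarray, lactate_fraction: np.ndarray):
    """Invert indirect calorimetry: gas fluxes -> substrate uptakes.

    Oxidative glucose g and palmitate p satisfy 6g + 23p = JO2 and
    6g + 16p = JCO2; a glycolytic stream adds ``lactate_fraction`` of total
    glucose uptake going to lactate (2 lactate per glucose, O2-neutral).
    """
    jco2 = rq * jo2
    p = (jo2 - jco2) / 7.0
    gox = (jo2 - 23.0 * p) / 6.0
    if np.any(gox < -1e-15) or np.any(p < -1e-15):
        raise ValueError("RQ trajectory outside the glucose/palmitate fan")
    gox = np.maximum(gox, 0.0)
    glac = gox * lactate_fraction / np.maximum(1.0 - lactate_fraction, 1e-9)
    carb = gox + glac
    lactate_out = 2.0 * glac
    return carb, p, jco2, lactate_out


def _saturating_ramp(t: np.ndarray, t_exhaust: float) -> np.ndarray:
    """0 -> 1 saturating workload profile with plateau near exhaustion."""
    tau = 0.35 * t_exhaust
    return (1.0 - np.exp(-t / tau)) / (1.0 - np.exp(-t_exhaust / tau))


def resting_boundary(spec: ProtocolSpec = HCR_LIKE) -> dict[str, float]:
    """Resting (t = 0) boundary fluxes, exactly elementally closed."""
    jo2 = np.array([spec.rest_jo2])
    rq = np.array([spec.rq_rest])
    lf = np.array([spec.lactate_fraction_rest])
    carb, fa, jco2, lac = _fuel_split(jo2, rq, lf)
    return {
        "jo2": float(jo2[0]), "jco2": float(jco2[0]), "carb": float(carb[0]),
        "fa": float(fa[0]), "lactate": float(lac[0]),
    }


def make_boundary_series(
    spec: ProtocolSpec,
    genotype: str | None = None,
) -> BoundaryFluxSeries:
    """Graded-exercise boundary-flux time courses for one phenotype.

    ``genotype`` (``"HCR_like"`` / ``"LCR_like"``) selects a canonical spec;
    otherwise the supplied spec is used as-is.  With ``noise = 0`` the four
    series satisfy the calorimetric closure identities exactly at every time
    point; noise is truncated Gaussian (values never go negative).
    """
    if genotype is not None:
        spec = _SPECS[genotype]
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + 1e-9, spec.step_interval)
    ramp = _saturating_ramp(t, spec.exhaustion_time)
    jo2 = spec.rest_jo2 + (spec.peak_jo2 - spec.rest_jo2) * ramp
    rq = spec.rq_rest + (spec.rq_peak - spec.rq_rest) * ramp
    lf = spec.lactate_fraction_rest + (
        spec.lactate_fraction_peak - spec.lactate_fraction_rest
    ) * ramp
    carb, fa, jco2, lactate = _fuel_split(jo2, rq, lf)

    def noisy(x: np.ndarray, rel: float) -> np.ndarray:
        if rel == 0:
            return x
        return np.maximum(x * (1.0 + rel * rng.standard_normal(x.shape)), 0.0)

    variance = {
        "jo2": (spec.noise_gas * jo2) ** 2 + 1e-30,
        "jco2": (spec.noise_gas * jco2) ** 2 + 1e-30,
        "carb": (spec.noise_gas * carb) ** 2 + 1e-30,
        "fa": (spec.noise_gas * fa) ** 2 + 1e-30,
    }
    return BoundaryFluxSeries(
        times=t,
        jo2=noisy(jo2, spec.noise_gas),
        jco2=noisy(jco2, spec.noise_gas),
        carb=noisy(carb, spec.noise_gas),
        fa=noisy(fa, spec.noise_gas),
        lactate=noisy(lactate, spec.noise_lactate),
        variance=variance,
    )


# ----------------------------------------------------------------------
# Ground truth
# ----------------------------------------------------------------------


@dataclass
class GroundTruth:
    """A generating parameterization: base activities, capacity factors, state.

    ``X_true`` holds the 86 adjustable base activities; ``factors`` are the
    per-reaction capacity factors derived from the genotype transform (the
    effective exercise activity of reaction k is proportional to
    ``X_true[k] * factors[k]``, so the between-phenotype exercise-activity
    ratio is the reciprocal factor ratio).
    """

    X_true: dict[str, float]
    conc0: dict[str, float]
    factors: dict[str, float] = field(default_factory=dict)
    genotype_transform: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def genotype_factor_map(
    net: MetabolicNetwork,
    mito_fraction: float = 1.0,
    fa_transport_factor: float = 1.0,
    extras: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Per-reaction capacity factors for a phenotype transform.

    Every mitochondrial reaction is scaled by ``mito_fraction`` and the FA
    transport steps (CD36/FAT, CPT1, the translocase, CPT2) are divided by a
    further ``fa_transport_factor``; ``extras`` multiply on top (e.g.
    per-acyl-CoA-dehydrogenase reductions).
    """
    mito = set(mitochondrial_members(net))
    fat = set(fa_transport_members(net))
    out = {}
    for rxn in net.reactions:
        f = 1.0
        if rxn.id in mito:
            f *= mito_fraction
        if rxn.id in fat:
            f /= fa_transport_factor
        if extras:
            f *= extras.get(rxn.id, 1.0)
        out[rxn.id] = f
    return out


def make_ground_truth_pair(
    net: MetabolicNetwork,
    conc0: Mapping[str, float],
    X_base: Mapping[str, float],
    mito_fraction: float = 0.5,
    fa_transport_factor: float = 5.0,
    acad_factors: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[GroundTruth, GroundTruth]:
    """Paired phenotype parameterizations from one base activity vector.

    The low-capacity truth is the high-capacity truth with every
    mitochondrial capacity multiplied by ``mito_fraction`` and the FA
    transport steps reduced a further ``fa_transport_factor``-fold (so a
    transport step's exercise-activity ratio between the phenotypes is
    ``fa_transport_factor / mito_fraction``); optional per-dehydrogenase
    extras multiply on top.  Applying the recorded transform to the first
    truth reproduces the second exactly.
    """
    transform = {"mito_fraction": mito_fraction, "fa_transport_factor": fa_transport_factor}
    if acad_factors:
        for rid, f in acad_factors.items():
            transform[f"extra_{rid}"] = f
    hcr = GroundTruth(
        X_true=dict(X_base), conc0=dict(conc0),
        factors={r.id: 1.0 for r in net.reactions}, seed=seed,
    )
    lcr = GroundTruth(
        X_true=dict(X_base),
        conc0=dict(conc0),
        factors=genotype_factor_map(net, mito_fraction, fa_transport_factor, acad_factors),
        genotype_transform=transform,
        seed=seed,
    )
    return hcr, lcr


# ----------------------------------------------------------------------
# Observations
# ----------------------------------------------------------------------


def make_observations(
    ref,
    truth: GroundTruth,
    demand_curve,
    spec: ProtocolSpec,
    biopsy_times: Sequence[float] = (0.0, 10.0),
    solver_opts: SolverOptions | None = None,
):
    """Forward-simulate a ground truth and sample noisy observations from it.

    The kinetic model runs under the supplied ATP-demand curve to the
    protocol's exhaustion time; gas fluxes, plasma lactate and RQ are
    sampled at the protocol step times and the six total acyl-carnitine
    pools at the biopsy times.  Noise is Gaussian with the spec's relative
    SDs; the attached variances are the true generating variances.

    ``ref`` is a :class:`~fuelswitch.pipeline.ReferenceState`; the truth's
    capacity factors are applied to its activity schedule.

    Returns an :class:`~fuelswitch.fitting.ObservationSet`.

    Raises
    ------
    RuntimeError
        if the forward simulation collapses before the last biopsy time
        (the supplied truth is not viable under the demand).
    """
    from .fitting import ObservationSet
    from .kinetics import DemandProtocol, simulate

    opts = solver_opts or ref.solver_opts
    protocol = DemandProtocol(mode="interpolated_curve", curve=demand_curve)
    schedule = ref.schedule(truth.factors)
    if truth.X_true != ref.X_rest:
        schedule.X_rest = dict(truth.X_true)
    traj = simulate(
        ref.net, truth.conc0, schedule, protocol, (0.0, spec.exhaustion_time),
        opts, model=ref.model,
    )
    min_viable = max(biopsy_times)
    if traj.status == "integration_error" or (
        traj.failure_time is not None and traj.failure_time < min_viable
    ):
        raise RuntimeError(
            f"ground truth not viable: simulation status {traj.status!r} "
            f"at t = {traj.failure_time}"
        )
    rng = np.random.default_rng(truth.seed)
    t_obs = np.arange(0.0, spec.exhaustion_time + 1e-9, spec.step_interval)

    def at(series: np.ndarray, ts: np.ndarray) -> np.ndarray:
        return np.interp(ts, traj.times, series)

    def noisy(x: np.ndarray, rel: float) -> tuple[np.ndarray, np.ndarray]:
        var = (rel * np.abs(x)) ** 2 + 1e-30
        if rel == 0:
            return x.copy(), var
        return x * (1.0 + rel * rng.standard_normal(x.shape)), var

    jo2, v_jo2 = noisy(at(traj.jo2, t_obs), spec.noise_gas)
    jco2, v_jco2 = noisy(at(traj.jco2, t_obs), spec.noise_gas)
    lac, v_lac = noisy(at(traj.plasma_lactate, t_obs), spec.noise_lactate)
    rq = jco2 / np.maximum(jo2, 1e-30)
    rq_true = at(traj.jco2, t_obs) / np.maximum(at(traj.jo2, t_obs), 1e-30)
    # propagated relative variance of a ratio of independent noisy fluxes
    v_rq = rq_true**2 * (v_jco2 / at(traj.jco2, t_obs) ** 2 + v_jo2 / at(traj.jo2, t_obs) ** 2)

    t_biopsy = np.asarray(biopsy_times, dtype=float)
    pools = traj.carnitine_pools()
    biopsies = {}
    for name, series in pools.items():
        val, var = noisy(at(series, t_biopsy), spec.noise_carnitine)
        biopsies[name] = (t_biopsy.copy(), val, var)
    return ObservationSet(
        times=t_obs,
        series={
            "JO2": (jo2, v_jo2),
            "JCO2": (jco2, v_jco2),
            "lactate": (lac, v_lac),
            "RQ": (rq, v_rq),
        },
        biopsies=biopsies,
    )
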