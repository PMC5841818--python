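"""Canonical model assembly: from boundary data to a simulation-ready state.

This module glues the stages together in the order the analysis uses them:

1. solve the resting constraint-based problem — with the inner-membrane
   proton leak taken as a fixed fraction of resting charge pumping — to get
   the resting flux pattern and the leak conductance;
2. take the packaged resting concentration vector, equilibrate the
   zero-flux side pools, and solve the rate law algebraically for the
   resting activities (an exact steady state of the kinetic model);
3. wrap the activities in a demand-tracking :class:`ActivitySchedule`:
   catalytic capacity is mobilized with the imposed work rate (with a
   modest relative reserve, absorbed by the leak), up to the exercise
   headroom ceiling;
4. solve a boundary-flux series per time point and fit the ATP-demand
   polynomial that drives the kinetic protocols.

The resulting :class:`ReferenceState` is the base parameterization every
downstream analysis perturbs: hypothesis fits, ensembles, sensitivity
ranking and capacity scans.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .cba import (
    BoundaryFluxSeries,
    FluxSolution,
    atpase_demand_curve,
    leak_flux_of,
    solve_series,
    solve_timepoint,
)
from .kinetics import (
    LEAK_EXPONENT,
    RESTING_LEAK_FRACTION,
    ActivitySchedule,
    DemandProtocol,
    KineticModel,
    SolverOptions,
    Trajectory,
    equilibrate_side_pools,
    initial_activities,
    simulate,
)
from .network import MetabolicNetwork, load_canonical_network
from .synthetic_data import HCR_LIKE, ProtocolSpec, make_boundary_series, resting_boundary

__all__ = ["ReferenceState", "build_reference_state", "demand_curve_for",
           "transition_spec_for", "run_protocol"]


@dataclass
class ReferenceState:
    """A simulation-ready resting parameterization of the kinetic model."""

    net: MetabolicNetwork
    model: KineticModel
    conc0: dict[str, float]  # resting concentrations (exact steady state)
    X_rest: dict[str, float]  # algebraic resting activities (86 adjustable)
    resting_fluxes: dict[str, float]
    leak_fraction: float
    headroom: float
    gamma: float
    demand_rest: float
    solver_opts: SolverOptions = field(default_factory=SolverOptions.fast)

    def schedule(self, factors: Mapping[str, float] | None = None) -> ActivitySchedule:
        """Demand-tracking activity schedule, optionally rescaled per reaction."""
        sched = ActivitySchedule(
            X_rest=dict(self.X_rest),
            demand_rest=self.demand_rest,
            gamma=self.gamma,
            headroom=self.headroom,
        )
        return sched.scaled(factors) if factors else sched


def build_reference_state(
    net: MetabolicNetwork | None = None,
    headroom: float = 10.0,
    gamma: float = 1.02,
    leak_fraction: float = RESTING_LEAK_FRACTION,
    solver_opts: SolverOptions | None = None,
    spec: ProtocolSpec = HCR_LIKE,
) -> ReferenceState:
    """Construct the canonical resting state of the kinetic model.

    The returned state is an exact steady state at the resting ATP demand;
    its activity schedule provides capacity up to ``headroom`` times the
    resting fluxes as demand rises.
    """
    net = net or load_canonical_network()
    opts = solver_opts or SolverOptions.fast()
    bnd = resting_boundary(spec)
    J, _, status = solve_timepoint(
        net, bnd, lactate_fixed=True, boundary_tolerance=1e-9, leak_fraction=leak_fraction
    )
    if status != "optimal":
        raise RuntimeError(f"resting constraint-based solve failed: {status}")
    fluxes = dict(zip(net.reaction_ids, J))
    conc0 = equilibrate_side_pools(net, net.default_concentrations())
    leak0 = leak_flux_of(net, J, leak_fraction)
    g = leak0 / conc0["dpsi_m"] ** LEAK_EXPONENT if leak_fraction > 0 else 0.0
    model = KineticModel(net, leak_conductance=g)
    X_rest = initial_activities(net, conc0, fluxes, headroom=1.0)
    return ReferenceState(
        net=net,
        model=model,
        conc0=conc0,
        X_rest=X_rest,
        resting_fluxes=fluxes,
        leak_fraction=leak_fraction,
        headroom=headroom,
        gamma=gamma,
        demand_rest=fluxes["ATPASE"],
        solver_opts=opts,
    )


def demand_curve_for(
    ref: ReferenceState,
    spec: ProtocolSpec,
    genotype: str | None = None,
    degree: int = 3,
) -> tuple[Callable, BoundaryFluxSeries, FluxSolution]:
    """Boundary series -> constraint-based series -> ATP-demand interpolant."""
    boundary = make_boundary_series(spec, genotype=genotype)
    # exactly closed (noise-free) series pin the lactate column; noisy series
    # leave lactate export free and rely on the +-2 sigma exchange bands
    noise_free = spec.noise_gas == 0
    sol = solve_series(
        ref.net,
        boundary,
        lactate_fixed=noise_free,
        boundary_tolerance=1e-9 if noise_free else 0.05,
        leak_fraction=ref.leak_fraction,
    )
    demand = atpase_demand_curve(sol, degree=degree)
    return demand, boundary, sol


def transition_spec_for(
    ref: ReferenceState,
    demand_curve: Callable,
    tc: float = 0.15,
    factors: Mapping[str, float] | None = None,
    t_peak: float = 50.0,
):
    """Rest-to-exercise monoexponential transition spec for normalized protocols.

    ``X_exercise`` is the fully mobilized capacity (base activity times
    headroom times the capacity factor); ``%VO2rest`` is the resting share
    of the peak demand, using ATP demand as the intensity proxy.
    """
    from .kinetics import TransitionSpec

    f = dict(factors or {})
    X_ex = {rid: x * ref.headroom * f.get(rid, 1.0) for rid, x in ref.X_rest.items()}
    d_peak = float(demand_curve(t_peak))
    vo2_rest = 100.0 * ref.demand_rest / d_peak
    return TransitionSpec(X_rest=dict(ref.X_rest), X_exercise=X_ex, Tc=tc, vo2_rest=vo2_rest)


def run_protocol(
    ref: ReferenceState,
    demand_curve: Callable,
    t_end: float,
    factors: Mapping[str, float] | None = None,
    solver_opts: SolverOptions | None = None,
) -> Trajectory:
    """Simulate the exercise protocol from the resting state.

    ``factors`` are per-reaction multiplicative activity scalings (genotype
    transforms, hypothesis fits); they apply to the whole demand-tracking
    schedule.
    """
    protocol = DemandProtocol(mode="interpolated_curve", curve=demand_curve)
    return simulate(
        ref.net,
        ref.conc0,
        ref.schedule(factors),
        protocol,
        (0.0, t_end),
        solver_opts or ref.solver_opts,
        model=ref.model,
    )
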