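"""Thermodynamic rate law, ODE system, schedules and fuel-selection readouts."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fuelswitch.constants import RT, WATER_VOLUME_L_PER_KG
from fuelswitch.kinetics import (
    ActivitySchedule,
    DemandProtocol,
    KineticModel,
    SolverOptions,
    TransitionSpec,
    activities_to_array,
    equilibrate_side_pools,
    fuel_fractions,
    initial_activities,
    reaction_flux,
    simulate,
    transition_activities,
)
from fuelswitch.network import Reaction

from conftest import make_species, make_toy


@pytest.fixture(scope="module")
def ab_kinetic_toy():
    """Single reversible A -> B reaction with tunable dG'0 = -RT ln 2."""
    species = [
        make_species("a_e", "extracellular", carbon=1),
        make_species("a", "cytosol", carbon=1),
        make_species("b_m", "mitochondrion", carbon=1),
    ]
    reactions = [
        Reaction("EX_GLC", "supply", {"a_e": 1}, -30.0, True, "exchange"),
        Reaction("TA", "import", {"a_e": -1, "a": 1}, 0.0, False, "glycolysis"),
        Reaction("R1", "A to B", {"a": -1, "b_m": 1}, -RT * np.log(2.0), False, "glycolysis"),
    ]
    return make_toy(species, reactions)


def test_rate_law_worked_example(ab_kinetic_toy):
    """X = 1, unit concentrations, dG'0 = -RT ln 2 gives J = 1 * 2 * (1/2) / 2 = 0.5."""
    conc = {"a_e": 1.0, "a": 1.0, "b_m": 1.0}
    J = reaction_flux(ab_kinetic_toy, conc, {"TA": 0.0, "R1": 1.0, "EX_GLC": 0.0})
    assert J["R1"] == pytest.approx(0.5, abs=1e-12)


def test_rate_law_equilibrium_gives_zero(ab_kinetic_toy):
    # dG' = 0 when [b]/[a] = 2 (Keq = 2)
    conc = {"a_e": 1.0, "a": 1e-3, "b_m": 2e-3}
    J = reaction_flux(ab_kinetic_toy, conc, {"TA": 0.0, "R1": 5.0, "EX_GLC": 0.0})
    assert J["R1"] == pytest.approx(0.0, abs=1e-15)


def test_rate_law_forward_saturation(ab_kinetic_toy):
    """As dG' -> -inf the flux approaches X * Ct (denominator -> 1)."""
    conc = {"a_e": 1.0, "a": 1.0, "b_m": 1e-30}
    J = reaction_flux(ab_kinetic_toy, conc, {"TA": 0.0, "R1": 3.0, "EX_GLC": 0.0})
    ct = 1.0 + 1e-30
    assert J["R1"] == pytest.approx(3.0 * ct, rel=1e-9)


@settings(max_examples=60, deadline=None)
@given(
    la=st.floats(-12, 2), lb=st.floats(-12, 2), x=st.floats(0.01, 100.0)
)
def test_rate_law_sign_opposes_free_energy(ab_kinetic_toy, la, lb, x):
    """sign(J) = -sign(dG') for any concentrations and activity."""
    from fuelswitch.thermo import delta_g_prime

    conc = {"a_e": 1.0, "a": float(np.exp(la)), "b_m": float(np.exp(lb))}
    J = reaction_flux(ab_kinetic_toy, conc, {"TA": 0.0, "R1": x, "EX_GLC": 0.0})
    dg = delta_g_prime(ab_kinetic_toy, conc)[ab_kinetic_toy.reaction_index("R1")]
    if abs(dg) < 1e-12:
        assert abs(J["R1"]) < 1e-9
    else:
        assert np.sign(J["R1"]) == -np.sign(dg)


def test_rhs_zero_activity_is_fixed_point(ab_kinetic_toy):
    model = KineticModel(ab_kinetic_toy, clamped=("a_e",))
    c = model.conc_array({"a_e": 1e-3, "a": 1e-3, "b_m": 1e-3})
    d = model.rhs(0.0, c, np.zeros(3), None, SolverOptions())
    np.testing.assert_allclose(d, 0.0, atol=1e-30)


def test_rhs_partition_volume_ratio(ab_kinetic_toy):
    """A (cytosol) -> B (mitochondrion): |dB/dt| / |dA/dt| = 0.75 / 0.05 = 15."""
    model = KineticModel(ab_kinetic_toy, clamped=("a_e",))
    conc = {"a_e": 1.0, "a": 1.0, "b_m": 1e-6}
    c = model.conc_array(conc)
    X = activities_to_array(ab_kinetic_toy, {"TA": 0.0, "R1": 1.0, "EX_GLC": 0.0})
    d = model.rhs(0.0, c, X, None, SolverOptions())
    ia, ib = ab_kinetic_toy.species_index("a"), ab_kinetic_toy.species_index("b_m")
    assert d[ib] / abs(d[ia]) == pytest.approx(0.75 / 0.05, rel=1e-12)
    assert abs(d[ia]) == pytest.approx(
        abs(model.fluxes(c, X)[2]) / (WATER_VOLUME_L_PER_KG * 0.75), rel=1e-12
    )


def test_transition_activities_closed_forms():
    spec = TransitionSpec(X_rest={"R": 1.0}, X_exercise={"R": 9.0}, Tc=0.1, vo2_rest=20.0)
    assert transition_activities(spec, 20.0)["R"] == pytest.approx(1.0)
    # one transition constant of intensity above rest: 1/e of the gap remains
    at_tc = transition_activities(spec, 20.0 + 1.0 / 0.1)["R"]
    assert at_tc == pytest.approx(9.0 + (1.0 - 9.0) / np.e, rel=1e-12)
    # far above rest the exercise activities are reached
    assert transition_activities(spec, 2000.0)["R"] == pytest.approx(9.0, rel=1e-9)
    with pytest.raises(ValueError):
        transition_activities(spec, 10.0)
    with pytest.raises(ValueError):
        TransitionSpec(X_rest={}, X_exercise={}, Tc=0.0)


@pytest.mark.parametrize(
    "rq, expected", [(0.7, (100.0, 0.0)), (1.0, (0.0, 100.0)), (0.85, (50.0, 50.0))]
)
def test_fuel_fractions(rq, expected):
    fa, cho = fuel_fractions(rq)
    assert fa == pytest.approx(expected[0], abs=1e-9)
    assert cho == pytest.approx(expected[1], abs=1e-9)


def test_fuel_fractions_clips_with_warning():
    with pytest.warns(UserWarning, match="clipping"):
        fa, cho = fuel_fractions(1.3)
    assert (fa, cho) == (0.0, 100.0)


def test_activity_schedule_semantics(ref):
    sched = ref.schedule()
    d0 = ref.demand_rest
    assert sched.activities(0.0) == ref.X_rest  # resting activities exact
    # mobilization tracks demand up to the headroom ceiling
    mid = sched.activities(3.0 * d0)
    s_expected = min(1.0 + ref.gamma * 2.0, ref.headroom)
    assert mid["CS"] == pytest.approx(ref.X_rest["CS"] * s_expected)
    top = sched.activities(100.0 * d0)
    assert top["CS"] == pytest.approx(ref.X_rest["CS"] * ref.headroom)
    # a capacity factor halves the ceiling without touching rest
    half = ref.schedule({"CS": 0.5})
    assert half.activities(0.0)["CS"] == pytest.approx(ref.X_rest["CS"])
    assert half.activities(100.0 * d0)["CS"] == pytest.approx(
        ref.X_rest["CS"] * ref.headroom * 0.5
    )


def test_resting_state_is_steady(ref):
    """At resting demand the assembled reference state barely drifts in 50 min."""
    protocol = DemandProtocol(mode="constant", level=ref.demand_rest)
    traj = simulate(
        ref.net, ref.conc0, ref.schedule(), protocol, (0.0, 50.0),
        ref.solver_opts, model=ref.model,
    )
    assert traj.status == "ok"
    rel = np.abs(traj.conc[-1] - traj.conc[0]) / np.maximum(traj.conc[0], 1e-30)
    assert rel.max() < 0.01
    assert traj.rq[-1] == pytest.approx(traj.rq[0], rel=0.01)


def test_initial_activities_reproduce_resting_fluxes(ref):
    X = initial_activities(ref.net, ref.conc0, ref.resting_fluxes, headroom=1.0)
    model = ref.model
    J = model.fluxes(
        model.conc_array(ref.conc0),
        activities_to_array(ref.net, X),
        ref.resting_fluxes["ATPASE"],
    )
    scale = max(abs(v) for v in ref.resting_fluxes.values())
    for rid, j_ref in ref.resting_fluxes.items():
        k = ref.net.reaction_index(rid)
        if rid.startswith("EX_") and rid != "EX_LAC":
            continue  # exchanges act on clamped species
        if rid == "ATPASE":
            # the driven demand carries the smooth ATP-floor attenuation
            assert J[k] == pytest.approx(j_ref, rel=1e-3)
            continue
        if abs(j_ref) > 1e-9 * scale:
            assert J[k] == pytest.approx(j_ref, rel=1e-6), rid


def test_initial_activities_reject_infeasible_state(ref):
    conc_bad = dict(ref.conc0)
    # push a flux-carrying reaction against its gradient: saturate cytosolic
    # pyruvate far above its equilibrium with lactate export running forward
    conc_bad["pyr"] = 1.0
    with pytest.raises(ValueError, match="gradient"):
        initial_activities(ref.net, conc_bad, ref.resting_fluxes, headroom=1.0)


def test_moiety_conservation_along_trajectory(ref, hcr_demand):
    """Carnitine and CoA moieties move between pools but their totals persist."""
    from fuelswitch.pipeline import run_protocol

    traj = run_protocol(ref, hcr_demand, 20.0)
    assert traj.status == "ok"
    net = ref.net
    vols = {s.id: ref.model.volumes[net.species_index(s.id)] for s in net.species}

    def moiety_total(members):
        tot = np.zeros(len(traj.times))
        for sid in members:
            tot += traj.conc_of(sid) * vols[sid]
        return tot

    carn = ["carn", "carn_m", "c16carn", "c16carn_m", "c14carn", "c14carn_m",
            "c8carn", "c8carn_m", "c4carn", "c4carn_m", "acarn", "acarn_m"]
    coa = ["coa", "facoa"]
    coa_m = ["coa_m", "accoa_m", "succoa_m"] + [
        f"c{n}{kind}_m" for n in (16, 14, 12, 10, 8, 6, 4)
        for kind in ("coa", "enoyl", "oh", "keto")
    ]
    for members in (carn, coa, coa_m):
        tot = moiety_total(members)
        assert np.max(np.abs(tot - tot[0])) <= 1e-4 * tot[0]


def test_second_law_along_short_trajectory(ref, hcr_demand):
    from fuelswitch.pipeline import run_protocol

    traj = run_protocol(ref, hcr_demand, 10.0)
    dg = traj.delta_g()
    J = traj.fluxes()
    dissipation = J * dg
    scale = np.max(np.abs(J)) * np.max(np.abs(dg))
    assert dissipation.max() <= 1e-9 * scale


def test_demand_protocol_modes():
    assert DemandProtocol(mode="constant", level=2.0).rate(5.0) == 2.0
    ramp = DemandProtocol(mode="linear_ramp", level=1.0, slope=0.5)
    assert ramp.rate(4.0) == pytest.approx(3.0)
    stepped = DemandProtocol(mode="stepped", steps=[(2.0, 1.0), (2.0, 5.0)])
    assert stepped.rate(1.0) == 1.0 and stepped.rate(3.0) == 5.0 and stepped.rate(10.0) == 5.0
    assert DemandProtocol(mode="linear_ramp", level=1.0, slope=-1.0).rate(5.0) == 0.0
    with pytest.raises(ValueError):
        DemandProtocol(mode="bogus").rate(0.0)
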