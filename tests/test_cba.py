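"""Constraint-based flux solves: stoichiometric oracles, loop law, envelopes."""
from itertools import combinations, product

import numpy as np
import pytest

from fuelswitch.cba import (
    BIG,
    BoundaryFluxSeries,
    InfeasibleBoundaryError,
    atpase_demand_curve,
    find_internal_cycles,
    flux_envelope,
    solve_series,
    solve_timepoint,
)
from fuelswitch.network import stoichiometric_matrix
from fuelswitch.synthetic_data import make_boundary_series, resting_boundary

from conftest import toy_boundary


def brute_force_lp(net, boundary, objective="ATPS", tolerance=1e-9):
    """Exhaustive vertex enumeration of {S J = 0, lb <= J <= ub}.

    Vertices are intersections of the equality system with enough active
    bound hyperplanes; feasible vertices are scored on the objective.  Only
    viable for toy networks (<= 10 reactions).
    """
    S = stoichiometric_matrix(net).astype(float)
    n = net.n_reactions
    from fuelswitch.cba import _exchange_bounds

    ex = _exchange_bounds(net, boundary, tolerance, None, False)
    bounds = []
    for rxn in net.reactions:
        bounds.append(ex.get(rxn.id, (0.0, BIG)))
    rank = np.linalg.matrix_rank(S)
    d = n - rank
    k_obj = net.reaction_index(objective) if objective in net.reaction_ids else None
    best_val, best_vertices = -np.inf, []
    for active in combinations(range(n), d):
        for sides in product((0, 1), repeat=d):
            A = [S[i] for i in range(S.shape[0])]
            b = [0.0] * S.shape[0]
            for j, side in zip(active, sides):
                row = np.zeros(n)
                row[j] = 1.0
                A.append(row)
                b.append(bounds[j][side])
            A, b = np.array(A), np.array(b)
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.max(np.abs(A @ sol - b)) > 1e-7:
                continue
            if any(sol[j] < bounds[j][0] - 1e-7 or sol[j] > bounds[j][1] + 1e-7 for j in range(n)):
                continue
            val = sol[k_obj] if k_obj is not None else 0.0
            if val > best_val + 1e-9:
                best_val, best_vertices = val, [sol]
            elif abs(val - best_val) <= 1e-9:
                best_vertices.append(sol)
    return best_val, best_vertices


def test_zero_boundary_gives_zero_flux(net):
    J, obj, status = solve_timepoint(net, toy_boundary())
    assert status == "optimal"
    assert obj == pytest.approx(0.0, abs=1e-12)
    assert np.max(np.abs(J)) == pytest.approx(0.0, abs=1e-10)


def test_pure_glucose_stoichiometry(net):
    """Glucose 1 : O2 6 : CO2 6 drives the oxidative route at unit yield; RQ = 1."""
    J, _, status = solve_timepoint(
        net, toy_boundary(carb=1e-3, jo2=6e-3, jco2=6e-3), boundary_tolerance=1e-9
    )
    assert status == "optimal"
    j = dict(zip(net.reaction_ids, J))
    rq = j["EX_CO2"] / j["EX_O2"]
    assert rq == pytest.approx(1.0, abs=1e-6)
    # stoichiometric ratios through the pathway
    assert j["PDH"] == pytest.approx(2 * j["GLUT"], rel=1e-6)
    assert j["CS"] == pytest.approx(2 * j["GLUT"], rel=1e-6)
    assert j["ACAD_C16"] == pytest.approx(0.0, abs=1e-9)
    assert j["LDH"] == pytest.approx(0.0, abs=1e-9)


def test_pure_palmitate_stoichiometry(net):
    """Palmitate 1 : O2 23 : CO2 16 runs the 7-round spiral; RQ = 16/23."""
    J, _, status = solve_timepoint(
        net, toy_boundary(fa=1e-4, jo2=23e-4, jco2=16e-4), boundary_tolerance=1e-9
    )
    assert status == "optimal"
    j = dict(zip(net.reaction_ids, J))
    assert j["EX_CO2"] / j["EX_O2"] == pytest.approx(16.0 / 23.0, rel=1e-6)
    for n_chain in (16, 14, 12, 10, 8, 6, 4):
        assert j[f"ACAD_C{n_chain}"] == pytest.approx(j["FAT"], rel=1e-6)
    assert j["CS"] == pytest.approx(8 * j["FAT"], rel=1e-6)
    assert j["GLUT"] == pytest.approx(0.0, abs=1e-9)


def test_mass_balance_residual(net):
    J, _, _ = solve_timepoint(net, resting_boundary(), lactate_fixed=True, boundary_tolerance=1e-9)
    S = stoichiometric_matrix(net).astype(float)
    assert np.max(np.abs(S @ J)) <= 1e-9 * max(np.max(np.abs(J)), 1.0)


def test_canonical_network_has_no_internal_cycles(net):
    assert find_internal_cycles(net) == []


def test_toy_vertex_enumeration_oracle(parallel_toy):
    boundary = toy_boundary(carb=1.0, jco2=6.0)
    best_val, vertices = brute_force_lp(parallel_toy, boundary)
    J, obj, status = solve_timepoint(parallel_toy, boundary, boundary_tolerance=1e-9)
    assert status == "optimal"
    # the LP optimum matches the best enumerated vertex objective, and the
    # returned solution lies on the optimal face
    best_val_ref, _ = brute_force_lp(parallel_toy, boundary, tolerance=1e-9)
    assert obj == pytest.approx(best_val_ref, rel=1e-6)


def test_loopless_solution_on_cycle_toy(cycle_toy):
    boundary = toy_boundary(carb=1.0, jco2=1.0)
    assert len(find_internal_cycles(cycle_toy)) == 1
    J, _, status = solve_timepoint(cycle_toy, boundary, boundary_tolerance=1e-9)
    assert status == "optimal"
    j = dict(zip(cycle_toy.reaction_ids, J))
    # the R1/R2 pair must not carry circulating flux: R2 stays at zero
    assert j["R2"] == pytest.approx(0.0, abs=1e-9)
    assert j["R1"] == pytest.approx(1.0, rel=0.05)
    # the MILP route agrees
    J2, _, status2 = solve_timepoint(cycle_toy, boundary, boundary_tolerance=1e-9, loopless="milp")
    assert status2 == "optimal"
    assert J2[cycle_toy.reaction_index("R2")] == pytest.approx(0.0, abs=1e-6)


def test_infeasible_boundary_reports(net):
    with pytest.raises(InfeasibleBoundaryError, match="carbon"):
        solve_timepoint(net, toy_boundary(carb=1e-5, jo2=1e-3, jco2=5e-3), boundary_tolerance=1e-9)


def test_constant_series_identical_solutions(net):
    b = resting_boundary()
    series = BoundaryFluxSeries(
        times=np.array([0.0, 2.0]),
        jo2=np.array([b["jo2"]] * 2), jco2=np.array([b["jco2"]] * 2),
        carb=np.array([b["carb"]] * 2), fa=np.array([b["fa"]] * 2),
        lactate=np.array([b["lactate"]] * 2),
    )
    sol = solve_series(net, series, lactate_fixed=True, boundary_tolerance=1e-9)
    assert sol.status == ["optimal", "optimal"]
    np.testing.assert_allclose(sol.J[0], sol.J[1], atol=1e-12)


def test_monotone_ramp_gives_monotone_oxidative_fluxes(net, hcr_spec_clean):
    boundary = make_boundary_series(hcr_spec_clean)
    sol = solve_series(net, boundary, lactate_fixed=True, boundary_tolerance=1e-9)
    assert all(s == "optimal" for s in sol.status)
    for rid in ("CS", "C34", "ATPS"):
        flux = sol.flux(rid)
        assert np.all(np.diff(flux) > -1e-12), rid


def test_lcr_ramp_has_lower_fa_flux(net, hcr_spec_clean, lcr_spec_clean):
    sol_h = solve_series(net, make_boundary_series(hcr_spec_clean),
                         lactate_fixed=True, boundary_tolerance=1e-9)
    sol_l = solve_series(net, make_boundary_series(lcr_spec_clean),
                         lactate_fixed=True, boundary_tolerance=1e-9)
    # at matched times within the LCR window the fatty-acid spiral carries
    # less flux for the carbohydrate-shifted phenotype
    t_common = sol_l.times[2:]
    f_h = np.interp(t_common, sol_h.times, sol_h.flux("ACAD_C16"))
    f_l = np.interp(t_common, sol_l.times, sol_l.flux("ACAD_C16"))
    assert np.all(f_l < f_h)


def test_variability_envelope_zero_on_unique_optimum(ab_toy):
    boundary = toy_boundary(carb=1.0, jco2=1.0)
    lo, hi = flux_envelope(ab_toy, boundary, mode="variability", boundary_tolerance=1e-9)
    assert np.max(hi - lo) <= 1e-6


def test_envelope_width_on_redundant_pair(parallel_toy):
    boundary = toy_boundary(carb=1.0, jco2=6.0)
    lo, hi = flux_envelope(parallel_toy, boundary, mode="variability", boundary_tolerance=1e-9)
    width = dict(zip(parallel_toy.reaction_ids, hi - lo))
    assert width["GLUT"] > 0.5 and width["GLUT2"] > 0.5
    for rid in ("EX_GLC", "ATPS", "EX_CO2"):
        assert width[rid] <= 0.15  # only the exchange slack band
    # the stochastic multi-start mode stays inside the deterministic hull
    lo2, hi2 = flux_envelope(parallel_toy, boundary, n_starts=20, seed=1,
                             mode="multistart", boundary_tolerance=1e-9)
    assert np.all(lo2 >= lo - 1e-7) and np.all(hi2 <= hi + 1e-7)


def test_atpase_demand_curve_shapes(net):
    rids = list(net.reaction_ids)
    k = rids.index("ATPASE")
    times = np.array([0.0, 10.0, 20.0, 30.0])
    J = np.zeros((4, len(rids)))
    J[:, k] = 2.0
    sol_const = type("S", (), {})()
    from fuelswitch.cba import FluxSolution

    sol = FluxSolution(reaction_ids=rids, times=times, J=J,
                       objective_value=np.ones(4), status=["optimal"] * 4)
    demand = atpase_demand_curve(sol, degree=2)
    assert demand(12.3) == pytest.approx(2.0, rel=1e-9)

    J[:, k] = 1.0 + 0.5 * times
    sol_lin = FluxSolution(reaction_ids=rids, times=times, J=J,
                           objective_value=np.ones(4), status=["optimal"] * 4)
    demand_lin = atpase_demand_curve(sol_lin, degree=1)
    assert demand_lin(17.0) == pytest.approx(1.0 + 0.5 * 17.0, rel=1e-9)

    with pytest.raises(ValueError, match="degree"):
        atpase_demand_curve(sol_lin, degree=4)


def test_demand_interpolant_tracks_solved_points(net, ref, hcr_spec_clean):
    boundary = make_boundary_series(hcr_spec_clean)
    sol = solve_series(net, boundary, lactate_fixed=True, boundary_tolerance=1e-9,
                       leak_fraction=ref.leak_fraction)
    demand = atpase_demand_curve(sol)
    fitted = demand(sol.times)
    solved = sol.flux("ATPASE")
    assert np.all(np.abs(fitted - solved) <= 0.05 * np.max(solved))
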