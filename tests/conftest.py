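"""Shared fixtures: the canonical network, the reference state, toy networks."""
from __future__ import annotations

from dataclasses import replace

import pytest

from fuelswitch.network import Compartment, MetabolicNetwork, Reaction, Species, load_canonical_network
from fuelswitch.pipeline import build_reference_state, demand_curve_for
from fuelswitch.synthetic_data import HCR_LIKE, LCR_LIKE

STD_COMPARTMENTS = [
    Compartment("extracellular", 0.2),
    Compartment("cytosol", 0.75),
    Compartment("mitochondrion", 0.05),
]


def make_species(sid, compartment, carbon=0, lo=1e-9, hi=1.0, default=1e-3):
    return Species(
        id=sid, name=sid, compartment=compartment, carbon_count=carbon,
        conc_lower=lo, conc_upper=hi, conc_default=default,
    )


def make_toy(species, reactions, name="toy") -> MetabolicNetwork:
    return MetabolicNetwork(
        compartments=list(STD_COMPARTMENTS), species=species, reactions=reactions, name=name
    )


@pytest.fixture(scope="session")
def net():
    return load_canonical_network()


@pytest.fixture(scope="session")
def ref():
    return build_reference_state()


@pytest.fixture(scope="session")
def hcr_spec_clean():
    return replace(HCR_LIKE, noise_gas=0.0, noise_lactate=0.0, noise_carnitine=0.0)


@pytest.fixture(scope="session")
def lcr_spec_clean():
    return replace(LCR_LIKE, noise_gas=0.0, noise_lactate=0.0, noise_carnitine=0.0)


@pytest.fixture(scope="session")
def hcr_demand(ref, hcr_spec_clean):
    demand, boundary, sol = demand_curve_for(ref, hcr_spec_clean)
    return demand


@pytest.fixture(scope="session")
def lcr_demand(ref, lcr_spec_clean):
    demand, boundary, sol = demand_curve_for(ref, lcr_spec_clean)
    return demand


@pytest.fixture(scope="session")
def ab_toy():
    """Two-species toy: boundary-fed A converts to B which is exported."""
    species = [
        make_species("a_e", "extracellular", carbon=1),
        make_species("a", "cytosol", carbon=1),
        make_species("b", "cytosol", carbon=1),
        make_species("b_e", "extracellular", carbon=1),
    ]
    reactions = [
        Reaction("EX_GLC", "A supply", {"a_e": 1}, -30.0, True, "exchange"),
        Reaction("TA", "A import", {"a_e": -1, "a": 1}, 0.0, False, "glycolysis"),
        Reaction("R1", "A to B", {"a": -1, "b": 1}, -5.0, False, "glycolysis"),
        Reaction("TB", "B export", {"b": -1, "b_e": 1}, 0.0, False, "glycolysis"),
        Reaction("EX_CO2", "B removal", {"b_e": -1}, -30.0, True, "exchange"),
    ]
    return make_toy(species, reactions)


@pytest.fixture(scope="session")
def parallel_toy():
    """Glucose-like toy with two redundant internal routes (alternate optima)."""
    species = [
        make_species("glc_e", "extracellular", carbon=6),
        make_species("glc", "cytosol", carbon=6),
        make_species("co2_e", "extracellular", carbon=1),
    ]
    reactions = [
        Reaction("EX_GLC", "glucose supply", {"glc_e": 1}, -30.0, True, "exchange"),
        Reaction("GLUT", "uptake route A", {"glc_e": -1, "glc": 1}, 0.0, False, "glycolysis"),
        Reaction("GLUT2", "uptake route B", {"glc_e": -1, "glc": 1}, 0.0, False, "glycolysis"),
        Reaction("ATPS", "oxidation", {"glc": -1, "co2_e": 6}, -100.0, False, "oxphos"),
        Reaction("EX_CO2", "CO2 out", {"co2_e": -1}, -30.0, True, "exchange"),
    ]
    return make_toy(species, reactions)


@pytest.fixture(scope="session")
def cycle_toy():
    """Toy containing a genuine internal stoichiometric cycle (R1 + R2back)."""
    species = [
        make_species("a_e", "extracellular", carbon=1),
        make_species("a", "cytosol", carbon=1),
        make_species("b", "cytosol", carbon=1),
        make_species("b_e", "extracellular", carbon=1),
    ]
    reactions = [
        Reaction("EX_GLC", "A supply", {"a_e": 1}, -30.0, True, "exchange"),
        Reaction("TA", "A import", {"a_e": -1, "a": 1}, 0.0, False, "glycolysis"),
        Reaction("R1", "A to B", {"a": -1, "b": 1}, -5.0, False, "glycolysis"),
        Reaction("R2", "B to A", {"b": -1, "a": 1}, 5.0, False, "glycolysis"),
        Reaction("TB", "B export", {"b": -1, "b_e": 1}, 0.0, False, "glycolysis"),
        Reaction("EX_CO2", "B removal", {"b_e": -1}, -30.0, True, "exchange"),
    ]
    return make_toy(species, reactions)


def toy_boundary(carb=0.0, fa=0.0, jo2=0.0, jco2=0.0, **extra):
    out = {"carb": carb, "fa": fa, "jo2": jo2, "jco2": jco2}
    out.update(extra)
    return out
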