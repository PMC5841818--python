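"""Structure and invariants of the canonical catabolic network."""
import json

import numpy as np
import pytest

from fuelswitch.network import (
    NetworkSchemaError,
    NetworkValidationError,
    PATHWAY_TAGS,
    canonical_network_path,
    load_network,
    mitochondrial_members,
    pathway_members,
    save_network,
    stoichiometric_matrix,
)

from conftest import make_species, make_toy
from fuelswitch.network import Reaction


def test_canonical_counts_and_shape(net):
    assert net.n_species == 98
    assert net.n_reactions == 87
    S = stoichiometric_matrix(net)
    assert S.shape == (98, 87)
    assert S.dtype == np.int64


def test_compartment_volume_fractions(net):
    vf = {c.id: c.volume_fraction for c in net.compartments}
    assert vf == {"extracellular": 0.2, "cytosol": 0.75, "mitochondrion": 0.05}
    assert sum(vf.values()) == pytest.approx(1.0)


def test_tca_and_exchange_membership(net):
    assert set(pathway_members(net, "tca")) == {
        "CS", "ACO", "IDH", "AKGDH", "SCS", "SDH", "FUM", "MDH"
    }
    exchange = pathway_members(net, "exchange")
    assert len(exchange) == 6
    assert set(exchange) == {"EX_GLC", "EX_FA", "EX_O2", "EX_LAC", "EX_CO2", "EX_H2O"}
    assert all(net.get_reaction(r).is_boundary for r in exchange)


def test_pathway_union_covers_all_reactions(net):
    seen = []
    for tag in PATHWAY_TAGS:
        seen.extend(pathway_members(net, tag))
    assert len(seen) == 87
    assert len(set(seen)) == 87
    with pytest.raises(ValueError):
        pathway_members(net, "nonsense")


def test_beta_oxidation_spiral_structure(net):
    """Seven rounds (C16 down to C4 in 2-carbon steps) of four enzymatic steps."""
    for n in (16, 14, 12, 10, 8, 6, 4):
        for step in ("ACAD", "ECH", "HACD", "KAT"):
            rid = f"{step}_C{n}"
            assert rid in net.reaction_ids, rid
    # the final thiolysis yields two acetyl units
    assert net.get_reaction("KAT_C4").stoichiometry["accoa_m"] == 2


def test_carbon_conservation_every_internal_reaction(net):
    carbon = {s.id: s.carbon_count for s in net.species}
    S = stoichiometric_matrix(net)
    w = np.array([carbon[s] for s in net.species_ids])
    for k, rxn in enumerate(net.reactions):
        total = int(w @ S[:, k])
        if rxn.is_boundary:
            continue
        assert total == 0, f"{rxn.id} carbon-imbalanced by {total}"


def test_suffix_convention(net):
    for s in net.species:
        if s.compartment == "extracellular":
            assert s.id.endswith("_e")
        elif s.compartment == "mitochondrion":
            assert s.id.endswith("_m")
        else:
            assert not (s.id.endswith("_e") or s.id.endswith("_m"))


def test_adjustable_activities_exclude_demand(net):
    non_demand = [r.id for r in net.reactions if r.id != "ATPASE"]
    assert len(non_demand) == 86


def test_round_trip_serialization(net, tmp_path):
    path = tmp_path / "roundtrip.json"
    save_network(net, path)
    again = load_network(path)
    assert again.species_ids == net.species_ids
    assert again.reaction_ids == net.reaction_ids
    for a, b in zip(net.reactions, again.reactions):
        assert a.stoichiometry == b.stoichiometry
        assert a.dG0_prime == b.dG0_prime
        assert a.pathway_tag == b.pathway_tag
    for a, b in zip(net.species, again.species):
        assert (a.conc_lower, a.conc_upper, a.conc_default) == (
            b.conc_lower, b.conc_upper, b.conc_default
        )


def test_toy_two_species_matrix(ab_toy):
    S = stoichiometric_matrix(ab_toy)
    k = ab_toy.reaction_index("R1")
    col = S[:, k]
    assert col[ab_toy.species_index("a")] == -1
    assert col[ab_toy.species_index("b")] == 1


def test_missing_species_reference_is_schema_error(tmp_path):
    doc = json.loads(canonical_network_path().read_text())
    doc["reactions"][10]["stoichiometry"]["xyz_m"] = 1
    p = tmp_path / "bad.json"
    p.write_text(json.dumps(doc))
    with pytest.raises(NetworkSchemaError, match="xyz_m"):
        load_network(p)


def test_carbon_imbalance_is_validation_error_naming_reaction(tmp_path):
    doc = json.loads(canonical_network_path().read_text())
    rxn = next(r for r in doc["reactions"] if r["id"] == "PDH")
    rxn["stoichiometry"]["co2_m"] = 2  # breaks carbon balance
    p = tmp_path / "imbalanced.json"
    p.write_text(json.dumps(doc))
    with pytest.raises(NetworkValidationError, match="PDH"):
        load_network(p)


def test_orphan_species_rejected():
    species = [
        make_species("a_e", "extracellular"),
        make_species("lonely", "cytosol"),
    ]
    reactions = [Reaction("EX_GLC", "supply", {"a_e": 1}, 0.0, True, "exchange")]
    with pytest.raises(NetworkValidationError, match="orphan"):
        make_toy(species, reactions)


def test_mitochondrial_membership(net):
    mito = set(mitochondrial_members(net))
    assert "CPT1" in mito  # outer-membrane enzyme, included by convention
    assert "CS" in mito and "C1" in mito and "PCT" in mito
    assert "HK" not in mito and "LDH" not in mito
    assert "ATPASE" not in mito  # the driven load is not scaled with density
    assert not any(net.get_reaction(r).is_boundary for r in mito)
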