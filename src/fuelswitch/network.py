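"""Compartmentalized metabolic network: types, loading, and the stoichiometric matrix.

The canonical network packaged with this library describes whole-body
glucose and palmitate catabolism in three compartments (extracellular,
cytosol, mitochondrion): glycolysis, the glycerol-3-phosphate shuttle,
pyruvate handling, the TCA cycle, fatty-acid activation and the carnitine
shuttle, a seven-round beta-oxidation spiral (C16 down to C4 in two-carbon
steps), acyl-carnitine pool handling, oxidative phosphorylation with an
explicit protonmotive pseudo-species, and the bioenergetic demand reactions.
It has exactly 98 species and 87 reactions, six of which are boundary
(exchange) fluxes.

Conventions
-----------
* reactant coefficients are negative, products positive; a positive flux
  runs a reaction in its written direction;
* species ids carry ``_e`` (extracellular) or ``_m`` (mitochondrial)
  suffixes, cytosolic species have no suffix;
* ``carbon_count`` tracks catabolic skeleton carbons only — carrier
  moieties (CoA, NAD, FAD, Q, adenine nucleotides, carnitine, creatine)
  count zero, which makes per-reaction carbon conservation exact;
* ``dG0_prime`` is the standard transformed reaction free energy at
  298.15 K and pH 7 in kJ/mol.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "Compartment",
    "Species",
    "Reaction",
    "MetabolicNetwork",
    "NetworkSchemaError",
    "NetworkValidationError",
    "PATHWAY_TAGS",
    "canonical_network_path",
    "load_network",
    "load_canonical_network",
    "save_network",
    "stoichiometric_matrix",
    "pathway_members",
    "mitochondrial_members",
    "fao_members",
    "fa_transport_members",
]

PATHWAY_TAGS = (
    "glycolysis",
    "lactate",
    "g3p_shuttle",
    "pyruvate",
    "tca",
    "fa_activation_transport",
    "beta_oxidation",
    "carnitine_handling",
    "oxphos",
    "bioenergetics",
    "exchange",
)

_COMPARTMENT_IDS = ("extracellular", "cytosol", "mitochondrion")
_CANONICAL_VOLUME_FRACTIONS = {"extracellular": 0.2, "cytosol": 0.75, "mitochondrion": 0.05}
_SUFFIX = {"extracellular": "_e", "cytosol": "", "mitochondrion": "_m"}


class NetworkSchemaError(ValueError):
    """The definition file is structurally malformed (missing references, bad enums)."""


class NetworkValidationError(ValueError):
    """The parsed network violates a model invariant (e.g. carbon imbalance)."""


@dataclass(frozen=True)
class Compartment:
    id: str
    volume_fraction: float


@dataclass(frozen=True)
class Species:
    id: str
    name: str
    compartment: str
    carbon_count: int
    conc_lower: float
    conc_upper: float
    conc_default: float

    def __post_init__(self) -> None:
        if self.compartment not in _COMPARTMENT_IDS:
            raise NetworkSchemaError(f"species {self.id!r}: unknown compartment {self.compartment!r}")
        if self.carbon_count < 0:
            raise NetworkValidationError(f"species {self.id!r}: negative carbon count")
        if not (0.0 < self.conc_lower <= self.conc_upper):
            raise NetworkValidationError(
                f"species {self.id!r}: concentration bounds must satisfy 0 < lower <= upper"
            )
        suffix = _SUFFIX[self.compartment]
        if suffix and not self.id.endswith(suffix):
            raise NetworkValidationError(
                f"species {self.id!r}: id must end with {suffix!r} for {self.compartment} species"
            )
        if not suffix and (self.id.endswith("_e") or self.id.endswith("_m")):
            raise NetworkValidationError(f"species {self.id!r}: cytosolic ids carry no suffix")


@dataclass(frozen=True)
class Reaction:
    id: str
    name: str
    stoichiometry: dict[str, int]
    dG0_prime: float
    is_boundary: bool
    pathway_tag: str

    def __post_init__(self) -> None:
        if self.pathway_tag not in PATHWAY_TAGS:
            raise NetworkSchemaError(f"reaction {self.id!r}: unknown pathway tag {self.pathway_tag!r}")
        for sid, coeff in self.stoichiometry.items():
            if coeff == 0 or coeff != int(coeff):
                raise NetworkValidationError(
                    f"reaction {self.id!r}: coefficient for {sid!r} must be a nonzero integer"
                )

    @property
    def substrates(self) -> dict[str, int]:
        """Map species-id -> |mu| for reactants."""
        return {s: -c for s, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, int]:
        """Map species-id -> nu for products."""
        return {s: c for s, c in self.stoichiometry.items() if c > 0}


@dataclass
class MetabolicNetwork:
    compartments: list[Compartment]
    species: list[Species]
    reactions: list[Reaction]
    name: str = "unnamed"
    _species_index: dict[str, int] = field(default_factory=dict, repr=False)
    _reaction_index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._species_index = {s.id: i for i, s in enumerate(self.species)}
        self._reaction_index = {r.id: i for i, r in enumerate(self.reactions)}
        self.validate()

    # -- lookups -------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, sid: str) -> int:
        return self._species_index[sid]

    def reaction_index(self, rid: str) -> int:
        return self._reaction_index[rid]

    def get_species(self, sid: str) -> Species:
        return self.species[self._species_index[sid]]

    def get_reaction(self, rid: str) -> Reaction:
        return self.reactions[self._reaction_index[rid]]

    @property
    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def volume_fraction(self, compartment: str) -> float:
        for c in self.compartments:
            if c.id == compartment:
                return c.volume_fraction
        raise KeyError(compartment)

    @property
    def boundary_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.is_boundary]

    def default_concentrations(self) -> dict[str, float]:
        """Packaged resting concentration vector (molar)."""
        return {s.id: s.conc_default for s in self.species}

    def concentration_bounds(self) -> dict[str, tuple[float, float]]:
        return {s.id: (s.conc_lower, s.conc_upper) for s in self.species}

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if len(self._species_index) != len(self.species):
            raise NetworkValidationError("duplicate species ids")
        if len(self._reaction_index) != len(self.reactions):
            raise NetworkValidationError("duplicate reaction ids")
        if len(self.compartments) != 3:
            raise NetworkValidationError("exactly three compartments are required")
        total_vf = sum(c.volume_fraction for c in self.compartments)
        if abs(total_vf - 1.0) > 1e-9:
            raise NetworkValidationError(f"compartment volume fractions sum to {total_vf}, not 1")
        used: set[str] = set()
        carbon = {s.id: s.carbon_count for s in self.species}
        for rxn in self.reactions:
            for sid in rxn.stoichiometry:
                if sid not in self._species_index:
                    raise NetworkSchemaError(
                        f"reaction {rxn.id!r} references undeclared species {sid!r}"
                    )
                used.add(sid)
            if not rxn.is_boundary:
                balance = sum(c * carbon[sid] for sid, c in rxn.stoichiometry.items())
                if balance != 0:
                    raise NetworkValidationError(
                        f"reaction {rxn.id!r} is carbon-imbalanced (net {balance} C)"
                    )
        orphans = set(self._species_index) - used
        if orphans:
            raise NetworkValidationError(f"orphan species: {sorted(orphans)}")


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def canonical_network_path() -> Path:
    """Path of the packaged canonical network definition file."""
    return Path(resources.files("fuelswitch").joinpath("data/network.json"))  # type: ignore[arg-type]


def load_network(path: str | Path) -> MetabolicNetwork:
    """Load and validate a network definition file (JSON).

    Raises
    ------
    NetworkSchemaError
        on malformed structure or dangling species references.
    NetworkValidationError
        on invariant violations (carbon imbalance, orphans, bad bounds),
        naming the offending reaction or species.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise NetworkSchemaError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("compartments", "species", "reactions"):
        if key not in doc:
            raise NetworkSchemaError(f"{path}: missing top-level key {key!r}")
    compartments = [Compartment(c["id"], float(c["volume_fraction"])) for c in doc["compartments"]]
    species = [
        Species(
            id=s["id"],
            name=s.get("name", s["id"]),
            compartment=s["compartment"],
            carbon_count=int(s["carbon_count"]),
            conc_lower=float(s["conc_lower"]),
            conc_upper=float(s["conc_upper"]),
            conc_default=float(s.get("conc_default", np.sqrt(s["conc_lower"] * s["conc_upper"]))),
        )
        for s in doc["species"]
    ]
    reactions = [
        Reaction(
            id=r["id"],
            name=r.get("name", r["id"]),
            stoichiometry={k: int(v) for k, v in r["stoichiometry"].items()},
            dG0_prime=float(r["dG0_prime"]),
            is_boundary=bool(r["is_boundary"]),
            pathway_tag=r["pathway_tag"],
        )
        for r in doc["reactions"]
    ]
    return MetabolicNetwork(
        compartments=compartments,
        species=species,
        reactions=reactions,
        name=doc.get("name", path.stem),
    )


def load_canonical_network() -> MetabolicNetwork:
    """Load the packaged 98-species / 87-reaction catabolic network."""
    net = load_network(canonical_network_path())
    if net.n_species != 98 or net.n_reactions != 87:
        raise NetworkValidationError(
            f"canonical network must be 98 species x 87 reactions, "
            f"got {net.n_species} x {net.n_reactions}"
        )
    vf = {c.id: c.volume_fraction for c in net.compartments}
    if vf != _CANONICAL_VOLUME_FRACTIONS:
        raise NetworkValidationError(f"canonical volume fractions must be {_CANONICAL_VOLUME_FRACTIONS}")
    return net


def save_network(net: MetabolicNetwork, path: str | Path) -> None:
    """Serialize a network back to the JSON definition format (round-trips)."""
    doc = {
        "name": net.name,
        "compartments": [{"id": c.id, "volume_fraction": c.volume_fraction} for c in net.compartments],
        "species": [
            {
                "id": s.id,
                "name": s.name,
                "compartment": s.compartment,
                "carbon_count": s.carbon_count,
                "conc_default": s.conc_default,
                "conc_lower": s.conc_lower,
                "conc_upper": s.conc_upper,
            }
            for s in net.species
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": r.stoichiometry,
                "dG0_prime": r.dG0_prime,
                "is_boundary": r.is_boundary,
                "pathway_tag": r.pathway_tag,
            }
            for r in net.reactions
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


# ----------------------------------------------------------------------
# Derived structure
# ----------------------------------------------------------------------

def stoichiometric_matrix(net: MetabolicNetwork) -> np.ndarray:
    """Dense signed integer matrix S (n_species x n_reactions).

    Column k is reaction k's stoichiometry in the network's species order.
    """
    S = np.zeros((net.n_species, net.n_reactions), dtype=np.int64)
    for k, rxn in enumerate(net.reactions):
        for sid, coeff in rxn.stoichiometry.items():
            S[net.species_index(sid), k] = coeff
    return S


def pathway_members(net: MetabolicNetwork, tag: str) -> list[str]:
    """Reaction ids carrying a pathway tag; the union over tags is all reactions."""
    if tag not in PATHWAY_TAGS:
        raise ValueError(f"unknown pathway tag {tag!r}; valid: {PATHWAY_TAGS}")
    return [r.id for r in net.reactions if r.pathway_tag == tag]


def mitochondrial_members(net: MetabolicNetwork) -> list[str]:
    """Reactions belonging to the mitochondrial compartment for density scaling.

    Membership: any non-boundary reaction that touches a mitochondrial
    species, plus CPT1 (outer-membrane enzyme written on cytosolic-side
    species).  The ATP-demand reaction is excluded — it is the driven load,
    not part of the organelle.
    """
    mito_species = {s.id for s in net.species if s.compartment == "mitochondrion"}
    out = []
    for r in net.reactions:
        if r.is_boundary or r.id == "ATPASE":
            continue
        if r.id == "CPT1" or any(sid in mito_species for sid in r.stoichiometry):
            out.append(r.id)
    return out


def fao_members(net: MetabolicNetwork) -> list[str]:
    """Fatty-acid oxidation block: activation/transport plus the beta-oxidation spiral."""
    return pathway_members(net, "fa_activation_transport") + pathway_members(net, "beta_oxidation")


def fa_transport_members(net: MetabolicNetwork) -> list[str]:
    """The mitochondrial FA import machinery plus the sarcolemmal FA transporter."""
    return [rid for rid in ("FAT", "CPT1", "PCT", "CPT2") if rid in net._reaction_index]
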