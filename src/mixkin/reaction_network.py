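"""Per-chemical enzymatic pathways as species plus mass-action reactions.

Each chemical carries a small reaction network describing its hepatic
oxidation.  Three variants are supported:

* **type I** — the parent binds one cytochrome (CYP2E1), forming a complex
  that either dissociates or is catalyzed to the primary metabolite
  (benzene -> benzene oxide, toluene -> benzyl alcohol, ...).  Three
  microconstants: k1 (binding), k2 (unbinding), k3 (catalysis).
* **type II** — a second, unspecified lower-affinity cytochrome (CYPX)
  provides a concurrent route; the type I triple is duplicated with primed
  constants (k1' defaulting to k1/10, k2'=k2, k3'=k3).
* **type III** — the primary metabolite competes with its parent for the
  same cytochrome and is additionally cleared by a first-order step with
  constant kh; metabolite-side binding constants default to the parent's.

All rate laws are mass action on liver *amounts* (nmol): the rate of a
reaction is its constant times the product of reactant amounts raised to
their stoichiometries, so k1 carries units min^-1 nmol^-1 and the
first-order constants min^-1.

Pathways round-trip through a structured YAML/JSON file format
(``mixkin-pathway/1``); any non-mass-action rate law in a file is rejected
loudly rather than approximated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError, DomainError, UnsupportedFeatureError

__all__ = [
    "SpeciesSpec",
    "ReactionSpec",
    "MicroconstantSet",
    "ChemicalPathway",
    "build_type1_pathway",
    "build_type2_pathway",
    "build_type3_pathway",
    "mass_action_rate",
    "read_pathway",
    "write_pathway",
]

LOCATIONS = ("circulating", "liver_only")
ROLES = ("parent", "enzyme", "complex", "metabolite")
PATHWAY_FORMAT = "mixkin-pathway/1"


@dataclass(frozen=True)
class SpeciesSpec:
    """One chemical species of a pathway.

    ``location`` distinguishes species transported by the PBPK template
    (``circulating``) from liver-resident ones (``liver_only``); enzymes and
    enzyme complexes are always liver-resident.  ``initial_amount`` is in
    nmol (enzyme initial amounts are overridden by the composer's declared
    totals).
    """

    id: str
    name: str = ""
    location: str = "liver_only"
    role: str = "metabolite"
    initial_amount: float = 0.0

    def __post_init__(self):
        if self.location not in LOCATIONS:
            raise ConfigurationError(f"species {self.id!r}: unknown location {self.location!r}")
        if self.role not in ROLES:
            raise ConfigurationError(f"species {self.id!r}: unknown role {self.role!r}")
        if self.role in ("enzyme", "complex") and self.location != "liver_only":
            raise ConfigurationError(
                f"species {self.id!r}: {self.role} species must be liver_only"
            )
        if self.initial_amount < 0:
            raise ConfigurationError(f"species {self.id!r}: negative initial amount")


@dataclass(frozen=True)
class ReactionSpec:
    """A mass-action reaction: rate = constant * prod(reactant_amount^stoich)."""

    id: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_constant_id: str
    rate_law: str = "mass_action"

    def __post_init__(self):
        if self.rate_law != "mass_action":
            raise UnsupportedFeatureError(
                f"reaction {self.id!r}: unsupported rate law {self.rate_law!r} "
                "(only mass_action is supported)"
            )
        for sid, st in (*self.reactants, *self.products):
            if not (isinstance(st, int) and st > 0):
                raise ConfigurationError(
                    f"reaction {self.id!r}: stoichiometry of {sid!r} must be a positive integer"
                )


# Optional fields stay None when a variant does not use them; validation of
# which constants a variant requires happens in the builders.
@dataclass(frozen=True)
class MicroconstantSet:
    """Rate constants of one pathway.

    k1 in min^-1 nmol^-1; k2, k3, kh in min^-1.  Primed constants (k1p,
    k2p, k3p) belong to the second enzyme of type II pathways; km1..km3 to
    the metabolite branch of type III; kh is the first-order metabolite
    clearance of type III.
    """

    k1: float
    k2: float
    k3: float
    k1p: float | None = None
    k2p: float | None = None
    k3p: float | None = None
    km1: float | None = None
    km2: float | None = None
    km3: float | None = None
    kh: float | None = None

    def __post_init__(self):
        # the core triple must be positive; optional branch constants may be
        # zero, which switches the corresponding branch off (null pathway)
        for name in ("k1", "k2", "k3"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"microconstant {name} must be strictly positive")
        for name, value in self.as_dict().items():
            if value < 0:
                raise ConfigurationError(f"microconstant {name} must be >= 0")

    def as_dict(self) -> dict[str, float]:
        """Mapping of the constants that are set (None entries dropped)."""
        return {k: v for k, v in self.__dict__.items() if v is not None}

    def get(self, constant_id: str) -> float:
        value = self.__dict__.get(constant_id)
        if value is None:
            raise ConfigurationError(f"microconstant {constant_id!r} is not set")
        return value


@dataclass(frozen=True)
class ChemicalPathway:
    """A per-chemical reaction network ready for composition.

    ``shared_enzyme_ids`` declares which enzyme pools the composer must share
    across co-exposed chemicals; exactly one species is the circulating
    parent that the PBPK template transports.
    """

    chemical_id: str
    species: tuple[SpeciesSpec, ...]
    reactions: tuple[ReactionSpec, ...]
    constants: MicroconstantSet
    variant: str = "I"
    shared_enzyme_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.variant not in ("I", "II", "III"):
            raise ConfigurationError(f"unknown pathway variant {self.variant!r}")
        ids = [s.id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"pathway {self.chemical_id}: duplicate species ids")
        known = set(ids)
        for rxn in self.reactions:
            for sid, _ in (*rxn.reactants, *rxn.products):
                if sid not in known:
                    raise ConfigurationError(
                        f"pathway {self.chemical_id}: reaction {rxn.id!r} references "
                        f"unknown species {sid!r}"
                    )
        parents = [s for s in self.species if s.role == "parent" and s.location == "circulating"]
        if len(parents) != 1:
            raise ConfigurationError(
                f"pathway {self.chemical_id}: exactly one circulating parent required, "
                f"found {len(parents)}"
            )
        for eid in self.shared_enzyme_ids:
            if eid not in known:
                raise ConfigurationError(
                    f"pathway {self.chemical_id}: shared enzyme {eid!r} not among species"
                )

    @property
    def parent_id(self) -> str:
        return next(s.id for s in self.species if s.role == "parent")

    def species_by_id(self, sid: str) -> SpeciesSpec:
        return next(s for s in self.species if s.id == sid)


def _require(constants: MicroconstantSet, names: tuple[str, ...], context: str):
    for name in names:
        if getattr(constants, name) is None:
            raise ConfigurationError(f"{context}: required microconstant {name!r} is not set")


def build_type1_pathway(
    chemical_id: str, constants: MicroconstantSet, enzyme_id: str = "CYP2E1"
) -> ChemicalPathway:
    """Single-enzyme oxidation: parent + E <-> complex -> E + metabolite.

    Four species (circulating parent; liver enzyme, complex, metabolite) and
    three reactions governed by k1 (binding), k2 (unbinding), k3 (catalysis).
    The metabolite is a terminal product here: the composer tracks it as
    cumulative production only.
    """
    _require(constants, ("k1", "k2", "k3"), f"type I pathway for {chemical_id}")
    cx = f"{chemical_id}.{enzyme_id}"
    met = f"{chemical_id}_metabolite"
    species = (
        SpeciesSpec(chemical_id, name=chemical_id, location="circulating", role="parent"),
        SpeciesSpec(enzyme_id, name=enzyme_id, role="enzyme"),
        SpeciesSpec(cx, name=f"{chemical_id}-{enzyme_id} complex", role="complex"),
        SpeciesSpec(met, name=f"primary metabolite of {chemical_id}", role="metabolite"),
    )
    reactions = (
        ReactionSpec("bind", ((chemical_id, 1), (enzyme_id, 1)), ((cx, 1),), "k1"),
        ReactionSpec("unbind", ((cx, 1),), ((chemical_id, 1), (enzyme_id, 1)), "k2"),
        ReactionSpec("catalyze", ((cx, 1),), ((enzyme_id, 1), (met, 1)), "k3"),
    )
    return ChemicalPathway(chemical_id, species, reactions, constants, "I", (enzyme_id,))


def build_type2_pathway(
    chemical_id: str,
    constants: MicroconstantSet,
    enzyme_id: str = "CYP2E1",
    second_enzyme_id: str = "CYPX",
) -> ChemicalPathway:
    """Two concurrent cytochromes: the type I triple duplicated for a second enzyme.

    Unset primed constants default to k1p = k1/10, k2p = k2, k3p = k3 — the
    second route behaves as a lower-affinity pathway.  Six species, six
    reactions, both enzyme pools shared.
    """
    if enzyme_id == second_enzyme_id:
        raise ConfigurationError(
            f"type II pathway for {chemical_id}: the two enzymes must differ "
            f"(both are {enzyme_id!r})"
        )
    _require(constants, ("k1", "k2", "k3"), f"type II pathway for {chemical_id}")
    constants = replace(
        constants,
        k1p=constants.k1p if constants.k1p is not None else constants.k1 / 10.0,
        k2p=constants.k2p if constants.k2p is not None else constants.k2,
        k3p=constants.k3p if constants.k3p is not None else constants.k3,
    )
    base = build_type1_pathway(chemical_id, constants, enzyme_id)
    cx2 = f"{chemical_id}.{second_enzyme_id}"
    met = f"{chemical_id}_metabolite"
    species = base.species + (
        SpeciesSpec(second_enzyme_id, name=second_enzyme_id, role="enzyme"),
        SpeciesSpec(cx2, name=f"{chemical_id}-{second_enzyme_id} complex", role="complex"),
    )
    reactions = base.reactions + (
        ReactionSpec("bind2", ((chemical_id, 1), (second_enzyme_id, 1)), ((cx2, 1),), "k1p"),
        ReactionSpec("unbind2", ((cx2, 1),), ((chemical_id, 1), (second_enzyme_id, 1)), "k2p"),
        ReactionSpec("catalyze2", ((cx2, 1),), ((second_enzyme_id, 1), (met, 1)), "k3p"),
    )
    return ChemicalPathway(
        chemical_id, species, reactions, constants, "II", (enzyme_id, second_enzyme_id)
    )


def build_type3_pathway(
    chemical_id: str, constants: MicroconstantSet, enzyme_id: str = "CYP2E1"
) -> ChemicalPathway:
    """Parent/metabolite competition for one cytochrome plus first-order clearance.

    The primary metabolite binds the same enzyme (three more mass-action
    reactions, constants km1..km3 defaulting to the parent's k1..k3) and is
    cleared by a first-order step with constant kh (e.g. benzene oxide ->
    phenol).  kh has no literature default and must be supplied.  Seven rate
    constants in total; the first-order product is a terminal sink.
    """
    _require(constants, ("k1", "k2", "k3"), f"type III pathway for {chemical_id}")
    if constants.kh is None:
        raise ConfigurationError(
            f"type III pathway for {chemical_id}: kh (first-order metabolite "
            "clearance) must be supplied; there is no default"
        )
    constants = replace(
        constants,
        km1=constants.km1 if constants.km1 is not None else constants.k1,
        km2=constants.km2 if constants.km2 is not None else constants.k2,
        km3=constants.km3 if constants.km3 is not None else constants.k3,
    )
    base = build_type1_pathway(chemical_id, constants, enzyme_id)
    met = f"{chemical_id}_metabolite"
    mcx = f"{chemical_id}_metabolite.{enzyme_id}"
    sink = f"{chemical_id}_sink"
    species = base.species + (
        SpeciesSpec(mcx, name=f"metabolite-{enzyme_id} complex", role="complex"),
        SpeciesSpec(sink, name=f"terminal secondary metabolites of {chemical_id}", role="metabolite"),
    )
    reactions = base.reactions + (
        ReactionSpec("met_bind", ((met, 1), (enzyme_id, 1)), ((mcx, 1),), "km1"),
        ReactionSpec("met_unbind", ((mcx, 1),), ((met, 1), (enzyme_id, 1)), "km2"),
        ReactionSpec("met_catalyze", ((mcx, 1),), ((enzyme_id, 1), (sink, 1)), "km3"),
        ReactionSpec("met_clear", ((met, 1),), ((sink, 1),), "kh"),
    )
    return ChemicalPathway(chemical_id, species, reactions, constants, "III", (enzyme_id,))


def mass_action_rate(
    reaction: ReactionSpec,
    amounts: Mapping[str, float],
    constants: MicroconstantSet | Mapping[str, float],
) -> float:
    """Instantaneous rate of one reaction, nmol/min.

    rate = k * prod(amount_i ^ stoich_i) over the reactants; non-negative
    whenever the amounts are.
    """
    k = constants.get(reaction.rate_constant_id)
    if k is None:
        raise ConfigurationError(
            f"rate constant {reaction.rate_constant_id!r} missing for reaction {reaction.id!r}"
        )
    rate = float(k)
    for sid, st in reaction.reactants:
        amount = amounts[sid]
        if amount < 0:
            raise DomainError(f"negative amount for species {sid!r}: {amount}")
        rate *= amount**st
    return rate


# ---------------------------------------------------------------------------
# structured pathway file format (YAML or JSON by extension)

def _pathway_to_dict(pathway: ChemicalPathway) -> dict:
    return {
        "format": PATHWAY_FORMAT,
        "chemical_id": pathway.chemical_id,
        "variant": pathway.variant,
        "shared_enzymes": list(pathway.shared_enzyme_ids),
        "species": [
            {
                "id": s.id,
                "name": s.name,
                "location": s.location,
                "role": s.role,
                "initial_amount": s.initial_amount,
            }
            for s in pathway.species
        ],
        "reactions": [
            {
                "id": r.id,
                "reactants": [[sid, st] for sid, st in r.reactants],
                "products": [[sid, st] for sid, st in r.products],
                "rate_constant": r.rate_constant_id,
                "rate_law": r.rate_law,
            }
            for r in pathway.reactions
        ],
        "constants": pathway.constants.as_dict(),
    }


def write_pathway(pathway: ChemicalPathway, file: str | Path) -> None:
    """Serialize a pathway to the structured YAML/JSON pathway format."""
    path = Path(file)
    doc = _pathway_to_dict(pathway)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def read_pathway(file: str | Path) -> ChemicalPathway:
    """Read a pathway file; rejects any non-mass-action rate law by name."""
    path = Path(file)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict) or doc.get("format") != PATHWAY_FORMAT:
        raise UnsupportedFeatureError(
            f"{path}: not a {PATHWAY_FORMAT} document (format: {doc.get('format') if isinstance(doc, dict) else '?'})"
        )
    for rxn in doc.get("reactions", ()):
        law = rxn.get("rate_law", "mass_action")
        if law != "mass_action":
            raise UnsupportedFeatureError(
                f"reaction {rxn.get('id')!r}: unsupported rate law {law!r}"
            )
    species = tuple(
        SpeciesSpec(
            id=s["id"],
            name=s.get("name", ""),
            location=s.get("location", "liver_only"),
            role=s.get("role", "metabolite"),
            initial_amount=float(s.get("initial_amount", 0.0)),
        )
        for s in doc["species"]
    )
    reactions = tuple(
        ReactionSpec(
            id=r["id"],
            reactants=tuple((sid, int(st)) for sid, st in r["reactants"]),
            products=tuple((sid, int(st)) for sid, st in r["products"]),
            rate_constant_id=r["rate_constant"],
            rate_law=r.get("rate_law", "mass_action"),
        )
        for r in doc["reactions"]
    )
    constants = MicroconstantSet(**{k: float(v) for k, v in doc["constants"].items()})
    return ChemicalPathway(
        chemical_id=doc["chemical_id"],
        species=species,
        reactions=reactions,
        constants=constants,
        variant=doc.get("variant", "I"),
        shared_enzyme_ids=tuple(doc.get("shared_enzymes", ())),
    )
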