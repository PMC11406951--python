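"""Per-organism draft metabolic models and reference-genome selection.

A draft model contains all catalog reactions mapped by the genome's genes
plus every spontaneous catalog reaction.  Stoichiometry is compartment
tagged: ordinary reactions live in the cytosol (``c``); transporters span
the cytosol and the extracellular compartment (``e``).  The biomass
reaction consumes the universal biomass precursors for which the genome
carries at least one producing reaction.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .netgen import OrganismGenome, Reaction, UniversalNetwork

__all__ = [
    "DraftModelError",
    "NoReferenceError",
    "ModelReaction",
    "OrganismModel",
    "build_draft_model",
    "choose_reference_genome",
    "DEFAULT_UPPER",
]

DEFAULT_UPPER = 1000.0  # conventional GEM flux bound magnitude

BIOMASS_ID = "bio1"


class DraftModelError(ValueError):
    """Raised for degenerate genomes that cannot yield a usable draft model."""


class NoReferenceError(ValueError):
    """No publicly available reference genome for a taxon."""


@dataclass
class ModelReaction:
    """A reaction instance with compartment-tagged stoichiometry and bounds.

    Stoichiometry keys are ``(compound_id, compartment)`` pairs.
    """

    id: str
    stoichiometry: dict
    lower: float
    upper: float
    transport: bool = False

    def __post_init__(self):
        if self.lower > self.upper:
            raise DraftModelError(f"reaction {self.id}: lower bound exceeds upper bound")

    @property
    def reversible(self) -> bool:
        return self.lower < 0

    def compound_instances(self) -> set:
        return set(self.stoichiometry)


@dataclass
class OrganismModel:
    model_id: str
    member_label: str
    reactions: dict  # reaction id -> ModelReaction
    biomass_reaction: str
    objective: str
    provenance: str = "reference"  # "reference" | "mag"

    @property
    def compounds(self) -> set:
        """(compound id, compartment) instances referenced by the reactions."""
        out = set()
        for r in self.reactions.values():
            out |= r.compound_instances()
        return out

    def compound_ids(self) -> set:
        """Base compound ids, compartment stripped."""
        return {cid for cid, _ in self.compounds}

    def validate(self) -> None:
        if self.biomass_reaction not in self.reactions:
            raise DraftModelError("biomass reaction missing from model")
        if self.objective not in self.reactions:
            raise DraftModelError("objective reaction missing from model")

    def copy(self) -> "OrganismModel":
        return copy.deepcopy(self)


def _producers_in(reaction: Reaction) -> set:
    """Compounds a catalog reaction can make appear in the cytosol."""
    made = set()
    for cid, coeff in reaction.stoichiometry:
        if reaction.transport:
            made.add(cid)  # importer delivers its compound to the cytosol
        elif coeff > 0 or (reaction.reversible and coeff < 0):
            made.add(cid)
    return made


def _instantiate(reaction: Reaction) -> ModelReaction:
    if reaction.transport:
        (cid, _), = reaction.stoichiometry
        stoich = {(cid, "e"): -1.0, (cid, "c"): 1.0}
        lower, upper = -DEFAULT_UPPER, DEFAULT_UPPER  # transporters run both ways
    else:
        stoich = {(cid, "c"): float(v) for cid, v in reaction.stoichiometry}
        lower = -DEFAULT_UPPER if reaction.reversible else 0.0
        upper = DEFAULT_UPPER
    return ModelReaction(
        id=reaction.id, stoichiometry=stoich, lower=lower, upper=upper,
        transport=reaction.transport,
    )


def build_draft_model(
    genome: OrganismGenome,
    universal: UniversalNetwork,
    member_label: str,
    *,
    provenance: Optional[str] = None,
) -> OrganismModel:
    """Build a draft metabolic model from a genome against the catalog.

    Reactions = genome-mapped reactions plus all spontaneous catalog
    reactions.  A biomass precursor enters the biomass reaction iff the
    model carries at least one reaction able to produce it; a biomass with
    zero precursors is an error (degenerate genome), never a silent
    zero-growth model.
    """
    mapped = genome.reaction_ids()
    if not mapped:
        raise DraftModelError(f"genome {genome.organism_id} maps no reactions")
    unknown = mapped - set(universal.reactions)
    if unknown:
        raise DraftModelError(f"genome maps unknown reactions: {sorted(unknown)[:5]}")

    rids = sorted(mapped | set(universal.spontaneous_reactions()))
    reactions = {rid: _instantiate(universal.reactions[rid]) for rid in rids}

    producible = set()
    for rid in rids:
        producible |= _producers_in(universal.reactions[rid])
    included = [p for p in universal.biomass_precursors if p in producible]
    if not included:
        raise DraftModelError(
            f"genome {genome.organism_id} produces no biomass precursor; "
            "refusing to build a zero-growth model"
        )
    reactions[BIOMASS_ID] = ModelReaction(
        id=BIOMASS_ID,
        stoichiometry={(p, "c"): -1.0 for p in included},
        lower=0.0,
        upper=DEFAULT_UPPER,
    )
    model = OrganismModel(
        model_id=f"{member_label}_model",
        member_label=member_label,
        reactions=reactions,
        biomass_reaction=BIOMASS_ID,
        objective=BIOMASS_ID,
        provenance=provenance if provenance is not None else "reference",
    )
    model.validate()
    return model


def choose_reference_genome(candidates: Sequence[OrganismGenome]) -> OrganismGenome:
    """Pick the candidate with the highest feature count.

    Ties break to the lexicographically smallest organism id so the choice
    is deterministic.  An empty candidate list signals that no publicly
    available reference exists for the taxon.
    """
    if not candidates:
        raise NoReferenceError("no reference genome available")
    return sorted(candidates, key=lambda g: (-g.feature_count, g.organism_id))[0]
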