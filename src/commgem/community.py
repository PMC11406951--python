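"""Compartmentalized community models and census metrics.

Merging places each member's internal compounds and reactions in a uniquely
labeled compartment (``c1``, ``c2``, ...) and rewires the extracellular side
of every member transport reaction onto one shared compartment (``e0``), so
a compound exported by any member can be taken up by any other member that
carries an importer for it.

Census semantics: "total predicted metabolites" counts compound instances
per member model with duplicates kept (a shared-compartment compound is
attributed once per member referencing it); "extracellular" counts distinct
compounds present in the shared compartment; "unique metabolites" counts
distinct base compound ids across all compartments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .draftgem import ModelReaction, OrganismModel

__all__ = [
    "CommunityModel",
    "CensusReport",
    "merge_models",
    "census",
    "saturation_curve",
]

SHARED_COMPARTMENT = "e0"


@dataclass
class CommunityModel:
    members: list  # ordered list of (member_label, OrganismModel)
    reactions: dict  # merged reaction id -> ModelReaction (re-tagged)
    member_compartments: dict  # member_label -> internal compartment label
    objective_reactions: list  # merged ids of member biomass reactions
    shared_compartment: str = SHARED_COMPARTMENT

    @property
    def compounds(self) -> set:
        out = set()
        for r in self.reactions.values():
            out |= r.compound_instances()
        return out

    def compound_ids(self) -> set:
        return {cid for cid, _ in self.compounds}

    def extracellular_ids(self) -> set:
        return {cid for cid, comp in self.compounds if comp == self.shared_compartment}

    def validate(self) -> None:
        labels = [lbl for lbl, _ in self.members]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate member labels")
        comps = list(self.member_compartments.values())
        if len(set(comps)) != len(comps):
            raise ValueError("members share an internal compartment label")


def _retag(reaction: ModelReaction, label: str, internal: str) -> ModelReaction:
    stoich = {}
    for (cid, comp), coeff in reaction.stoichiometry.items():
        newcomp = SHARED_COMPARTMENT if comp == "e" else internal
        stoich[(cid, newcomp)] = coeff
    return ModelReaction(
        id=f"{label}__{reaction.id}",
        stoichiometry=stoich,
        lower=reaction.lower,
        upper=reaction.upper,
        transport=reaction.transport,
    )


def merge_models(models: Sequence[OrganismModel]) -> CommunityModel:
    """Merge member models into one compartmentalized community model.

    Member k's internals go to compartment ``c<k>``; the extracellular side
    of its transporters is rewired to the shared ``e0``.  Member reaction
    counts are preserved (reaction ids are prefixed with the member label).
    """
    if not models:
        raise ValueError("need >= 1 model to merge")
    labels = [m.member_label for m in models]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate member labels: {labels}")

    reactions = {}
    member_compartments = {}
    objective_reactions = []
    for k, model in enumerate(models, start=1):
        internal = f"c{k}"
        member_compartments[model.member_label] = internal
        for rid in sorted(model.reactions):
            merged = _retag(model.reactions[rid], model.member_label, internal)
            reactions[merged.id] = merged
        objective_reactions.append(f"{model.member_label}__{model.biomass_reaction}")

    community = CommunityModel(
        members=[(m.member_label, m) for m in models],
        reactions=reactions,
        member_compartments=member_compartments,
        objective_reactions=objective_reactions,
    )
    community.validate()
    return community


@dataclass
class CensusReport:
    taxa: int
    total_predicted: int
    total_extracellular: int
    unique_metabolites: int
    per_member_counts: dict

    def __post_init__(self):
        if self.unique_metabolites > self.total_predicted:
            raise ValueError("unique_metabolites cannot exceed total_predicted")
        if self.total_extracellular > self.total_predicted:
            raise ValueError("total_extracellular cannot exceed total_predicted")

    def to_dict(self) -> dict:
        return {
            "taxa": self.taxa,
            "total_predicted": self.total_predicted,
            "total_extracellular": self.total_extracellular,
            "unique_metabolites": self.unique_metabolites,
            "per_member_counts": dict(sorted(self.per_member_counts.items())),
        }


def census(community: CommunityModel, *, shared_once: bool = False) -> CensusReport:
    """Compute the three census metrics plus the taxa count.

    With ``shared_once=False`` (default) a shared-compartment compound is
    counted once per exporting/importing member in the total; with
    ``shared_once=True`` the shared compartment is counted once globally --
    both readings of "duplicates not removed" for a shared compartment are
    available.
    """
    per_member = {lbl: len(model.compounds) for lbl, model in community.members}
    if shared_once:
        internal = sum(
            len({k for k in model.compounds if k[1] != "e"})
            for _, model in community.members
        )
        total = internal + len(community.extracellular_ids())
    else:
        total = sum(per_member.values())
    return CensusReport(
        taxa=len(community.members),
        total_predicted=total,
        total_extracellular=len(community.extracellular_ids()),
        unique_metabolites=len(community.compound_ids()),
        per_member_counts=per_member,
    )


def saturation_curve(models: Sequence[OrganismModel]) -> list:
    """Cumulative unique-compound counts over a member ordering.

    ``models`` should be ordered by descending abundance; the k-th entry is
    the number of distinct base compounds over the first k models.
    """
    if not models:
        raise ValueError("need >= 1 model")
    seen = set()
    curve = []
    for m in models:
        seen |= m.compound_ids()
        curve.append(len(seen))
    return curve
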