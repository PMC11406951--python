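"""Input-selection strategies.

Reference-guided selection: mean relative abundance per group with
zero-filled absences, then an inclusive cutoff (species with mean >= cutoff
are selected).  MAG-guided selection: quality tiers (high: >90% complete
and <5% contamination; medium: >=50% complete and <10% contamination),
dereplication by a declared-ancestry identity proxy (or gene-set Jaccard
for file-mode MAGs), and optional normalization to the n most complete
high-quality MAGs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .netgen import AbundanceTable, MagRecord

__all__ = [
    "SelectionResult",
    "mean_relative_abundance",
    "select_by_cutoff",
    "classify_mag_quality",
    "dereplicate_mags",
    "normalize_mag_count",
]


@dataclass
class SelectionResult:
    approach: str  # "reference" | "mag"
    parameters: dict
    taxa_detected: list
    taxa_used: list
    exclusions: list = field(default_factory=list)  # (taxon, reason)

    def __post_init__(self):
        if not set(self.taxa_used) <= set(self.taxa_detected):
            raise ValueError("taxa_used must be a subset of taxa_detected")
        for taxon, reason in self.exclusions:
            if not reason:
                raise ValueError(f"exclusion of {taxon} lacks a reason")

    def exclude(self, taxon: str, reason: str) -> None:
        if not reason:
            raise ValueError("exclusion reason must be non-empty")
        if taxon in self.taxa_used:
            self.taxa_used = [t for t in self.taxa_used if t != taxon]
        self.exclusions.append((taxon, reason))

    def to_dict(self) -> dict:
        return {
            "approach": self.approach,
            "parameters": dict(self.parameters),
            "taxa_detected": list(self.taxa_detected),
            "taxa_used": list(self.taxa_used),
            "exclusions": [list(x) for x in self.exclusions],
        }


def mean_relative_abundance(table: AbundanceTable, group: str) -> dict:
    """Arithmetic mean abundance per species over all samples of a group.

    Species absent from a sample count as zero in that sample (zero-fill).
    """
    if group not in table.groups:
        raise KeyError(f"unknown group {group!r}")
    cols = table.groups[group]
    if not cols:
        raise ValueError(f"group {group!r} has no samples")
    sub = table.data[cols].fillna(0.0)
    return {str(sp): float(v) for sp, v in sub.mean(axis=1).items()}


def select_by_cutoff(means: Mapping[str, float], cutoff: float) -> SelectionResult:
    """Select species with mean relative abundance >= cutoff (inclusive).

    Ordering is deterministic: descending mean, then species id.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    selected = sorted(
        (sp for sp, m in means.items() if m >= cutoff),
        key=lambda sp: (-means[sp], sp),
    )
    return SelectionResult(
        approach="reference",
        parameters={"cutoff": cutoff},
        taxa_detected=list(selected),
        taxa_used=list(selected),
    )


def classify_mag_quality(completeness: float, contamination: float) -> str:
    """Tier a MAG: ``high`` iff completeness > 90 and contamination < 5;
    else ``medium`` iff completeness >= 50 and contamination < 10; else
    ``fail``.  The high-completeness bound is strict."""
    if not 0 <= completeness <= 100:
        raise ValueError("completeness out of [0, 100]")
    if not 0 <= contamination <= 100:
        raise ValueError("contamination out of [0, 100]")
    if completeness > 90 and contamination < 5:
        return "high"
    if completeness >= 50 and contamination < 10:
        return "medium"
    return "fail"


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def dereplicate_mags(
    mags: Sequence[MagRecord],
    identity_threshold: float = 0.99,
    *,
    proxy: str = "ancestry",
) -> list:
    """Collapse near-identical MAGs to one representative per cluster.

    Identity proxy: shared ``source_organism`` (synthetic mode, default) or
    gene-set Jaccard >= threshold (file mode, ``proxy='jaccard'``).  The
    representative is the highest-completeness member (ties: lowest
    contamination, then mag id).
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    if proxy not in ("ancestry", "jaccard"):
        raise ValueError("proxy must be 'ancestry' or 'jaccard'")

    mags = sorted(mags, key=lambda m: m.mag_id)
    clusters = []  # list of lists
    if proxy == "ancestry":
        by_source = {}
        for m in mags:
            by_source.setdefault(m.source_organism, []).append(m)
        clusters = [by_source[k] for k in sorted(by_source)]
    else:
        # single-linkage over pairwise Jaccard of reaction-gene content
        assigned = {}
        for m in mags:
            placed = None
            for ci, cluster in enumerate(clusters):
                if any(
                    _jaccard(m.genome.reaction_ids(), o.genome.reaction_ids())
                    >= identity_threshold
                    for o in cluster
                ):
                    placed = ci
                    break
            if placed is None:
                clusters.append([m])
            else:
                clusters[placed].append(m)

    reps = [
        sorted(c, key=lambda m: (-m.completeness, m.contamination, m.mag_id))[0]
        for c in clusters
    ]
    return sorted(reps, key=lambda m: m.mag_id)


def normalize_mag_count(mags: Sequence[MagRecord], n: int) -> tuple:
    """Take the ``n`` most complete high-quality MAGs.

    Sorts by completeness descending (ties: contamination ascending, then
    mag id).  Returns ``(selected, shortfall)`` where shortfall is the number
    of MAGs missing if fewer than ``n`` high-quality MAGs exist.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    high = [m for m in mags if classify_mag_quality(m.completeness, m.contamination) == "high"]
    high.sort(key=lambda m: (-m.completeness, m.contamination, m.mag_id))
    selected = high[:n]
    return selected, max(0, n - len(selected))
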