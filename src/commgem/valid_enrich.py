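"""Metabolomics validation bookkeeping, Venn complementarity, and pathway
over-representation analysis (cumulative hypergeometric with
Benjamini-Hochberg correction).

The validation arithmetic follows the census bookkeeping: of the unique
predicted metabolites, only those with an external (KEGG-style) id are
mappable ("data loss" is the unmappable fraction); a mappable metabolite is
confirmed when its id -- or any replicate alias -- appears in the
untargeted-metabolomics presence set.  Percentages are reported to two
decimals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from .netgen import MetabolomicsTable, pathway_source

__all__ = [
    "ValidationReport",
    "VennPartition",
    "EnrichmentRecord",
    "EnrichmentResult",
    "to_presence",
    "match_predictions",
    "venn",
    "hypergeom_ora",
    "bh_correct",
    "apply_bh",
    "compare_enrichment",
    "combine_lists",
]


@dataclass
class ValidationReport:
    unique_count: int
    mappable_count: int
    data_loss_pct: float
    confirmed_count: int
    confirmed_pct: float
    confirmed_ids: set = field(default_factory=set)

    @classmethod
    def from_counts(cls, unique_count: int, mappable_count: int, confirmed_count: int,
                    confirmed_ids: Optional[set] = None) -> "ValidationReport":
        if not confirmed_count <= mappable_count <= unique_count:
            raise ValueError("need confirmed <= mappable <= unique")
        data_loss = 100.0 * (unique_count - mappable_count) / unique_count if unique_count else 0.0
        confirmed = 100.0 * confirmed_count / mappable_count if mappable_count else 0.0
        return cls(
            unique_count=unique_count,
            mappable_count=mappable_count,
            data_loss_pct=round(data_loss, 2),
            confirmed_count=confirmed_count,
            confirmed_pct=round(confirmed, 2),
            confirmed_ids=set(confirmed_ids or ()),
        )

    @classmethod
    def from_printed(cls, unique_count: int, data_loss_pct: float,
                     confirmed_count: int) -> "ValidationReport":
        """Rebuild a report from printed summary integers.

        The mappable denominator is recovered as
        ``unique * (1 - data_loss/100)`` and the confirmed percentage as
        ``100 * confirmed / mappable``, rounded to 2 decimals.
        """
        mappable = unique_count * (1.0 - data_loss_pct / 100.0)
        if mappable <= 0:
            raise ValueError("data loss leaves no mappable metabolites")
        return cls(
            unique_count=unique_count,
            mappable_count=int(round(mappable)),
            data_loss_pct=data_loss_pct,
            confirmed_count=confirmed_count,
            confirmed_pct=round(100.0 * confirmed_count / mappable, 2),
        )

    def to_dict(self) -> dict:
        return {
            "unique_count": self.unique_count,
            "mappable_count": self.mappable_count,
            "data_loss_pct": self.data_loss_pct,
            "confirmed_count": self.confirmed_count,
            "confirmed_pct": self.confirmed_pct,
        }


@dataclass
class VennPartition:
    overlap: set
    only_a: set
    only_b: set

    @property
    def overlap_count(self) -> int:
        return len(self.overlap)

    @property
    def only_a_count(self) -> int:
        return len(self.only_a)

    @property
    def only_b_count(self) -> int:
        return len(self.only_b)

    def to_dict(self) -> dict:
        return {
            "overlap": self.overlap_count,
            "only_a": self.only_a_count,
            "only_b": self.only_b_count,
        }


def to_presence(metabolomics: MetabolomicsTable, group: str) -> set:
    """External ids of metabolites present in >= 1 sample of the group.

    A metabolite is present when it has a non-missing, positive abundance in
    at least one of the group's samples.  Replicate ids of present
    metabolites are included as aliases.
    """
    if group not in metabolomics.groups:
        raise KeyError(f"unknown group {group!r}")
    cols = metabolomics.groups[group]
    if not cols:
        raise ValueError(f"group {group!r} has no samples")
    ids = set()
    for row in metabolomics.rows:
        present = any(
            row.abundances.get(s) is not None and row.abundances[s] > 0 for s in cols
        )
        if present and row.external_id is not None:
            ids.add(row.external_id)
            ids.update(row.replicate_ids)
    return ids


def match_predictions(
    unique_ids: Iterable[str],
    id_map: Mapping[str, Optional[str]],
    presence: set,
) -> ValidationReport:
    """Validate a unique-metabolite prediction set against a presence set.

    ``id_map`` maps compound id -> external id (or None/absent when the
    compound has no assigned id).  Confirmation is counted once per external
    id; distinct compounds sharing an external id trigger a warning.
    """
    unique_ids = set(unique_ids)
    mapped = {}
    for cid in sorted(unique_ids):
        ext = id_map.get(cid)
        if ext:
            mapped[cid] = ext
    ext_to_cids = {}
    for cid, ext in mapped.items():
        ext_to_cids.setdefault(ext, []).append(cid)
    dups = {e: c for e, c in ext_to_cids.items() if len(c) > 1}
    if dups:
        warnings.warn(
            f"{len(dups)} external ids map to multiple compounds; counted once by id",
            stacklevel=2,
        )
    confirmed = set(ext_to_cids) & presence
    return ValidationReport.from_counts(
        unique_count=len(unique_ids),
        mappable_count=len(mapped),
        confirmed_count=len(confirmed),
        confirmed_ids=confirmed,
    )


def venn(a: Iterable[str], b: Iterable[str]) -> VennPartition:
    a, b = set(a), set(b)
    return VennPartition(overlap=a & b, only_a=a - b, only_b=b - a)


def combine_lists(a: Iterable[str], b: Iterable[str]) -> set:
    """Merge two prediction lists, removing duplicates (set union)."""
    return set(a) | set(b)


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentRecord:
    pathway_id: str
    source: str
    k: int  # test-set hits in the pathway
    K: int  # pathway size within the background
    n: int  # mapped test-set size
    N: int  # background size
    p_value: float
    q_value: Optional[float] = None


@dataclass
class EnrichmentResult:
    records: list  # of EnrichmentRecord, stable pathway-id order
    unmapped: set  # test ids outside the background, excluded from n

    def p_values(self) -> list:
        return [r.p_value for r in self.records]

    def significant(self, q_threshold: float = 0.05) -> set:
        """Pathways with q strictly below the threshold."""
        if any(r.q_value is None for r in self.records):
            raise ValueError("q-values not computed; call apply_bh first")
        return {r.pathway_id for r in self.records if r.q_value < q_threshold}

    def to_dict(self) -> dict:
        return {
            r.pathway_id: {
                "source": r.source, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                "p": r.p_value, "q": r.q_value,
            }
            for r in self.records
        }


def hypergeom_ora(
    test: Iterable[str],
    background: Iterable[str],
    pathways: Mapping[str, set],
) -> EnrichmentResult:
    """Cumulative hypergeometric over-representation p-values per pathway.

    p = P(X >= k) with X ~ Hypergeometric(N, K, n), where N is the
    background size, K the pathway size within the background, n the mapped
    test-set size and k the test-set hits.  Test ids outside the background
    are excluded from n and reported in ``unmapped``.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    test = set(test)
    unmapped = test - background
    mapped = test & background
    n, N = len(mapped), len(background)
    records = []
    for pid in sorted(pathways):
        members = set(pathways[pid]) & background
        K = len(members)
        k = len(mapped & members)
        # survival function at k-1 gives the inclusive upper tail P(X >= k)
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        records.append(
            EnrichmentRecord(
                pathway_id=pid, source=pathway_source(pid),
                k=k, K=K, n=n, N=N, p_value=p,
            )
        )
    return EnrichmentResult(records=records, unmapped=unmapped)


def bh_correct(pvalues: Sequence[float]) -> list:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending ordering, capped
    at 1.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return [float(x) for x in q]


def apply_bh(result: EnrichmentResult) -> EnrichmentResult:
    """Attach BH q-values to an enrichment result (in place; returned)."""
    qs = bh_correct(result.p_values())
    for rec, q in zip(result.records, qs):
        rec.q_value = q
    return result


def compare_enrichment(
    results_a: EnrichmentResult,
    results_b: EnrichmentResult,
    q_threshold: float = 0.05,
) -> tuple:
    """Compare significant pathway sets (strict q < threshold) of two runs.

    Returns ``(shared, only_a, only_b)`` pathway-id sets.
    """
    universe_a = {r.pathway_id for r in results_a.records}
    universe_b = {r.pathway_id for r in results_b.records}
    if universe_a != universe_b:
        raise ValueError("enrichment results cover different pathway universes")
    sig_a = results_a.significant(q_threshold)
    sig_b = results_b.significant(q_threshold)
    return sig_a & sig_b, sig_a - sig_b, sig_b - sig_a
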