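"""Synthetic data generation: universal reaction networks, organism genomes,
simulated MAGs, relative-abundance tables and untargeted-metabolomics tables.

All generators are seed-deterministic: the same arguments always produce the
same (byte-identical when serialized) output.  Sub-generators derive child
seeds from a global seed via :func:`derive_seed` so individual stages can be
re-run in isolation.

The universal network is a desk-scale stand-in for a global biochemistry
catalog: a set of compounds plus stoichiometric reactions, a designated set
of freely available seed compounds, and an ordered list of biomass precursor
compounds that are guaranteed reachable from the seeds.  Reactions are
partitioned into one ``core`` module (the precursor-producing backbone plus
seed transporters and spontaneous reactions) and a number of accessory
modules; organisms are sampled as core + a subset of accessory modules so
that taxa share a metabolic core and differ in accessory content.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenerationError",
    "Compound",
    "Reaction",
    "UniversalNetwork",
    "OrganismGenome",
    "MagRecord",
    "AbundanceTable",
    "MetaboliteRow",
    "MetabolomicsTable",
    "derive_seed",
    "generate_universal_network",
    "sample_organism_genome",
    "strain_variant",
    "simulate_mag",
    "sample_abundance_table",
    "simulate_metabolomics",
    "generate_pathways",
]


class GenerationError(RuntimeError):
    """Raised when a synthetic artifact cannot be constructed."""


def derive_seed(seed: int, *keys: object) -> int:
    """Derive a deterministic child seed from a global seed and a key path.

    Uses BLAKE2b over the repr of ``(seed, keys)`` so the derivation is
    stable across processes and platforms (independent of PYTHONHASHSEED).
    """
    digest = hashlib.blake2b(repr((int(seed), keys)).encode(), digest_size=8)
    return int.from_bytes(digest.digest(), "big") % (2**32)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Compound:
    id: str
    name: str
    external_id: Optional[str] = None  # KEGG-style "C" + 5 digits, or None


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction.

    ``stoichiometry`` maps compound id -> signed integer coefficient
    (negative = substrate, positive = product).  A transport reaction moves
    a single compound between cytosolic and extracellular roles; its
    stoichiometry names exactly that one compound (the sign is not
    meaningful for transporters -- directionality comes from ``reversible``
    and the compartment tagging applied at model-build time).
    """

    id: str
    stoichiometry: tuple  # tuple of (compound_id, coeff) pairs, sorted
    reversible: bool
    spontaneous: bool = False
    transport: bool = False

    @property
    def stoich(self) -> dict:
        return dict(self.stoichiometry)

    def substrates(self) -> list:
        return sorted(c for c, v in self.stoichiometry if v < 0)

    def products(self) -> list:
        return sorted(c for c, v in self.stoichiometry if v > 0)


def _mkstoich(d: Mapping[str, int]) -> tuple:
    return tuple(sorted(d.items()))


@dataclass
class UniversalNetwork:
    """Global catalog of compounds and reactions from which organisms draw."""

    compounds: dict  # id -> Compound
    reactions: dict  # id -> Reaction
    biomass_precursors: list
    seed_compounds: list
    modules: dict = field(default_factory=dict)  # name -> sorted list of rids

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for cid, _ in rxn.stoichiometry:
                if cid not in self.compounds:
                    raise GenerationError(
                        f"reaction {rxn.id} references unknown compound {cid}"
                    )
            if rxn.transport and len(rxn.stoichiometry) != 1:
                raise GenerationError(
                    f"transport reaction {rxn.id} must reference exactly one compound"
                )
        unreachable = set(self.biomass_precursors) - self.reachable_compounds()
        if unreachable:
            raise GenerationError(f"unreachable biomass precursors: {sorted(unreachable)}")

    def reachable_compounds(self) -> set:
        """Compounds reachable from the seed set by forward hypergraph closure.

        A reaction fires once all of its substrates are reachable, making its
        products reachable (and vice versa for reversible reactions).
        Transporters do not change compound-space reachability.
        """
        reached = set(self.seed_compounds)
        rxns = [r for r in self.reactions.values() if not r.transport]
        changed = True
        while changed:
            changed = False
            for r in rxns:
                subs, prods = r.substrates(), r.products()
                if subs and set(subs) <= reached and not set(prods) <= reached:
                    reached |= set(prods)
                    changed = True
                if r.reversible and prods and set(prods) <= reached and not set(subs) <= reached:
                    reached |= set(subs)
                    changed = True
        return reached

    def spontaneous_reactions(self) -> list:
        return sorted(r.id for r in self.reactions.values() if r.spontaneous)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "compounds": [asdict(c) for c in sorted(self.compounds.values(), key=lambda c: c.id)],
            "reactions": [
                {
                    "id": r.id,
                    "stoichiometry": {c: v for c, v in r.stoichiometry},
                    "reversible": r.reversible,
                    "spontaneous": r.spontaneous,
                    "transport": r.transport,
                }
                for r in sorted(self.reactions.values(), key=lambda r: r.id)
            ],
            "biomass_precursors": list(self.biomass_precursors),
            "seed_compounds": list(self.seed_compounds),
            "modules": {k: list(v) for k, v in sorted(self.modules.items())},
        }

    def to_json(self, path: Optional[str] = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "UniversalNetwork":
        compounds = {c["id"]: Compound(**c) for c in d["compounds"]}
        reactions = {
            r["id"]: Reaction(
                id=r["id"],
                stoichiometry=_mkstoich(r["stoichiometry"]),
                reversible=r["reversible"],
                spontaneous=r["spontaneous"],
                transport=r["transport"],
            )
            for r in d["reactions"]
        }
        return cls(
            compounds=compounds,
            reactions=reactions,
            biomass_precursors=list(d["biomass_precursors"]),
            seed_compounds=list(d["seed_compounds"]),
            modules={k: list(v) for k, v in d.get("modules", {}).items()},
        )

    @classmethod
    def from_json(cls, path: str) -> "UniversalNetwork":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class OrganismGenome:
    """One member's genome: genes mapped one-to-one onto catalog reactions."""

    organism_id: str
    gene_set: set
    gene_reaction_map: dict  # gene id -> reaction id
    feature_count: int
    ancestor_id: str  # species identity; dereplication/strain proxy
    modules: tuple = ()  # module names this genome was assembled from

    def __post_init__(self):
        if self.feature_count != len(self.gene_set):
            raise GenerationError("feature_count must equal |gene_set|")
        if set(self.gene_reaction_map) != set(self.gene_set):
            raise GenerationError("gene_reaction_map keys must equal gene_set")

    def reaction_ids(self) -> set:
        return set(self.gene_reaction_map.values())

    def to_dict(self) -> dict:
        return {
            "organism_id": self.organism_id,
            "ancestor_id": self.ancestor_id,
            "feature_count": self.feature_count,
            "gene_reaction_map": dict(sorted(self.gene_reaction_map.items())),
            "modules": list(self.modules),
        }

    def to_json(self, path: Optional[str] = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "OrganismGenome":
        grm = dict(d["gene_reaction_map"])
        return cls(
            organism_id=d["organism_id"],
            gene_set=set(grm),
            gene_reaction_map=grm,
            feature_count=d["feature_count"],
            ancestor_id=d["ancestor_id"],
            modules=tuple(d.get("modules", ())),
        )


@dataclass
class MagRecord:
    """A simulated metagenome-assembled genome with realized quality stats."""

    mag_id: str
    genome: OrganismGenome
    completeness: float  # realized, percent
    contamination: float  # realized, percent
    source_organism: str


@dataclass
class AbundanceTable:
    """Relative-abundance table (percent), species x samples, grouped."""

    data: pd.DataFrame  # index: species ids, columns: sample ids, values in [0, 100]
    groups: dict  # group label -> list of sample column names

    @property
    def species(self) -> list:
        return list(self.data.index)

    def validate(self, tol: float = 1e-6) -> None:
        if (self.data.values < 0).any():
            raise GenerationError("negative abundance entry")
        sums = self.data.sum(axis=0)
        if not np.allclose(sums, 100.0, atol=tol):
            raise GenerationError(f"sample columns do not sum to 100: {sums.to_dict()}")
        for g, cols in self.groups.items():
            missing = set(cols) - set(self.data.columns)
            if missing:
                raise GenerationError(f"group {g} references unknown samples {missing}")

    def to_metaphlan_tsv(self, path: str) -> None:
        out = self.data.copy()
        out.index = ["k__Bacteria|s__" + s for s in out.index]
        out.index.name = "clade_name"
        out.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def from_metaphlan_tsv(cls, path: str, groups: Optional[dict] = None) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        keep = [i for i in df.index if "s__" in str(i)]
        df = df.loc[keep]
        df.index = [str(i).rsplit("s__", 1)[1] for i in df.index]
        if groups is None:
            groups = {"all": list(df.columns)}
        return cls(data=df, groups=groups)


@dataclass
class MetaboliteRow:
    name: str
    external_id: Optional[str]
    replicate_ids: tuple
    abundances: dict  # sample id -> float or None (missing)


@dataclass
class MetabolomicsTable:
    rows: list  # of MetaboliteRow
    samples: list
    groups: dict  # group label -> list of sample ids

    def validate(self) -> None:
        if not self.samples:
            raise GenerationError("metabolomics table needs >= 1 sample column")
        primary = {}
        for row in self.rows:
            if row.external_id is not None:
                primary.setdefault(row.external_id, row.name)
        for row in self.rows:
            for rid in row.replicate_ids:
                if rid in primary and primary[rid] != row.name:
                    raise GenerationError(
                        f"replicate id {rid} collides with a different metabolite's primary id"
                    )

    def to_tsv(self, path: str) -> None:
        recs = []
        for row in self.rows:
            rec = {
                "name": row.name,
                "external_id": row.external_id or "",
                "replicate_ids": ";".join(row.replicate_ids),
            }
            for s in self.samples:
                v = row.abundances.get(s)
                rec[s] = "" if v is None else f"{v:.6g}"
            recs.append(rec)
        pd.DataFrame(recs).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, groups: Optional[dict] = None) -> "MetabolomicsTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        samples = [c for c in df.columns if c not in ("name", "external_id", "replicate_ids")]
        rows = []
        for _, r in df.iterrows():
            ab = {s: (None if r[s] == "" else float(r[s])) for s in samples}
            reps = tuple(x for x in str(r["replicate_ids"]).split(";") if x)
            rows.append(
                MetaboliteRow(
                    name=r["name"],
                    external_id=r["external_id"] or None,
                    replicate_ids=reps,
                    abundances=ab,
                )
            )
        if groups is None:
            groups = {"all": samples}
        return cls(rows=rows, samples=samples, groups=groups)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_universal_network(
    n_compounds: int,
    n_reactions: int,
    transport_fraction: float,
    seed: int,
    *,
    external_id_rate: float = 0.7,
    n_biomass_precursors: int = 8,
    n_accessory_modules: int = 12,
    max_retries: int = 5,
) -> UniversalNetwork:
    """Generate a connected universal reaction network.

    The network is built so that every biomass precursor is reachable from
    the seed compounds: each non-seed compound receives a dedicated
    "backbone" producing reaction whose substrates are earlier compounds.
    Seed compounds always receive transporter reactions (so that complete
    genomes can import them from the extracellular pool and carry biomass
    flux); additional transporters and random internal reactions fill the
    catalog to exactly ``n_reactions``.

    ``external_id_rate`` controls the fraction of compounds carrying a
    KEGG-style external id; compounds without one are unmappable to
    metabolomics and produce the "data loss" bookkeeping downstream.
    """
    if n_compounds < 10:
        raise ValueError("n_compounds must be >= 10")
    if n_reactions < n_compounds:
        raise ValueError("n_reactions must be >= n_compounds")
    if not 0.0 <= transport_fraction <= 0.5:
        raise ValueError("transport_fraction must be in [0, 0.5]")
    if n_compounds >= 70000:
        raise ValueError("n_compounds must be < 70000 (external-id namespace)")

    rng = np.random.default_rng(derive_seed(seed, "universal"))
    for _attempt in range(max_retries):
        net = _try_generate_network(
            n_compounds,
            n_reactions,
            transport_fraction,
            rng,
            external_id_rate,
            n_biomass_precursors,
            n_accessory_modules,
        )
        if net is not None:
            return net
    raise GenerationError(
        "could not construct a network with all biomass precursors reachable "
        f"after {max_retries} attempts"
    )


def _try_generate_network(
    n_compounds, n_reactions, transport_fraction, rng, external_id_rate,
    n_biomass_precursors, n_accessory_modules,
):
    cids = [f"cpd{i:05d}" for i in range(1, n_compounds + 1)]
    has_ext = rng.random(n_compounds) < external_id_rate
    compounds = {
        cid: Compound(
            id=cid,
            name=f"metabolite_{i + 1}",
            external_id=f"C{i + 1:05d}" if has_ext[i] else None,
        )
        for i, cid in enumerate(cids)
    }
    n_seed = max(3, n_compounds // 20)
    seeds = cids[:n_seed]

    # layout: an "early" compound pool (seeds + shared central metabolism,
    # all of it in the core module) followed by per-module compound
    # territories.  Localizing accessory reactions to territories keeps
    # per-organism compound coverage partial, so unique-metabolite curves
    # rise and then saturate instead of every member touching the whole
    # catalog.
    pool = min(
        max(n_seed + n_biomass_precursors, n_compounds // 6),
        n_compounds,
    )
    territory_cpds = list(rng.permutation(np.arange(pool, n_compounds)))
    territories = [
        [int(x) for x in chunk]
        for chunk in np.array_split(np.array(territory_cpds, dtype=int), n_accessory_modules)
    ]
    module_of_cpd = {}
    for m, terr in enumerate(territories):
        for j in terr:
            module_of_cpd[j] = m

    reactions = {}
    ridx = 0
    module_rids = {m: [] for m in range(n_accessory_modules)}
    core_rids = []

    def next_rid():
        nonlocal ridx
        ridx += 1
        return f"rxn{ridx:05d}"

    def add_reaction(stoich, reversible, spontaneous, transport, module):
        rid = next_rid()
        reactions[rid] = Reaction(
            id=rid, stoichiometry=_mkstoich(stoich), reversible=reversible,
            spontaneous=spontaneous, transport=transport,
        )
        (core_rids if module is None else module_rids[module]).append(rid)
        return rid

    # backbone: one producing reaction per non-seed compound, substrates
    # drawn from the early pool (or the compound's own territory for late
    # compounds), so every compound is reachable from the seeds
    producer = {}
    for i in range(n_seed, n_compounds):
        hi = min(i, pool)
        k = 1 + int(rng.integers(0, min(3, hi)))
        subs = rng.choice(hi, size=k, replace=False)
        stoich = {cids[j]: -1 for j in sorted(subs)}
        stoich[cids[i]] = 1
        early = i < pool
        producer[cids[i]] = add_reaction(
            stoich,
            reversible=bool(rng.random() < 0.2),
            spontaneous=bool(early and rng.random() < 0.1),
            transport=False,
            module=None if early else module_of_cpd[i],
        )

    # transporters: one per seed compound always (feasibility guarantee),
    # then extras over territory compounds up to the transport fraction
    n_transport = max(int(round(transport_fraction * n_reactions)), n_seed)
    n_transport = min(n_transport, n_compounds)
    for cid in seeds:
        add_reaction({cid: 1}, reversible=True, spontaneous=False, transport=True, module=None)
    extra_t = min(n_transport - n_seed, n_compounds - n_seed)
    if extra_t > 0:
        others = rng.choice(np.arange(n_seed, n_compounds), size=extra_t, replace=False)
        for j in sorted(int(x) for x in others):
            if len(reactions) >= n_reactions:
                break
            add_reaction(
                {cids[j]: 1}, reversible=True, spontaneous=False, transport=True,
                module=None if j < pool else module_of_cpd[j],
            )

    # internal extras: a few early-pool reactions (spontaneous-eligible,
    # shared), then territory-localized module reactions
    n_extras = n_reactions - len(reactions)
    n_early_extras = min(max(2, n_extras // 10), n_extras)
    for _ in range(n_early_extras):
        picked = rng.choice(pool, size=min(3, pool), replace=False)
        stoich = {cids[int(picked[0])]: -1, cids[int(picked[1])]: 1}
        if len(picked) > 2:
            stoich[cids[int(picked[2])]] = 1
        add_reaction(
            stoich, reversible=bool(rng.random() < 0.3),
            spontaneous=bool(rng.random() < 0.3), transport=False, module=None,
        )
    m = 0
    while len(reactions) < n_reactions:
        terr = territories[m % n_accessory_modules]
        if terr:
            ns = 1 + int(rng.integers(0, 2))
            npr = 1 + int(rng.integers(0, min(2, len(terr))))
            subs = [int(x) for x in rng.choice(pool, size=ns, replace=False)]
            prods = [int(x) for x in rng.choice(terr, size=npr, replace=False)]
            stoich = {cids[j]: -1 for j in subs}
            for j in prods:
                stoich[cids[j]] = 1
            add_reaction(
                stoich, reversible=bool(rng.random() < 0.3),
                spontaneous=False, transport=False, module=m % n_accessory_modules,
            )
        m += 1

    n_prec = min(n_biomass_precursors, pool - n_seed)
    precursors = sorted(
        str(c) for c in rng.choice(cids[n_seed:pool], size=n_prec, replace=False)
    )

    net = UniversalNetwork(
        compounds=compounds,
        reactions=reactions,
        biomass_precursors=precursors,
        seed_compounds=list(seeds),
        modules={},
    )
    if not set(precursors) <= net.reachable_compounds():
        return None  # retry

    modules = {"core": sorted(core_rids)}
    for m in range(n_accessory_modules):
        modules[f"M{m + 1:02d}"] = sorted(module_rids[m])
    net.modules = modules
    net.validate()
    return net


def sample_organism_genome(
    universal: UniversalNetwork,
    n_modules: int,
    seed: int,
    *,
    organism_id: Optional[str] = None,
    ancestor_id: Optional[str] = None,
) -> OrganismGenome:
    """Sample an organism genome as core + ``n_modules`` accessory modules.

    Every organism from the same universal network shares the core module,
    which carries a feasible biomass route; accessory modules provide the
    between-taxon metabolic variation behind saturation of cumulative
    unique-metabolite curves.
    """
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    accessory_names = sorted(m for m in universal.modules if m != "core")
    if n_modules > len(accessory_names):
        raise GenerationError(
            f"requested {n_modules} accessory modules, only {len(accessory_names)} available"
        )
    rng = np.random.default_rng(derive_seed(seed, "organism"))
    chosen = sorted(str(m) for m in rng.choice(accessory_names, size=n_modules, replace=False))
    rids = sorted(set(universal.modules["core"]).union(*(universal.modules[m] for m in chosen)))
    oid = organism_id if organism_id is not None else f"org{seed:05d}"
    gene_map = {f"{oid}_g{i + 1:05d}": rid for i, rid in enumerate(rids)}
    return OrganismGenome(
        organism_id=oid,
        gene_set=set(gene_map),
        gene_reaction_map=gene_map,
        feature_count=len(gene_map),
        ancestor_id=ancestor_id if ancestor_id is not None else oid,
        modules=("core", *chosen),
    )


def strain_variant(
    genome: OrganismGenome,
    universal: UniversalNetwork,
    swap_fraction: float,
    seed: int,
    *,
    organism_id: Optional[str] = None,
) -> OrganismGenome:
    """Derive a strain-level variant: swap a fraction of accessory reactions.

    Models the deviation of a reference genome from the strain actually
    present in a sample.  The variant keeps the same ``ancestor_id`` (species
    identity).  ``swap_fraction = 0`` returns an identical reaction content
    under a new organism id.
    """
    if not 0.0 <= swap_fraction <= 1.0:
        raise ValueError("swap_fraction must be in [0, 1]")
    rng = np.random.default_rng(derive_seed(seed, "strain", genome.organism_id))
    core = set(universal.modules.get("core", []))
    acc = sorted(genome.reaction_ids() - core)
    k = int(round(swap_fraction * len(acc)))
    drop = set(str(x) for x in rng.choice(acc, size=k, replace=False)) if k else set()
    unused = sorted(set(universal.reactions) - genome.reaction_ids())
    add = [str(x) for x in rng.choice(unused, size=min(k, len(unused)), replace=False)] if k else []
    rids = sorted((genome.reaction_ids() - drop) | set(add))
    oid = organism_id if organism_id is not None else genome.organism_id + "_ref"
    gene_map = {f"{oid}_g{i + 1:05d}": rid for i, rid in enumerate(rids)}
    return OrganismGenome(
        organism_id=oid,
        gene_set=set(gene_map),
        gene_reaction_map=gene_map,
        feature_count=len(gene_map),
        ancestor_id=genome.ancestor_id,
        modules=genome.modules,
    )


def simulate_mag(
    source: OrganismGenome,
    completeness: float,
    contamination: float,
    pool: Sequence[OrganismGenome],
    seed: int,
    *,
    mag_id: Optional[str] = None,
) -> MagRecord:
    """Simulate a MAG by subsampling a source genome and adding foreign genes.

    Retains ``round(completeness/100 * |source genes|)`` uniformly sampled
    source genes.  Foreign genes from other pool members are added until the
    foreign fraction of the total reaches the requested contamination
    (largest foreign count whose realized percentage does not exceed it).
    Realized percentages are recorded on the returned record.
    """
    if not 0 < completeness <= 100:
        raise ValueError("completeness must be in (0, 100]")
    if not 0 <= contamination < 100:
        raise ValueError("contamination must be in [0, 100)")
    others = [g for g in pool if g.organism_id != source.organism_id]
    if contamination > 0 and not others:
        raise ValueError("contamination > 0 requires a non-empty pool of other genomes")

    rng = np.random.default_rng(derive_seed(seed, "mag", source.organism_id))
    src_genes = sorted(source.gene_set)
    n_keep = int(round(completeness / 100.0 * len(src_genes)))
    n_keep = min(n_keep, len(src_genes))
    kept = sorted(str(g) for g in rng.choice(src_genes, size=n_keep, replace=False))
    mid = mag_id if mag_id is not None else f"mag_{source.organism_id}"

    gene_map = {g: source.gene_reaction_map[g] for g in kept}
    n_foreign = 0
    if contamination > 0 and n_keep > 0:
        # largest f with 100*f/(n_keep+f) <= contamination
        f_target = int(np.floor(contamination * n_keep / (100.0 - contamination)))
        candidates = []
        for g in sorted(others, key=lambda g: g.organism_id):
            for gene in sorted(g.gene_set - source.gene_set):
                candidates.append((gene, g.gene_reaction_map[gene]))
        f_actual = min(f_target, len(candidates))
        if f_actual > 0:
            idx = sorted(int(i) for i in rng.choice(len(candidates), size=f_actual, replace=False))
            for i in idx:
                gene, rid = candidates[i]
                gene_map[f"{mid}_x_{gene}"] = rid
            n_foreign = f_actual

    realized_completeness = 100.0 * n_keep / len(src_genes) if src_genes else 0.0
    total = n_keep + n_foreign
    realized_contamination = 100.0 * n_foreign / total if total else 0.0
    genome = OrganismGenome(
        organism_id=mid,
        gene_set=set(gene_map),
        gene_reaction_map=gene_map,
        feature_count=len(gene_map),
        ancestor_id=source.ancestor_id,
        modules=source.modules,
    )
    return MagRecord(
        mag_id=mid,
        genome=genome,
        completeness=realized_completeness,
        contamination=realized_contamination,
        source_organism=source.organism_id,
    )


def sample_abundance_table(
    organisms: Sequence,
    n_samples: int,
    lognormal_sigma: float,
    seed: int,
    *,
    group: str = "group1",
) -> AbundanceTable:
    """Draw per-sample log-normal abundance weights and normalize to 100%."""
    ids = [getattr(o, "organism_id", o) for o in organisms]
    if len(ids) < 2:
        raise ValueError("need >= 2 organisms")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate organism ids")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if lognormal_sigma <= 0:
        raise ValueError("lognormal_sigma must be positive")
    rng = np.random.default_rng(derive_seed(seed, "abundance", group))
    weights = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=(len(ids), n_samples))
    pct = 100.0 * weights / weights.sum(axis=0, keepdims=True)
    samples = [f"{group}_s{j + 1:02d}" for j in range(n_samples)]
    df = pd.DataFrame(pct, index=ids, columns=samples)
    table = AbundanceTable(data=df, groups={group: samples})
    table.validate()
    return table


def simulate_metabolomics(
    true_exometabolome: Iterable[str],
    universal: UniversalNetwork,
    id_loss_rate: float,
    n_host_extras: int,
    n_samples: int,
    seed: int,
    *,
    group: str = "group1",
    missing_rate: float = 0.2,
    n_replicate_ids: int = 0,
) -> MetabolomicsTable:
    """Simulate an untargeted-metabolomics table for a true exometabolome.

    Each true compound yields one row carrying the compound's catalog
    external id, except rows selected for id loss (rounded fraction
    ``id_loss_rate``), which lose it.  ``n_host_extras`` extra rows carry
    external ids absent from the universal catalog (host/diet metabolites).
    Some replicate external ids can be attached as aliases.  Abundances are
    positive log-normal draws with per-cell missingness.
    """
    if not 0.0 <= id_loss_rate < 1.0:
        raise ValueError("id_loss_rate must be in [0, 1)")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    cids = sorted(set(true_exometabolome))
    unknown = [c for c in cids if c not in universal.compounds]
    if unknown:
        raise ValueError(f"exometabolome compounds not in catalog: {unknown[:5]}")

    rng = np.random.default_rng(derive_seed(seed, "metabolomics", group))
    n_loss = int(round(id_loss_rate * len(cids)))
    lost = set(
        str(c) for c in rng.choice(cids, size=min(n_loss, len(cids)), replace=False)
    )
    samples = [f"{group}_m{j + 1:02d}" for j in range(n_samples)]

    def draw_abundances():
        ab = {}
        for s in samples:
            ab[s] = None if rng.random() < missing_rate else float(rng.lognormal(0.0, 1.0))
        return ab

    rows = []
    n_rep = 0
    for cid in cids:
        comp = universal.compounds[cid]
        ext = None if cid in lost else comp.external_id
        reps = ()
        if ext is not None and n_rep < n_replicate_ids:
            n_rep += 1
            reps = (f"C7{n_rep:04d}",)
        rows.append(
            MetaboliteRow(name=comp.name, external_id=ext, replicate_ids=reps,
                          abundances=draw_abundances())
        )
    for i in range(n_host_extras):
        rows.append(
            MetaboliteRow(
                name=f"host_metabolite_{i + 1}",
                external_id=f"C9{i + 1:04d}",
                replicate_ids=(),
                abundances=draw_abundances(),
            )
        )
    table = MetabolomicsTable(rows=rows, samples=samples, groups={group: samples})
    table.validate()
    return table


def generate_pathways(
    universal: UniversalNetwork,
    n_pathways: int,
    seed: int,
    *,
    size_range: tuple = (5, 20),
    localized_fraction: float = 0.6,
) -> dict:
    """Generate synthetic pathway annotations over the mappable catalog.

    Returns pathway id -> set of compound ids.  A fraction of pathways is
    localized to the compounds of a single accessory module (real pathways
    cluster with gene modules), the rest are drawn uniformly; ids alternate
    between KEGG-style (``mapNNNNN``) and HMDB/SMPDB-style (``SMPNNNNN``)
    prefixes so enrichment reports can carry a source label.
    """
    if n_pathways < 1:
        raise ValueError("n_pathways must be >= 1")
    background = sorted(c.id for c in universal.compounds.values() if c.external_id)
    if not background:
        raise GenerationError("no externally mappable compounds in catalog")
    rng = np.random.default_rng(derive_seed(seed, "pathways"))
    bg = set(background)
    module_cpds = {}
    for name, rids in universal.modules.items():
        if name == "core":
            continue
        cpds = sorted(
            {cid for rid in rids for cid, _ in universal.reactions[rid].stoichiometry}
            & bg
        )
        if cpds:
            module_cpds[name] = cpds
    module_names = sorted(module_cpds)
    lo, hi = size_range
    pathways = {}
    for i in range(n_pathways):
        pool = background
        if module_names and rng.random() < localized_fraction:
            pool = module_cpds[module_names[int(rng.integers(len(module_names)))]]
        size = int(rng.integers(lo, min(hi, len(pool)) + 1))
        members = set(str(c) for c in rng.choice(pool, size=size, replace=False))
        prefix = "map" if i % 2 == 0 else "SMP"
        pathways[f"{prefix}{i + 1:05d}"] = members
    return pathways


def pathway_source(pathway_id: str) -> str:
    """Source label for a pathway id (KEGG-style vs HMDB-style)."""
    return "KEGG" if pathway_id.startswith("map") else "HMDB"
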