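"""End-to-end experiment orchestration.

Runs the full comparison: simulate a community, select input taxa with both
strategies (abundance cutoffs for the reference-guided approach; quality
tiers, dereplication and count normalization for the MAG-guided approach),
build and merge models, compute census metrics and saturation curves,
validate against simulated untargeted metabolomics, optionally gapfill and
classify blocked reactions, and compare pathway over-representation between
the approaches.  Everything is driven by one global seed; each stage derives
its own child seed so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import community as community_mod
from . import fluxcore, io, netgen, selection, valid_enrich
from .draftgem import DraftModelError, build_draft_model, choose_reference_genome

__all__ = ["ExperimentConfig", "ReportBundle", "run_comparison", "fold_change"]

log = logging.getLogger("commgem")

REFERENCE_CONDITION = "reference_{cutoff:g}"
MAG_CONDITIONS = ("mag_high", "mag_high_medium", "mag_normalized")


def fold_change(pre: int, post: int) -> float:
    """post/pre rounded to 2 decimals (the gapfilling fold bookkeeping)."""
    if pre <= 0:
        raise ValueError("pre-count must be positive")
    return round(post / pre, 2)


@dataclass
class ExperimentConfig:
    seed: int = 1
    # universal network
    n_compounds: int = 300
    n_reactions: int = 620
    transport_fraction: float = 0.2
    external_id_rate: float = 0.7
    n_accessory_modules: int = 40
    n_biomass_precursors: int = 6
    # community
    n_organisms: int = 40
    modules_min: int = 1
    modules_max: int = 3
    n_samples: int = 8
    lognormal_sigma: float = 2.0
    # reference-guided selection
    cutoffs: tuple = (5.0, 2.5, 1.0, 0.5)
    missing_reference_rate: float = 0.0
    strain_swap_fraction: float = 0.0
    # MAG-guided selection
    mag_completeness: tuple = (55.0, 99.0)
    mag_contamination: tuple = (0.0, 0.0)
    # metabolomics
    n_met_samples: int = 6
    id_loss_rate: float = 0.0
    n_host_extras: int = 15
    n_replicate_ids: int = 5
    metabolomics_missing_rate: float = 0.2
    # flux analyses
    gapfill: bool = False
    fva: bool = False
    uptake_limit: float = 10.0
    # enrichment
    n_pathways: int = 40
    q_threshold: float = 0.05
    # output
    out_dir: Optional[str] = None

    def validate(self) -> None:
        cutoffs = list(self.cutoffs)
        if any(c2 >= c1 for c1, c2 in zip(cutoffs, cutoffs[1:])):
            raise ValueError("cutoffs must be strictly decreasing")
        if any(c <= 0 for c in cutoffs):
            raise ValueError("cutoffs must be positive")
        for name in ("transport_fraction", "external_id_rate", "missing_reference_rate",
                     "strain_swap_fraction", "id_loss_rate", "metabolomics_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.modules_min < 1 or self.modules_max < self.modules_min:
            raise ValueError("invalid accessory-module range")
        if self.n_organisms < 2:
            raise ValueError("need >= 2 organisms")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cutoffs", "mag_completeness", "mag_contamination"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for key in ("cutoffs", "mag_completeness", "mag_contamination"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class ConditionReport:
    name: str
    approach: str
    selection: selection.SelectionResult
    census: Optional[community_mod.CensusReport]
    validation: Optional[valid_enrich.ValidationReport]
    unique_ids: set = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "approach": self.approach,
            "selection": self.selection.to_dict(),
            "census": self.census.to_dict() if self.census else None,
            "validation": self.validation.to_dict() if self.validation else None,
        }


@dataclass
class ReportBundle:
    config: ExperimentConfig
    conditions: dict  # name -> ConditionReport
    condition_order: list
    venn_unique: Optional[valid_enrich.VennPartition]
    venn_confirmed: Optional[valid_enrich.VennPartition]
    saturation: list
    enrichment: dict
    gapfill: dict
    blocked: dict

    def to_dict(self) -> dict:
        return {
            "config": dataclasses.asdict(self.config),
            "conditions": {k: self.conditions[k].to_dict() for k in self.condition_order},
            "venn_unique": self.venn_unique.to_dict() if self.venn_unique else None,
            "venn_confirmed": self.venn_confirmed.to_dict() if self.venn_confirmed else None,
            "saturation": list(self.saturation),
            "enrichment": self.enrichment,
            "gapfill": self.gapfill,
            "blocked": self.blocked,
        }

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            if isinstance(o, tuple):
                return list(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"not serializable: {type(o)}")

        return json.dumps(self.to_dict(), indent=1, sort_keys=True, default=default)

    def census_table(self) -> "pd.DataFrame":
        """Census + validation summary, one condition per column, rows in the
        taxa / total / extracellular / unique / confirmed / data-loss /
        confirmed-% order."""
        import pandas as pd

        rows = [
            "Taxa",
            "Total predicted metabolites",
            "Total extracellular metabolites",
            "Unique metabolites",
            "Confirmed unique metabolites (total)",
            "Data loss (%)",
            "Confirmed unique metabolites (%)",
        ]
        table = {}
        for name in self.condition_order:
            cond = self.conditions[name]
            cen, val = cond.census, cond.validation
            detected = len(cond.selection.taxa_detected)
            used = len(cond.selection.taxa_used)
            taxa = str(used) if used == detected else f"{used} ({detected})"
            table[name] = [
                taxa,
                cen.total_predicted if cen else None,
                cen.total_extracellular if cen else None,
                cen.unique_metabolites if cen else None,
                val.confirmed_count if val else None,
                val.data_loss_pct if val else None,
                val.confirmed_pct if val else None,
            ]
        return pd.DataFrame(table, index=rows)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        self.census_table().to_csv(out / "census.tsv", sep="\t")


def _seed(cfg: ExperimentConfig, *keys) -> int:
    return netgen.derive_seed(cfg.seed, *keys)


def run_comparison(config: ExperimentConfig) -> ReportBundle:
    """Execute the full reference-vs-MAG comparison for one configuration."""
    config.validate()
    log.info("stage=simulate seed=%d", config.seed)

    universal = netgen.generate_universal_network(
        config.n_compounds,
        config.n_reactions,
        config.transport_fraction,
        _seed(config, "universal"),
        external_id_rate=config.external_id_rate,
        n_biomass_precursors=config.n_biomass_precursors,
        n_accessory_modules=config.n_accessory_modules,
    )

    rng = np.random.default_rng(_seed(config, "organisms"))
    organisms = []
    for i in range(config.n_organisms):
        n_modules = int(rng.integers(config.modules_min, config.modules_max + 1))
        organisms.append(
            netgen.sample_organism_genome(
                universal, n_modules, _seed(config, "org", i),
                organism_id=f"sp{i + 1:03d}",
            )
        )
    by_id = {g.organism_id: g for g in organisms}

    abundance = netgen.sample_abundance_table(
        organisms, config.n_samples, config.lognormal_sigma,
        _seed(config, "abundance"), group="community",
    )

    # reference genomes (strain variants of the sampled organisms)
    ref_rng = np.random.default_rng(_seed(config, "references"))
    reference_genomes = {}
    for g in organisms:
        if ref_rng.random() < config.missing_reference_rate:
            continue  # no publicly available reference for this taxon
        variant = netgen.strain_variant(
            g, universal, config.strain_swap_fraction,
            _seed(config, "ref", g.organism_id),
        )
        reference_genomes[g.organism_id] = choose_reference_genome([variant])

    # MAGs, one per organism
    mag_rng = np.random.default_rng(_seed(config, "mags"))
    mags = []
    c_lo, c_hi = config.mag_completeness
    t_lo, t_hi = config.mag_contamination
    for i, g in enumerate(organisms):
        completeness = float(mag_rng.uniform(c_lo, c_hi))
        contamination = float(mag_rng.uniform(t_lo, t_hi))
        mags.append(
            netgen.simulate_mag(
                g, completeness, contamination, organisms,
                _seed(config, "mag", g.organism_id), mag_id=f"mag{i + 1:03d}",
            )
        )

    # model caches
    def build_cached(cache, key, genome, provenance):
        if key not in cache:
            cache[key] = build_draft_model(genome, universal, key, provenance=provenance)
        return cache[key]

    ref_models, mag_models = {}, {}

    # ground-truth exometabolome from the complete (source-genome) community
    truth_models = [
        build_draft_model(g, universal, g.organism_id) for g in organisms
    ]
    truth_community = community_mod.merge_models(truth_models)
    true_exo = truth_community.extracellular_ids()

    metabolomics = netgen.simulate_metabolomics(
        true_exo, universal, config.id_loss_rate, config.n_host_extras,
        config.n_met_samples, _seed(config, "metabolomics"), group="donor",
        missing_rate=config.metabolomics_missing_rate,
        n_replicate_ids=config.n_replicate_ids,
    )
    presence = valid_enrich.to_presence(metabolomics, "donor")
    id_map = {c.id: c.external_id for c in universal.compounds.values()}

    conditions = {}
    condition_order = []
    communities = {}

    def finish_condition(name, approach, sel, models):
        nonlocal conditions, condition_order
        if models:
            comm = community_mod.merge_models(models)
            cen = community_mod.census(comm)
            unique_ids = comm.compound_ids()
            val = valid_enrich.match_predictions(unique_ids, id_map, presence)
            communities[name] = comm
        else:
            cen, val, unique_ids = None, None, set()
        conditions[name] = ConditionReport(
            name=name, approach=approach, selection=sel,
            census=cen, validation=val, unique_ids=unique_ids,
        )
        condition_order.append(name)

    # --- reference-guided conditions ------------------------------------
    means = selection.mean_relative_abundance(abundance, "community")
    for cutoff in config.cutoffs:
        name = REFERENCE_CONDITION.format(cutoff=cutoff)
        sel = selection.select_by_cutoff(means, cutoff)
        models = []
        for taxon in list(sel.taxa_used):
            genome = reference_genomes.get(taxon)
            if genome is None:
                sel.exclude(taxon, "no publicly available reference genome")
                continue
            try:
                models.append(build_cached(ref_models, taxon, genome, "reference"))
            except DraftModelError as exc:
                sel.exclude(taxon, f"draft model failed: {exc}")
        log.info("stage=select condition=%s detected=%d used=%d",
                 name, len(sel.taxa_detected), len(sel.taxa_used))
        finish_condition(name, "reference", sel, models)

    # --- MAG-guided conditions ------------------------------------------
    tiers = {
        m.mag_id: selection.classify_mag_quality(m.completeness, m.contamination)
        for m in mags
    }
    passing = [m for m in mags if tiers[m.mag_id] != "fail"]
    dereplicated = selection.dereplicate_mags(passing)

    def mag_condition(name, selected, extra_params):
        sel = selection.SelectionResult(
            approach="mag",
            parameters=extra_params,
            taxa_detected=[m.mag_id for m in selected],
            taxa_used=[m.mag_id for m in selected],
        )
        models = []
        for m in selected:
            try:
                models.append(build_cached(mag_models, m.mag_id, m.genome, "mag"))
            except DraftModelError as exc:
                sel.exclude(m.mag_id, f"draft model failed: {exc}")
        log.info("stage=select condition=%s used=%d", name, len(sel.taxa_used))
        finish_condition(name, "mag", sel, models)
        return sel

    high = [m for m in dereplicated if tiers[m.mag_id] == "high"]
    mag_condition("mag_high", high, {"tiers": ["high"]})
    mag_condition("mag_high_medium", dereplicated, {"tiers": ["high", "medium"]})

    ref_at_lowest = REFERENCE_CONDITION.format(cutoff=config.cutoffs[-1])
    n_norm = max(1, len(conditions[ref_at_lowest].selection.taxa_used))
    normalized, shortfall = selection.normalize_mag_count(dereplicated, n_norm)
    sel_norm = mag_condition(
        "mag_normalized", normalized,
        {"tiers": ["high"], "normalize_to": n_norm},
    )
    sel_norm.parameters["shortfall"] = shortfall

    # --- Venn complementarity -------------------------------------------
    ref_ids = conditions[ref_at_lowest].unique_ids
    mag_ids = conditions["mag_high_medium"].unique_ids
    venn_unique = valid_enrich.venn(ref_ids, mag_ids)
    ref_conf = (conditions[ref_at_lowest].validation.confirmed_ids
                if conditions[ref_at_lowest].validation else set())
    mag_conf = (conditions["mag_high_medium"].validation.confirmed_ids
                if conditions["mag_high_medium"].validation else set())
    venn_confirmed = valid_enrich.venn(ref_conf, mag_conf)

    # --- saturation curve (members ordered by descending abundance) -----
    order = sorted(means, key=lambda sp: (-means[sp], sp))
    sat_models = [m for sp in order for m in [ref_models.get(sp)] if m is not None]
    if not sat_models:
        sat_models = [build_draft_model(by_id[sp], universal, sp) for sp in order]
    saturation = community_mod.saturation_curve(sat_models)

    # --- pathway over-representation ------------------------------------
    pathways = netgen.generate_pathways(universal, config.n_pathways, _seed(config, "pathways"))
    background = {c.id for c in universal.compounds.values() if c.external_id}
    combined_ids = valid_enrich.combine_lists(ref_ids, mag_ids)
    ora = {}
    for label, ids in (("reference", ref_ids), ("mag", mag_ids), ("combined", combined_ids)):
        ora[label] = valid_enrich.apply_bh(
            valid_enrich.hypergeom_ora(ids & background, background, pathways)
        )
    shared, only_ref, only_mag = valid_enrich.compare_enrichment(
        ora["reference"], ora["mag"], config.q_threshold
    )
    enrichment = {
        "q_threshold": config.q_threshold,
        "significant": {k: sorted(v.significant(config.q_threshold)) for k, v in ora.items()},
        "comparison": {
            "shared": sorted(shared),
            "only_reference": sorted(only_ref),
            "only_mag": sorted(only_mag),
        },
    }

    # --- gapfilling -------------------------------------------------------
    gapfill_report = {}
    if config.gapfill:
        medium = fluxcore.default_medium(universal)
        core = set(universal.modules.get("core", []))
        for name in (ref_at_lowest, "mag_normalized"):
            cond = conditions[name]
            if cond.census is None:
                continue
            comm = communities[name]
            filled_models = []
            n_added = 0
            for lbl, model in comm.members:
                # restrict candidates to missing core reactions first: this is
                # what MAG incompleteness removed; fall back to the full pool
                result = fluxcore.gapfill(
                    model, universal, medium,
                    candidates=sorted(core - set(model.reactions)),
                    uptake_limit=config.uptake_limit,
                )
                if result.status == "unfillable":
                    result = fluxcore.gapfill(
                        model, universal, medium, method="greedy",
                        uptake_limit=config.uptake_limit,
                    )
                filled = fluxcore.apply_gapfill(model, universal, result.added)
                filled_models.append(filled)
                n_added += len(result.added)
            post_comm = community_mod.merge_models(filled_models)
            post_cen = community_mod.census(post_comm)
            gapfill_report[name] = {
                "reactions_added": n_added,
                "total_pre": cond.census.total_predicted,
                "total_post": post_cen.total_predicted,
                "total_fold": fold_change(cond.census.total_predicted, post_cen.total_predicted),
                "unique_pre": cond.census.unique_metabolites,
                "unique_post": post_cen.unique_metabolites,
                "unique_fold": fold_change(cond.census.unique_metabolites, post_cen.unique_metabolites),
            }
            log.info("stage=gapfill condition=%s added=%d", name, n_added)

    # --- blocked-reaction classification ---------------------------------
    blocked_report = {}
    if config.fva:
        medium = fluxcore.default_medium(universal)
        cond = conditions[ref_at_lowest]
        if cond.census is not None:
            per_member = {}
            for lbl, model in communities[ref_at_lowest].members:
                problem = fluxcore.build_flux_problem(
                    model, medium, uptake_limit=config.uptake_limit
                )
                per_member[lbl] = fluxcore.fva(problem).blocked_percentage
            blocked_report[ref_at_lowest] = {
                "per_member": per_member,
                "mean": float(np.mean(list(per_member.values()))),
            }

    bundle = ReportBundle(
        config=config,
        conditions=conditions,
        condition_order=condition_order,
        venn_unique=venn_unique,
        venn_confirmed=venn_confirmed,
        saturation=saturation,
        enrichment=enrichment,
        gapfill=gapfill_report,
        blocked=blocked_report,
    )

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.write(out)
        universal.to_json(out / "universal_network.json")
        abundance.to_metaphlan_tsv(out / "abundance.tsv")
        metabolomics.to_tsv(out / "metabolomics.tsv")
        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        for name, model in sorted({**ref_models, **mag_models}.items()):
            io.write_json_model(model, models_dir / f"{model.model_id}.json")
        for name in (ref_at_lowest, "mag_high_medium"):
            if name in communities:
                io.write_sbml_community(communities[name], out / f"community_{name}.xml")
        log.info("stage=report out=%s", out)

    return bundle
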