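"""End-to-end orchestration: preprocess -> select -> patterns -> breaks -> enrich."""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from stagewise import __version__, io
from stagewise.enrich import build_cases
from stagewise.errors import ConfigurationError
from stagewise.patterns import ClusterConfig, find_patterns
from stagewise.preprocess import (
    StageSeries,
    differential_profiles,
    filter_low_expression,
    log2_transform,
)
from stagewise.select import NullModel, SelectionConfig, estimate_null, select_genes
from stagewise.timebreaks import (
    BreakConfig,
    assign_time_breaks,
    default_grouping,
    summarize_main_patterns,
)

log = logging.getLogger("stagewise")


@dataclass
class PipelineConfig:
    counts_path: str
    gmt_path: str
    out_dir: str
    hierarchy_path: str | None = None
    category_map_path: str | None = None
    exclusion_path: str | None = None
    stage_order: list[str] | None = None
    min_mean_count: float = 10.0
    alpha: float = 0.01
    null_mu: float | None = None
    null_sigma: float | None = None
    min_r2: float = 0.8
    require_positive_slope: bool = True
    max_iter: int = 20
    break_threshold: float = 0.2
    break_grouping: dict[int, str] | None = None
    pattern_mean: str = "abs"
    exclusion_stage: str = "post_selection"  # or "pre_selection"
    background: str = "de"  # or "expressed"
    fdr_alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.break_grouping is not None:
            cfg.break_grouping = {int(k): str(v) for k, v in cfg.break_grouping.items()}
        if cfg.exclusion_stage not in ("pre_selection", "post_selection"):
            raise ConfigurationError(f"bad exclusion_stage {cfg.exclusion_stage!r}")
        if cfg.background not in ("de", "expressed"):
            raise ConfigurationError(f"bad background mode {cfg.background!r}")
        return cfg


def apply_exclusion(series: StageSeries, exclusion: set[str]) -> StageSeries:
    """Remove listed genes from a series; ids not present are warned about."""
    missing = exclusion - set(series.genes)
    if missing:
        log.warning("exclusion list: %d ids not in the series", len(missing))
    keep = np.array([g not in exclusion for g in series.genes], dtype=bool)
    return series.subset(keep)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write all stage outputs plus a manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    counts = io.read_counts(config.counts_path, config.stage_order)
    manifest: dict = {
        "version": __version__,
        "started": datetime.datetime.now().isoformat(),
        "config": {k: v for k, v in vars(config).items()},
        "funnel": {"genes_input": counts.n_genes},
    }

    exclusion: set[str] = set()
    if config.exclusion_path:
        exclusion = io.read_gene_list(config.exclusion_path)
    if exclusion and config.exclusion_stage == "pre_selection":
        before = counts.n_genes
        counts = apply_exclusion(counts, exclusion)
        manifest["funnel"]["genes_excluded_pre"] = before - counts.n_genes

    filtered = filter_low_expression(counts, config.min_mean_count)
    manifest["funnel"]["genes_expressed"] = filtered.n_genes
    logged = log2_transform(filtered)
    profiles = differential_profiles(logged)

    if config.null_mu is not None and config.null_sigma is not None:
        null = NullModel(config.null_mu, config.null_sigma)
        manifest["null"] = {"source": "fixed"}
    else:
        null = estimate_null(logged)
        manifest["null"] = {"source": "estimated", "n_null": null.n_null}
    manifest["null"].update({"log_mu": null.log_mu, "log_sigma": null.log_sigma})

    sel_config = SelectionConfig(alpha=config.alpha)
    selection = select_genes(profiles, null, sel_config)
    manifest["funnel"]["seeds"] = int((selection["label"] == "seed").sum())
    manifest["funnel"]["candidates"] = int((selection["label"] == "candidate").sum())

    if exclusion and config.exclusion_stage == "post_selection":
        hit = selection.index.isin(exclusion)
        n_hit = int((hit & (selection["label"] != "none")).sum())
        selection.loc[hit, "label"] = "none"
        manifest["funnel"]["genes_excluded_post"] = n_hit
        missing = exclusion - set(selection.index)
        if missing:
            log.warning("exclusion list: %d ids not in the selection table", len(missing))
    selection.to_csv(out / "selection.tsv", sep="\t", float_format=io.FLOAT_FORMAT)

    annotations = io.read_gmt(config.gmt_path)
    hierarchy = io.read_hierarchy(config.hierarchy_path) if config.hierarchy_path else None
    if hierarchy is None:
        log.info("no hierarchy file: running in flat-annotation mode")
    cluster_config = ClusterConfig(
        min_r2=config.min_r2,
        require_positive_slope=config.require_positive_slope,
        max_iter=config.max_iter,
    )
    result = find_patterns(selection, profiles, annotations, hierarchy, cluster_config)
    manifest["funnel"]["de_genes"] = len(result.de_genes)
    manifest["funnel"]["temporal_patterns"] = len(result.patterns)
    manifest["skipped_terms"] = len(result.skipped_terms)

    stages = list(profiles.axis.stages)
    tp_rows, tmpl_rows = [], []
    for tp in result.patterns:
        for g in tp.members:
            tp_rows.append((tp.term_id, tp.index, g, g in set(tp.seed_members)))
        for i, stage in enumerate(stages):
            tmpl_rows.append((tp.term_id, tp.index, stage, tp.template[i]))
    pd.DataFrame(tp_rows, columns=["term_id", "tp_index", "gene_id", "is_seed"]).to_csv(
        out / "temporal_patterns.tsv", sep="\t", index=False
    )
    pd.DataFrame(tmpl_rows, columns=["term_id", "tp_index", "stage", "value"]).to_csv(
        out / "tp_templates.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT
    )

    grouping = config.break_grouping or default_grouping(len(stages))
    break_config = BreakConfig(
        threshold=config.break_threshold,
        grouping=grouping,
        pattern_mean=config.pattern_mean,
    )
    assignments = [assign_time_breaks(tp, break_config) for tp in result.patterns]
    mps, unclassified = summarize_main_patterns(assignments, cluster_config)
    manifest["funnel"]["main_patterns"] = len(mps)
    manifest["funnel"]["unclassified_tps"] = len(unclassified)

    mp_rows, mp_profile_rows, mp_gene_rows = [], [], []
    for mp in mps:
        mp_rows.append(
            (
                mp.mp_id,
                stages[mp.time_break],
                mp.sign or "unclassifiable",
                len(mp.members),
                len(mp.member_genes),
            )
        )
        for i, stage in enumerate(stages):
            mp_profile_rows.append((mp.mp_id, stage, mp.profile[i]))
        for g in mp.member_genes:
            mp_gene_rows.append((mp.mp_id, g))
    pd.DataFrame(
        mp_rows, columns=["mp_id", "time_break", "sign", "tp_count", "gene_count"]
    ).to_csv(out / "main_patterns.tsv", sep="\t", index=False)
    pd.DataFrame(mp_profile_rows, columns=["mp_id", "stage", "value"]).to_csv(
        out / "mp_profiles.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT
    )
    pd.DataFrame(mp_gene_rows, columns=["mp_id", "gene_id"]).to_csv(
        out / "mp_genes.tsv", sep="\t", index=False
    )

    if config.category_map_path:
        category_map = io.read_category_map(config.category_map_path)
        if config.background == "de":
            background = set(result.de_genes)
            for mp in mps:
                background |= set(mp.member_genes)
        else:
            background = set(filtered.genes)
        if background:
            enrichment = build_cases(
                mps, category_map, break_config, background, config.fdr_alpha
            )
        else:
            enrichment = pd.DataFrame(
                columns=["kind", "case", "category", "a", "b", "c", "d",
                         "odds_ratio", "p", "q", "significant"]
            )
        enrichment.to_csv(
            out / "enrichment.tsv", sep="\t", index=False, float_format=io.FLOAT_FORMAT
        )
        manifest["funnel"]["enrichment_tests"] = len(enrichment)

    manifest["finished"] = datetime.datetime.now().isoformat()
    io.write_manifest(manifest, out / "manifest.json")
    return manifest
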