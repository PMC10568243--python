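"""End-to-end orchestration: load resources, search, annotate, label, report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import annotation_store as store
from .config import RunConfig
from .reporting import ChartBundle, build_charts, build_database_tables, build_summary
from .risk_engine import RiskLabel, assign_risks
from .sequence_search import GuideRNA, OffTargetSite, find_offtargets
from .site_annotator import SiteAnnotation, annotate_sites

logger = logging.getLogger(__name__)


@dataclass
class Resources:
    """All loaded annotation layers for one run."""

    genome: Optional[dict[str, str]] = None
    gene_models: Optional[store.GeneModelSet] = None
    tracks: list[store.AnnotationTrack] = field(default_factory=list)
    function_index: store.GeneFunctionIndex = field(default_factory=store.GeneFunctionIndex)


_BED_LAYER_KINDS = {
    "promoters": "promoter",
    "enhancers": "enhancer",
    "regulator_peaks": "regulator_peak",
    "protein_domains": "protein_domain",
    "mirna_genes": "mirna_gene",
    "mirna_targets": "mirna_target",
}


def load_resources(cfg: RunConfig, need_genome: bool = True) -> Resources:
    """Load every configured layer; omitted layers are skipped."""
    res = Resources()
    if need_genome:
        if cfg.genome is None:
            raise ValueError("no genome configured")
        res.genome = store.load_genome(cfg.genome)
    db = cfg.databases
    if "gene_models" in db:
        res.gene_models = store.load_gene_models(db["gene_models"])
    for layer, kind in _BED_LAYER_KINDS.items():
        if layer in db:
            res.tracks.append(store.load_track(db[layer], kind))
    res.function_index = store.load_function_tables(
        phenotypes=db.get("phenotypes"), cancer_genes=db.get("cancer_genes"),
        tf=db.get("tf"), rbp=db.get("rbp"), expression=db.get("expression"))
    if res.genome is not None:
        named = []
        if res.gene_models is not None:
            named.append(("gene_models", res.gene_models.chroms()))
        for t in res.tracks:
            named.append((t.kind, {r.chrom for r in t.records}))
        store.check_chrom_consistency(set(res.genome), *named)
    return res


def search_sites(res: Resources, guide: GuideRNA, cfg: RunConfig) -> list[OffTargetSite]:
    if res.genome is None:
        raise ValueError("genome required for search")
    sites = find_offtargets(res.genome, guide, cfg.search)
    logger.info("found %d candidate sites", len(sites))
    return sites


@dataclass
class AnalysisResult:
    sites: list[OffTargetSite]
    annotations: list[SiteAnnotation]
    labels: list[RiskLabel]
    summary: pd.DataFrame
    charts: ChartBundle
    tables: dict[str, pd.DataFrame]


def analyze_sites(sites: Sequence[OffTargetSite], res: Resources) -> AnalysisResult:
    """Annotate sites against every loaded layer, label them and build reports."""
    annotations = annotate_sites(sites, res.gene_models, res.tracks, res.function_index)
    labels = assign_risks(annotations)
    summary = build_summary(annotations, labels)
    charts = build_charts(annotations, labels, res.function_index)
    tables = build_database_tables(annotations, res.function_index)
    return AnalysisResult(sites=list(sites), annotations=annotations, labels=labels,
                          summary=summary, charts=charts, tables=tables)
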