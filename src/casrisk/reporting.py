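"""Summary tables, per-database tables, chart data and exports.

The summary table carries one color-coded row per deduplicated site; the
chart bundle holds the four standard distributions (genomic locations,
targeted gene types, risk labels, expression of targeted protein-coding
genes).  Everything exports to csv (one file per table), xlsx (one workbook,
one sheet per table) or json (single document), plus a BED of the sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .annotation_store import GeneFunctionIndex
from .risk_engine import RiskLabel, risk_distribution
from .sequence_search import OffTargetSite, write_sites_bed
from .site_annotator import SiteAnnotation

SUMMARY_COLUMNS = [
    "chrom", "start", "end", "strand", "site_sequence", "pam_sequence",
    "mismatches", "dna_bulges", "rna_bulges", "genes", "biotypes", "segments",
    "promoters", "enhancers", "regulator_peaks", "protein_domains",
    "mirna_genes", "mirna_targets", "phenotypes", "cancer_gene",
    "tf", "rbp", "risk_label", "risk_rationale", "color",
]

DB_TABLE_NAMES = ["gencode", "mirgene", "remap_epd", "enhancer", "pfam",
                  "targetscan", "omim", "tf", "expression", "rbp", "cosmic"]


@dataclass
class ChartBundle:
    """Chart-ready datasets.

    ``locations``: sites per chromosome; ``gene_types``: (biotype, segment)
    counts over gene hits; ``risk_labels``: sites per risk label;
    ``expression``: targeted protein-coding genes x tissues.
    """

    locations: dict[str, int] = field(default_factory=dict)
    gene_types: list[dict] = field(default_factory=list)
    risk_labels: dict[str, int] = field(default_factory=dict)
    expression: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_jsonable(self) -> dict:
        return {
            "locations": self.locations,
            "gene_types": self.gene_types,
            "risk_labels": self.risk_labels,
            "expression": {g: {t: float(v) for t, v in row.items()}
                           for g, row in self.expression.to_dict(orient="index").items()},
        }


def _join(values: Sequence[str]) -> str:
    seen: list[str] = []
    for v in values:
        if v and v not in seen:
            seen.append(v)
    return ";".join(seen)


def build_summary(annotations: Sequence[SiteAnnotation],
                  labels: Sequence[RiskLabel]) -> pd.DataFrame:
    """One row per site, fixed column order, color-coded by risk tier
    (high -> red, medium -> orange, low -> yellow, none -> green)."""
    if len(annotations) != len(labels):
        raise ValueError(f"{len(annotations)} annotations vs {len(labels)} labels")
    rows = []
    for ann, lab in zip(annotations, labels):
        s = ann.site
        phen: list[str] = []
        cancer = False
        tf: list[str] = []
        rbp: list[str] = []
        for gid, rec in ann.functional.items():
            phen.extend(rec.phenotypes)
            cancer = cancer or rec.is_cancer_gene
            if rec.tf_class != "none":
                tf.append(f"{gid}:{rec.tf_class}")
            if rec.rbp_functions:
                rbp.append(f"{gid}:{'|'.join(rec.rbp_functions)}")
        rows.append({
            "chrom": s.chrom, "start": s.start, "end": s.end, "strand": s.strand,
            "site_sequence": s.site_sequence, "pam_sequence": s.pam_sequence,
            "mismatches": "" if s.mismatches is None else s.mismatches,
            "dna_bulges": s.dna_bulges, "rna_bulges": s.rna_bulges,
            "genes": _join([h.gene_name for h in ann.gene_hits]),
            "biotypes": _join([h.biotype for h in ann.gene_hits]),
            "segments": _join([h.segment for h in ann.gene_hits]),
            "promoters": _join([h.feature_name for h in ann.promoter_hits]),
            "enhancers": _join([h.feature_name for h in ann.enhancer_hits]),
            "regulator_peaks": _join([h.feature_name for h in ann.regulator_peak_hits]),
            "protein_domains": _join([h.feature_name for h in ann.domain_hits]),
            "mirna_genes": _join([h.feature_name for h in ann.mirna_gene_hits]),
            "mirna_targets": _join([h.feature_name for h in ann.mirna_target_hits]),
            "phenotypes": _join(phen),
            "cancer_gene": bool(cancer),
            "tf": _join(tf),
            "rbp": _join(rbp),
            "risk_label": lab.label,
            "risk_rationale": lab.rationale,
            "color": lab.color,
        })
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def build_charts(annotations: Sequence[SiteAnnotation], labels: Sequence[RiskLabel],
                 function_index: Optional[GeneFunctionIndex] = None) -> ChartBundle:
    """Compute the four chart datasets from annotated, labeled sites."""
    locations: dict[str, int] = {}
    for ann in annotations:
        locations[ann.site.chrom] = locations.get(ann.site.chrom, 0) + 1

    type_counts: dict[tuple[str, str], int] = {}
    coding_genes: list[str] = []
    for ann in annotations:
        for hit in ann.gene_hits:
            key = (hit.biotype, hit.segment)
            type_counts[key] = type_counts.get(key, 0) + 1
            if hit.biotype == "protein_coding" and hit.gene_id not in coding_genes:
                coding_genes.append(hit.gene_id)
    gene_types = [{"biotype": b, "segment": s, "count": c}
                  for (b, s), c in sorted(type_counts.items())]

    expr = pd.DataFrame()
    if function_index is not None and coding_genes:
        data = {g: function_index.get(g).expression for g in coding_genes}
        data = {g: v for g, v in data.items() if v}
        if data:
            expr = pd.DataFrame.from_dict(data, orient="index").fillna(0.0)
            expr.index.name = "gene_id"

    return ChartBundle(
        locations=dict(sorted(locations.items())),
        gene_types=gene_types,
        risk_labels=risk_distribution(labels),
        expression=expr,
    )


def build_database_tables(annotations: Sequence[SiteAnnotation],
                          function_index: Optional[GeneFunctionIndex] = None
                          ) -> dict[str, pd.DataFrame]:
    """Per-database result tables, one frame per annotation resource."""
    def site_cols(ann: SiteAnnotation) -> dict:
        s = ann.site
        return {"chrom": s.chrom, "start": s.start, "end": s.end, "strand": s.strand}

    gencode, mirgene, remap, enhancer, pfam, targetscan = [], [], [], [], [], []
    omim, tfrows, rbp, cosmic, expr_gene_ids = [], [], [], [], []
    for ann in annotations:
        base = site_cols(ann)
        for h in ann.gene_hits:
            gencode.append({**base, "gene_id": h.gene_id, "gene_name": h.gene_name,
                            "biotype": h.biotype, "segment": h.segment})
            if h.biotype == "protein_coding" and h.gene_id not in expr_gene_ids:
                expr_gene_ids.append(h.gene_id)
        for h in ann.mirna_gene_hits:
            mirgene.append({**base, "mirna": h.feature_name})
        in_promoter = {p.feature_name for p in ann.peaks_in_promoters}
        for h in ann.regulator_peak_hits:
            remap.append({**base, "peak": h.feature_name,
                          "in_promoter": h.feature_name in in_promoter})
        for h in ann.promoter_hits:
            remap.append({**base, "peak": "", "promoter": h.feature_name,
                          "linked_gene": h.linked_gene_id or ""})
        for h in ann.enhancer_hits:
            enhancer.append({**base, "enhancer": h.feature_name,
                             "linked_gene": h.linked_gene_id or ""})
        for h in ann.domain_hits:
            pfam.append({**base, "domain": h.feature_name})
        for h in ann.mirna_target_hits:
            targetscan.append({**base, "target_site": h.feature_name,
                               "linked_gene": h.linked_gene_id or ""})
        for gid, rec in ann.functional.items():
            for p in rec.phenotypes:
                omim.append({**base, "gene_id": gid, "phenotype": p})
            if rec.tf_class != "none":
                tfrows.append({**base, "gene_id": gid, "tf_class": rec.tf_class})
            for fn in rec.rbp_functions:
                rbp.append({**base, "gene_id": gid, "function": fn})
            if rec.is_cancer_gene:
                cosmic.append({**base, "gene_id": gid})

    expr_rows = []
    if function_index is not None:
        for gid in expr_gene_ids:
            rec = function_index.get(gid)
            for tissue, level in rec.expression.items():
                expr_rows.append({"gene_id": gid, "tissue": tissue, "tpm": level})

    return {
        "gencode": pd.DataFrame(gencode),
        "mirgene": pd.DataFrame(mirgene),
        "remap_epd": pd.DataFrame(remap),
        "enhancer": pd.DataFrame(enhancer),
        "pfam": pd.DataFrame(pfam),
        "targetscan": pd.DataFrame(targetscan),
        "omim": pd.DataFrame(omim),
        "tf": pd.DataFrame(tfrows),
        "expression": pd.DataFrame(expr_rows),
        "rbp": pd.DataFrame(rbp),
        "cosmic": pd.DataFrame(cosmic),
    }


def export(summary: pd.DataFrame, charts: ChartBundle,
           per_db_tables: Mapping[str, pd.DataFrame], out_dir: str | Path,
           fmt: str = "csv", sites: Optional[Sequence[OffTargetSite]] = None
           ) -> list[Path]:
    """Write all result tables in the requested format.

    csv: ``summary.csv`` + ``charts.json`` + ``tables/<db>.tsv``;
    xlsx: one workbook with one sheet per table;
    json: a single ``results.json`` with keys summary/charts/tables.
    A ``sites.bed`` is written alongside when sites are given.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "csv":
        p = out_dir / "summary.csv"
        summary.to_csv(p, index=False)
        written.append(p)
        tdir = out_dir / "tables"
        tdir.mkdir(exist_ok=True)
        for name, df in per_db_tables.items():
            tp = tdir / f"{name}.tsv"
            df.to_csv(tp, sep="\t", index=False)
            written.append(tp)
        cp = out_dir / "charts.json"
        cp.write_text(json.dumps(charts.to_jsonable(), indent=2, sort_keys=True))
        written.append(cp)
    elif fmt == "xlsx":
        p = out_dir / "summary.xlsx"
        with pd.ExcelWriter(p, engine="openpyxl") as xw:
            summary.to_excel(xw, sheet_name="summary", index=False)
            for name, df in per_db_tables.items():
                df.to_excel(xw, sheet_name=name[:31], index=False)
        written.append(p)
        cp = out_dir / "charts.json"
        cp.write_text(json.dumps(charts.to_jsonable(), indent=2, sort_keys=True))
        written.append(cp)
    elif fmt == "json":
        doc = {
            "summary": summary.to_dict(orient="records"),
            "charts": charts.to_jsonable(),
            "tables": {name: df.to_dict(orient="records")
                       for name, df in per_db_tables.items()},
        }
        p = out_dir / "results.json"
        p.write_text(json.dumps(doc, indent=2, sort_keys=True))
        written.append(p)
    else:
        raise ValueError(f"unknown export format {fmt!r} (expected csv/xlsx/json)")
    if sites is not None:
        bp = out_dir / "sites.bed"
        write_sites_bed(sites, bp)
        written.append(bp)
    return written


def render_html(summary: pd.DataFrame, charts: ChartBundle, out_path: str | Path) -> Path:
    """Minimal static self-contained HTML report: the color-coded summary
    table plus the chart datasets as preformatted JSON."""
    out_path = Path(out_path)
    color_col = summary.columns.get_loc("color") if "color" in summary.columns else None
    rows_html = []
    for _, row in summary.iterrows():
        color = row["color"] if color_col is not None else "white"
        cells = "".join(f"<td>{v}</td>" for v in row)
        rows_html.append(f'<tr style="background-color:{color}">{cells}</tr>')
    header = "".join(f"<th>{c}</th>" for c in summary.columns)
    html = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>off-target risk report</title>"
        "<style>table{border-collapse:collapse}td,th{border:1px solid #999;"
        "padding:2px 6px;font:12px sans-serif}</style></head><body>"
        f"<h1>Off-target risk report</h1><table><tr>{header}</tr>"
        f"{''.join(rows_html)}</table><h2>Charts</h2><pre>"
        f"{json.dumps(charts.to_jsonable(), indent=2, sort_keys=True)}"
        "</pre></body></html>"
    )
    out_path.write_text(html)
    return out_path
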