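"""Per-site aggregation of interval overlaps and gene-function lookups.

Each off-target site receives one SiteAnnotation collecting every gene it
overlaps (with the gene segment hit), every regulatory/auxiliary feature
overlap, and the functional record of every gene implicated directly or via
a linked regulatory element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .annotation_store import (
    AnnotationTrack,
    GeneFunctionIndex,
    GeneFunctionRecord,
    GeneModel,
    GeneModelSet,
    TrackRecord,
)
from .interval_engine import Overlap, intersect
from .sequence_search import OffTargetSite

# precedence when a site straddles segment boundaries
_SEGMENT_PRECEDENCE = ("CDS", "5UTR", "3UTR", "exon", "intron")

EXONIC_SEGMENTS = frozenset({"CDS", "5UTR", "3UTR", "exon"})


@dataclass(frozen=True)
class GeneHit:
    gene_id: str
    gene_name: str
    biotype: str
    segment: str


@dataclass(frozen=True)
class FeatureHit:
    feature_name: str
    linked_gene_id: Optional[str]


@dataclass
class SiteAnnotation:
    """Aggregated evidence for one off-target site."""

    site: OffTargetSite
    gene_hits: list[GeneHit] = field(default_factory=list)
    promoter_hits: list[FeatureHit] = field(default_factory=list)
    enhancer_hits: list[FeatureHit] = field(default_factory=list)
    regulator_peak_hits: list[FeatureHit] = field(default_factory=list)
    domain_hits: list[FeatureHit] = field(default_factory=list)
    mirna_gene_hits: list[FeatureHit] = field(default_factory=list)
    mirna_target_hits: list[FeatureHit] = field(default_factory=list)
    # regulator peaks that additionally fall inside a promoter window
    peaks_in_promoters: list[FeatureHit] = field(default_factory=list)
    functional: dict[str, GeneFunctionRecord] = field(default_factory=dict)

    @property
    def inside_coding_transcribed_region(self) -> bool:
        return any(h.biotype == "protein_coding" for h in self.gene_hits)

    @property
    def hit_gene_ids(self) -> list[str]:
        seen: list[str] = []
        for h in self.gene_hits:
            if h.gene_id not in seen:
                seen.append(h.gene_id)
        for hits in (self.promoter_hits, self.enhancer_hits):
            for fh in hits:
                if fh.linked_gene_id and fh.linked_gene_id not in seen:
                    seen.append(fh.linked_gene_id)
        return seen


def classify_segment(site: OffTargetSite, gene: GeneModel) -> str:
    """Label the gene segment a site hits, with precedence
    CDS > 5UTR/3UTR > exon > intron when the site straddles boundaries.

    The site must overlap the gene span; anything else is a caller bug.
    """
    if site.chrom != gene.chrom or site.end <= gene.start or site.start >= gene.end:
        raise ValueError(
            f"site {site.chrom}:{site.start}-{site.end} does not overlap "
            f"gene {gene.gene_id} span {gene.chrom}:{gene.start}-{gene.end}")
    for label in _SEGMENT_PRECEDENCE:
        for s, e in gene.segments.get(label, ()):
            if site.start < e and site.end > s:
                return label
    # a gene span is exon ∪ intron by construction, so this is unreachable
    raise AssertionError("segment classification fell through")  # pragma: no cover


def annotate_site(site: OffTargetSite, overlaps: Sequence[Overlap],
                  gene_models: GeneModelSet,
                  function_index: GeneFunctionIndex) -> SiteAnnotation:
    """Compose one SiteAnnotation from this site's overlaps.

    ``overlaps`` must all refer to ``site``; missing function data yields
    empty records, never an error.
    """
    ann = SiteAnnotation(site=site)
    bucket = {
        "promoter": ann.promoter_hits,
        "enhancer": ann.enhancer_hits,
        "regulator_peak": ann.regulator_peak_hits,
        "protein_domain": ann.domain_hits,
        "mirna_gene": ann.mirna_gene_hits,
        "mirna_target": ann.mirna_target_hits,
    }
    for ov in overlaps:
        if ov.kind == "gene":
            gene = gene_models.get(ov.record.name)
            if gene is None:
                continue
            ann.gene_hits.append(GeneHit(
                gene_id=gene.gene_id, gene_name=gene.gene_name,
                biotype=gene.biotype, segment=classify_segment(site, gene)))
        elif ov.kind in bucket:
            bucket[ov.kind].append(FeatureHit(
                feature_name=ov.record.name,
                linked_gene_id=ov.record.linked_gene_id))
    # regulator peaks are reported independently of promoters; those that
    # co-occur with a promoter hit at this site are additionally flagged
    if ann.regulator_peak_hits and ann.promoter_hits:
        ann.peaks_in_promoters = list(ann.regulator_peak_hits)
    for gid in ann.hit_gene_ids:
        ann.functional[gid] = function_index.get(gid)
    return ann


def annotate_sites(sites: Sequence[OffTargetSite],
                   gene_models: Optional[GeneModelSet],
                   tracks: Sequence[AnnotationTrack],
                   function_index: Optional[GeneFunctionIndex] = None,
                   min_overlap: int = 1) -> list[SiteAnnotation]:
    """Annotate every site against gene models and all given tracks.

    Runs one intersection per layer, groups overlaps per site, and returns
    one SiteAnnotation per input site in input order.
    """
    if function_index is None:
        function_index = GeneFunctionIndex()
    gms = gene_models or GeneModelSet()
    per_site: list[list[Overlap]] = [[] for _ in sites]
    layers: list[tuple[str, Sequence[TrackRecord]]] = []
    if gene_models is not None:
        layers.append(("gene", gene_models.gene_span_records()))
    for track in tracks:
        layers.append((track.kind, track.records))
    for kind, records in layers:
        for ov in intersect(sites, records, kind=kind, min_overlap=min_overlap):
            per_site[ov.site_index].append(ov)
    return [annotate_site(site, per_site[i], gms, function_index)
            for i, site in enumerate(sites)]
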