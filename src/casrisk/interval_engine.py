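"""Interval intersection with BEDTools-like semantics.

Half-open [start, end) intervals; overlap requires at least ``min_overlap``
shared bases on the same chromosome, so intervals that merely touch at an
endpoint do not overlap.  Strand is ignored for overlap testing (Cas9 cuts
double-stranded DNA, so feature disruption is strand-independent) but kept
on the records for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from intervaltree import IntervalTree

from .annotation_store import TrackRecord
from .sequence_search import OffTargetSite


@dataclass(frozen=True)
class Overlap:
    """One (site, feature) overlap pair."""

    site_index: int
    site: OffTargetSite
    record_index: int
    record: TrackRecord
    kind: str
    overlap_bp: int


def intersect(sites: Sequence[OffTargetSite], records: Sequence[TrackRecord],
              kind: str = ".", min_overlap: int = 1) -> list[Overlap]:
    """All (site, record) pairs sharing >= min_overlap bases.

    Output is ordered by (site index, record index).  Equivalent to
    ``bedtools intersect -wa -wb`` on the two interval sets.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for ri, rec in enumerate(records):
        trees.setdefault(rec.chrom, IntervalTree()).addi(rec.start, rec.end, ri)
    out: list[Overlap] = []
    for si, site in enumerate(sites):
        tree = trees.get(site.chrom)
        if tree is None:
            continue
        hits = []
        for iv in tree.overlap(site.start, site.end):
            bp = min(site.end, iv.end) - max(site.start, iv.begin)
            if bp >= min_overlap:
                hits.append((iv.data, bp))
        for ri, bp in sorted(hits):
            out.append(Overlap(site_index=si, site=site, record_index=ri,
                               record=records[ri], kind=kind, overlap_bp=bp))
    return out


def dump_pairs_tsv(overlaps: Sequence[Overlap], path: str | Path) -> None:
    """Debug dump mirroring ``bedtools intersect -wa -wb`` column order:
    site BED6 columns, then feature BED6+gene columns, then overlap bp."""
    with open(path, "w") as fh:
        for ov in overlaps:
            s, r = ov.site, ov.record
            mm = "." if s.mismatches is None else str(s.mismatches)
            fh.write("\t".join([
                s.chrom, str(s.start), str(s.end), s.name or ".", mm, s.strand,
                r.chrom, str(r.start), str(r.end), r.name, ".", r.strand,
                r.linked_gene_id or ".", str(ov.overlap_bp),
            ]) + "\n")
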