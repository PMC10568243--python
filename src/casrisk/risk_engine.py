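"""Rule-based risk labeling of annotated off-target sites.

Each site gets one composite label, tier x region:

  high-coding        exonic hit (CDS/UTR/exon) in a protein-coding gene with
                     disease evidence (known phenotype or cancer role)
  medium-coding      exonic hit in a protein-coding gene without such evidence
  low-coding         intronic hit in a protein-coding gene
  medium-noncoding   exonic hit in a non-protein-coding gene (lncRNA, miRNA,
                     pseudogene, TEC, ...)
  low-noncoding      intronic hit in a non-protein-coding gene
  medium-regulatory  no gene overlap, but the site falls in a promoter or
                     enhancer linked to a gene with disease evidence
  low-regulatory     promoter/enhancer hit linked to genes without evidence
  none               no qualifying overlap (intergenic)

When a site qualifies under several genes or features, the highest-severity
outcome wins under the total order below.  A site overlapping any gene never
receives a regulatory label.  TF/co-TF and RBP status, mismatch counts,
regulator peaks, protein domains and miRNA features annotate the site but do
not change its tier.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .site_annotator import EXONIC_SEGMENTS, SiteAnnotation

#: total severity order, most severe first
SEVERITY_ORDER: tuple[str, ...] = (
    "high-coding",
    "medium-coding",
    "medium-noncoding",
    "medium-regulatory",
    "low-coding",
    "low-noncoding",
    "low-regulatory",
    "none",
)

_RANK = {label: i for i, label in enumerate(SEVERITY_ORDER)}

_COLOR_BY_TIER = {"high": "red", "medium": "orange", "low": "yellow", "none": "green"}


@dataclass(frozen=True)
class RiskLabel:
    tier: str              # high | medium | low | none
    region: str            # coding | noncoding | regulatory | intergenic
    rationale: str         # fired rule id, e.g. "coding.exonic.disease"

    @property
    def label(self) -> str:
        return "none" if self.tier == "none" else f"{self.tier}-{self.region}"

    @property
    def color(self) -> str:
        return _COLOR_BY_TIER[self.tier]


_LABEL_TO_RISK = {
    "high-coding": ("high", "coding"),
    "medium-coding": ("medium", "coding"),
    "low-coding": ("low", "coding"),
    "medium-noncoding": ("medium", "noncoding"),
    "low-noncoding": ("low", "noncoding"),
    "medium-regulatory": ("medium", "regulatory"),
    "low-regulatory": ("low", "regulatory"),
    "none": ("none", "intergenic"),
}


def assign_risk(annotation: SiteAnnotation) -> RiskLabel:
    """Assign the risk label for one annotated site.

    Candidate labels are collected from every overlapped gene — coding-branch
    labels for protein-coding genes, noncoding-branch labels otherwise.  Only
    when the site overlaps no gene at all do promoter/enhancer hits produce
    regulatory candidates.  The final label is the maximum-severity candidate.
    """
    candidates: list[tuple[str, str]] = []  # (label, rationale)
    for hit in annotation.gene_hits:
        exonic = hit.segment in EXONIC_SEGMENTS
        if hit.biotype == "protein_coding":
            if exonic:
                rec = annotation.functional.get(hit.gene_id)
                if rec is not None and rec.has_disease_evidence:
                    candidates.append(("high-coding", "coding.exonic.disease"))
                else:
                    candidates.append(("medium-coding", "coding.exonic"))
            else:
                candidates.append(("low-coding", "coding.intronic"))
        else:
            if exonic:
                candidates.append(("medium-noncoding", "noncoding.exonic"))
            else:
                candidates.append(("low-noncoding", "noncoding.intronic"))
    if not annotation.gene_hits:
        for branch, hits in (("promoter", annotation.promoter_hits),
                             ("enhancer", annotation.enhancer_hits)):
            for fh in hits:
                rec = (annotation.functional.get(fh.linked_gene_id)
                       if fh.linked_gene_id else None)
                if rec is not None and rec.has_disease_evidence:
                    candidates.append(("medium-regulatory", f"regulatory.{branch}.disease"))
                else:
                    candidates.append(("low-regulatory", f"regulatory.{branch}"))
    if not candidates:
        return RiskLabel(tier="none", region="intergenic", rationale="intergenic")
    label, rationale = min(candidates, key=lambda c: _RANK[c[0]])
    tier, region = _LABEL_TO_RISK[label]
    return RiskLabel(tier=tier, region=region, rationale=rationale)


def assign_risks(annotations: Sequence[SiteAnnotation]) -> list[RiskLabel]:
    return [assign_risk(a) for a in annotations]


def risk_distribution(labels: Iterable[RiskLabel | str]) -> dict[str, int]:
    """Count sites per label over the full label vocabulary (zeros included)."""
    counts = Counter(l if isinstance(l, str) else l.label for l in labels)
    unknown = set(counts) - set(SEVERITY_ORDER)
    if unknown:
        raise ValueError(f"unknown risk labels: {sorted(unknown)}")
    return {label: counts.get(label, 0) for label in SEVERITY_ORDER}
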