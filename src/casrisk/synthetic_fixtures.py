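"""Self-contained synthetic test worlds with planted ground truth.

A fixture is a small genome plus every annotation layer the pipeline
consumes (gene models, promoters, enhancers, regulator peaks, protein
domains, miRNA loci/targets, gene-function TSVs) with a manifest that fully
determines the expected pipeline output: which sites the search must find
(with exact mismatch counts), how each site must be annotated, and which
risk label it must receive.

Planted protospacers carry exactly the intended number of mismatches next to
a concrete PAM; the random background is screened with an internal
brute-force scan so no unplanned site exists within the mismatch budget
(re-sampling the background until clean).  Genomes stay small (tens of kb)
so that screening is instant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .sequence_search import IUPAC, revcomp

BASES = "ACGT"

#: annotation context of a planted site -> the risk label it must receive
CONTEXT_LABELS = {
    "exon_disease": "high-coding",        # exonic in coding gene w/ phenotype
    "exon_cancer": "high-coding",         # exonic in coding cancer gene
    "exon_plain": "medium-coding",
    "intron": "low-coding",
    "noncoding_exon": "medium-noncoding",
    "noncoding_intron": "low-noncoding",
    "promoter_disease": "medium-regulatory",
    "promoter_plain": "low-regulatory",
    "enhancer_disease": "medium-regulatory",
    "enhancer_plain": "low-regulatory",
    "intergenic": "none",
}

_GENE_CONTEXTS = {"exon_disease", "exon_cancer", "exon_plain", "intron",
                  "noncoding_exon", "noncoding_intron"}
_REGULATORY_CONTEXTS = {"promoter_disease", "promoter_plain",
                        "enhancer_disease", "enhancer_plain"}


@dataclass(frozen=True)
class PlantedSite:
    mismatches: int
    context: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.context not in CONTEXT_LABELS:
            raise ValueError(f"unknown context {self.context!r}")


def default_site_plan() -> list[PlantedSite]:
    """The standard study world: mismatch histogram {0:1, 2:1, 3:3, 4:5}
    spread across coding genes, noncoding genes, promoters and enhancers
    with known disease/cancer flags, plus one intergenic site."""
    return [
        PlantedSite(0, "exon_disease"),           # the on-target analog
        PlantedSite(2, "exon_plain"),
        PlantedSite(3, "intron"),
        PlantedSite(3, "noncoding_exon"),
        PlantedSite(3, "promoter_disease"),
        PlantedSite(4, "enhancer_plain"),
        PlantedSite(4, "intergenic", strand="-"),
        PlantedSite(4, "noncoding_intron"),
        PlantedSite(4, "promoter_plain"),
        PlantedSite(4, "exon_cancer"),
    ]


@dataclass
class FixtureSpec:
    """Counts, mismatch plan and annotation plan for one synthetic world."""

    sites: list[PlantedSite] = field(default_factory=default_site_plan)
    guide: Optional[str] = None               # random 20-mer when None
    guide_length: int = 20
    pam: str = "NGG"
    chrom: str = "chr1"
    genome_length: int = 20000
    max_mismatches: int = 4
    tissues: tuple[str, ...] = ("blood", "brain", "liver")


@dataclass
class FixtureManifest:
    """Ground truth: fully determines the expected pipeline output."""

    seed: int
    guide: str
    pam: str
    chrom: str
    genome_length: int
    max_mismatches: int
    sites: list[dict] = field(default_factory=list)
    genes: list[dict] = field(default_factory=list)
    mismatch_histogram: dict[str, int] = field(default_factory=dict)
    expected_risk_distribution: dict[str, int] = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


class InfeasibleFixtureError(ValueError):
    """The requested world does not fit in the requested genome."""


# --------------------------------------------------------------------------
# internal brute-force screen (kept deliberately simple and scan-everything)
# --------------------------------------------------------------------------

def _scan_hits(seq: str, guide: str, pam: str, max_mm: int) -> set[tuple[int, int, str, int]]:
    """All (start, end, strand, mm) protospacer hits with a matching PAM."""
    hits: set[tuple[int, int, str, int]] = set()
    L, plen, n = len(guide), len(pam), len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for i in range(n - L - plen + 1):
            pam_seq = s[i + L:i + L + plen]
            if any(b not in "ACGT" or b not in IUPAC[p] for p, b in zip(pam, pam_seq)):
                continue
            mm = sum(1 for a, b in zip(guide, s[i:i + L]) if a != b or b not in "ACGT")
            if mm <= max_mm:
                if strand == "+":
                    hits.add((i, i + L, "+", mm))
                else:
                    hits.add((n - (i + L), n - i, "-", mm))
    return hits


def _mutate(guide: str, k: int, rng: np.random.Generator) -> str:
    pos = rng.choice(len(guide), size=k, replace=False)
    out = list(guide)
    for p in pos:
        out[p] = rng.choice([b for b in BASES if b != out[p]])
    return "".join(out)


# --------------------------------------------------------------------------
# generator
# --------------------------------------------------------------------------

def make_fixture(spec: FixtureSpec, seed: int, out_dir: str | Path) -> FixtureManifest:
    """Generate all fixture files plus the ground-truth manifest.

    Files written: genome.fa, genes.gff3, promoters.bed, enhancers.bed,
    regulator_peaks.bed, domains.bed, mirna_genes.bed, mirna_targets.bed,
    phenotypes.tsv, cancer_genes.tsv, tf.tsv, rbp.tsv, expression.tsv,
    config.yaml, manifest.json.  Same spec + same seed => byte-identical
    files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n_sites = len(spec.sites)
    slot = spec.genome_length // max(1, n_sites)
    L = spec.guide_length
    footprint = L + len(spec.pam)
    if slot < max(1400, footprint + 200):
        raise InfeasibleFixtureError(
            f"genome of {spec.genome_length} bp cannot host {n_sites} planted "
            f"sites with their annotation contexts (need >= "
            f"{n_sites * max(1400, footprint + 200)} bp)")

    guide = spec.guide or "".join(rng.choice(list(BASES), size=L))
    guide = guide.upper()
    pam_concrete = "".join(b if b in "ACGT" else rng.choice(list(IUPAC[b]))
                           for b in spec.pam)

    # place each site near the centre of its slot
    placements: list[dict] = []
    for idx, ps in enumerate(spec.sites):
        centre = idx * slot + slot // 2
        q = int(centre + rng.integers(-slot // 8, slot // 8 + 1))
        proto = _mutate(guide, ps.mismatches, rng)
        insert = proto + pam_concrete
        if ps.strand == "-":
            insert = revcomp(insert)
            start, end = q + len(spec.pam), q + footprint
        else:
            start, end = q, q + L
        placements.append({
            "q": q, "insert": insert, "start": start, "end": end,
            "strand": ps.strand, "mismatches": ps.mismatches,
            "context": ps.context, "site_sequence": proto,
            "expected_label": CONTEXT_LABELS[ps.context],
        })

    expected_hits = {(p["start"], p["end"], p["strand"], p["mismatches"])
                     for p in placements}
    genome_seq = ""
    for _attempt in range(50):
        bg = rng.choice(list(BASES), size=spec.genome_length)
        seq = list("".join(bg))
        for p in placements:
            seq[p["q"]:p["q"] + footprint] = p["insert"]
        candidate = "".join(seq)
        found = _scan_hits(candidate, guide, spec.pam, spec.max_mismatches)
        if found == expected_hits:
            genome_seq = candidate
            break
    else:
        raise InfeasibleFixtureError(
            "could not screen a clean background in 50 attempts; "
            "genome too dense for the requested mismatch budget")

    # ---- annotations ------------------------------------------------------
    genes: list[dict] = []
    gff_lines: list[str] = []
    promoters: list[str] = []
    enhancers: list[str] = []
    peaks: list[str] = []
    domains: list[str] = []
    phen_rows: list[tuple[str, str]] = []
    cancer_rows: list[str] = []
    tf_rows: list[tuple[str, str]] = []
    rbp_rows: list[tuple[str, str]] = []
    expr_rows: list[tuple[str, list[float]]] = []
    chrom = spec.chrom

    def new_gene(i: int) -> str:
        return f"GENE{i:04d}"

    for i, p in enumerate(placements):
        ctx = p["context"]
        if ctx == "intergenic":
            continue
        gid = new_gene(i + 1)
        gname = f"gene{i + 1}"
        s, e = p["start"], p["end"]
        if ctx in _GENE_CONTEXTS:
            biotype = ("protein_coding" if ctx.startswith(("exon", "intron"))
                       else "lncRNA")
            g0, g1 = s - 300, e + 300
            if ctx in ("intron", "noncoding_intron"):
                exons = [(g0, g0 + 60), (g1 - 60, g1)]
            else:
                exons = [(g0, e + 50), (g1 - 80, g1)]
            cds = []
            if ctx in ("exon_disease", "exon_cancer"):
                cds = [(s - 10, e + 10)]
            genes.append({"gene_id": gid, "gene_name": gname, "biotype": biotype,
                          "chrom": chrom, "start": g0, "end": g1, "strand": "+",
                          "context": ctx, "exons": exons, "cds": cds})
            gff_lines.append(
                f"{chrom}\tsynth\tgene\t{g0 + 1}\t{g1}\t.\t+\t.\t"
                f"ID={gid};gene_id={gid};gene_name={gname};gene_biotype={biotype}")
            tid = f"{gid}.t1"
            gff_lines.append(
                f"{chrom}\tsynth\ttranscript\t{g0 + 1}\t{g1}\t.\t+\t.\t"
                f"ID={tid};Parent={gid};transcript_id={tid}")
            for xs, xe in exons:
                gff_lines.append(
                    f"{chrom}\tsynth\texon\t{xs + 1}\t{xe}\t.\t+\t.\tParent={tid}")
            for cs, ce in cds:
                gff_lines.append(
                    f"{chrom}\tsynth\tCDS\t{cs + 1}\t{ce}\t.\t+\t0\tParent={tid}")
            if ctx == "exon_disease":
                phen_rows.append((gid, "synthetic recessive disorder"))
            if ctx == "exon_cancer":
                cancer_rows.append(gid)
            if biotype == "protein_coding":
                expr_rows.append((gid, [round(float(v), 2)
                                        for v in rng.gamma(2.0, 20.0, len(spec.tissues))]))
        elif ctx in _REGULATORY_CONTEXTS:
            # linked gene placed clear of the site so no gene overlap occurs
            g0, g1 = e + 200, e + 800
            genes.append({"gene_id": gid, "gene_name": gname,
                          "biotype": "protein_coding", "chrom": chrom,
                          "start": g0, "end": g1, "strand": "+",
                          "context": ctx, "exons": [(g0, g1)], "cds": []})
            gff_lines.append(
                f"{chrom}\tsynth\tgene\t{g0 + 1}\t{g1}\t.\t+\t.\t"
                f"ID={gid};gene_id={gid};gene_name={gname};gene_biotype=protein_coding")
            tid = f"{gid}.t1"
            gff_lines.append(
                f"{chrom}\tsynth\ttranscript\t{g0 + 1}\t{g1}\t.\t+\t.\t"
                f"ID={tid};Parent={gid};transcript_id={tid}")
            gff_lines.append(
                f"{chrom}\tsynth\texon\t{g0 + 1}\t{g1}\t.\t+\t.\tParent={tid}")
            rec = f"{chrom}\t{s - 50}\t{e + 50}\t{gid}_reg\t0\t+\t{gid}"
            if ctx.startswith("promoter"):
                promoters.append(rec)
            else:
                enhancers.append(rec)
            if ctx.endswith("_disease"):
                if ctx.startswith("enhancer"):
                    cancer_rows.append(gid)      # cancer role, no phenotype
                else:
                    phen_rows.append((gid, "synthetic dominant disorder"))
            expr_rows.append((gid, [round(float(v), 2)
                                    for v in rng.gamma(2.0, 20.0, len(spec.tissues))]))

    for g in genes:
        if g["start"] < 0 or g["end"] > spec.genome_length:
            raise InfeasibleFixtureError(
                f"gene {g['gene_id']} ({g['context']}) at [{g['start']}, "
                f"{g['end']}) falls outside the {spec.genome_length} bp genome")

    # auxiliary layers: a regulator peak on the first promoter site, a protein
    # domain on the first exonic site, TF/RBP flags, and miRNA decoys that no
    # planted site touches
    first_prom = next((p for p in placements if p["context"].startswith("promoter")), None)
    if first_prom is not None:
        peaks.append(f"{chrom}\t{first_prom['start'] - 20}\t{first_prom['end'] + 20}\t"
                     f"TFpeak1\t0\t.")
    first_exonic = next((p for p in placements if p["context"].startswith("exon")), None)
    if first_exonic is not None:
        domains.append(f"{chrom}\t{first_exonic['start'] - 5}\t{first_exonic['end'] + 5}\t"
                       f"DomainA\t0\t+")
    coding_gene_ids = [g["gene_id"] for g in genes if g["biotype"] == "protein_coding"]
    if coding_gene_ids:
        tf_rows.append((coding_gene_ids[0], "TF"))
        if len(coding_gene_ids) > 1:
            tf_rows.append((coding_gene_ids[1], "co-TF"))
        rbp_rows.append((coding_gene_ids[-1], "RNA stability and decay"))
    mirna_genes = [f"{chrom}\t{spec.genome_length - 120}\t{spec.genome_length - 40}\t"
                   f"mir-syn-1\t0\t+"]
    mirna_targets = [f"{chrom}\t{spec.genome_length - 260}\t{spec.genome_length - 200}\t"
                     f"mir-syn-1-target\t0\t+\t"
                     f"{coding_gene_ids[0] if coding_gene_ids else '.'}"]

    # ---- write files ------------------------------------------------------
    files = {
        "genome": "genome.fa", "gene_models": "genes.gff3",
        "promoters": "promoters.bed", "enhancers": "enhancers.bed",
        "regulator_peaks": "regulator_peaks.bed", "protein_domains": "domains.bed",
        "mirna_genes": "mirna_genes.bed", "mirna_targets": "mirna_targets.bed",
        "phenotypes": "phenotypes.tsv", "cancer_genes": "cancer_genes.tsv",
        "tf": "tf.tsv", "rbp": "rbp.tsv", "expression": "expression.tsv",
        "config": "config.yaml", "manifest": "manifest.json",
    }

    with open(out_dir / files["genome"], "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome_seq), 70):
            fh.write(genome_seq[i:i + 70] + "\n")
    (out_dir / files["gene_models"]).write_text(
        "##gff-version 3\n" + "\n".join(gff_lines) + ("\n" if gff_lines else ""))
    for key, lines in (("promoters", promoters), ("enhancers", enhancers),
                       ("regulator_peaks", peaks), ("protein_domains", domains),
                       ("mirna_genes", mirna_genes), ("mirna_targets", mirna_targets)):
        (out_dir / files[key]).write_text("\n".join(lines) + ("\n" if lines else ""))
    (out_dir / files["phenotypes"]).write_text(
        "gene_id\tphenotype\n" + "".join(f"{g}\t{p}\n" for g, p in phen_rows))
    (out_dir / files["cancer_genes"]).write_text(
        "gene_id\n" + "".join(f"{g}\n" for g in cancer_rows))
    (out_dir / files["tf"]).write_text(
        "gene_id\ttf_class\n" + "".join(f"{g}\t{c}\n" for g, c in tf_rows))
    (out_dir / files["rbp"]).write_text(
        "gene_id\tfunction\n" + "".join(f"{g}\t{f}\n" for g, f in rbp_rows))
    (out_dir / files["expression"]).write_text(
        "gene_id\t" + "\t".join(spec.tissues) + "\n" +
        "".join(g + "\t" + "\t".join(str(v) for v in vals) + "\n"
                for g, vals in expr_rows))
    (out_dir / files["config"]).write_text(_config_yaml(spec, files))

    hist: dict[str, int] = {}
    dist: dict[str, int] = {}
    for p in placements:
        hist[str(p["mismatches"])] = hist.get(str(p["mismatches"]), 0) + 1
        dist[p["expected_label"]] = dist.get(p["expected_label"], 0) + 1
    manifest = FixtureManifest(
        seed=seed, guide=guide, pam=spec.pam, chrom=chrom,
        genome_length=spec.genome_length, max_mismatches=spec.max_mismatches,
        sites=[{k: p[k] for k in ("start", "end", "strand", "mismatches",
                                  "context", "site_sequence", "expected_label")}
               for p in placements],
        genes=genes, mismatch_histogram=hist,
        expected_risk_distribution=dist, files=files)
    (out_dir / files["manifest"]).write_text(manifest.to_json() + "\n")
    return manifest


def _config_yaml(spec: FixtureSpec, files: dict[str, str]) -> str:
    db_keys = ("gene_models", "promoters", "enhancers", "regulator_peaks",
               "protein_domains", "mirna_genes", "mirna_targets", "phenotypes",
               "cancer_genes", "tf", "rbp", "expression")
    lines = [f"genome: {files['genome']}", "databases:"]
    lines += [f"  {k}: {files[k]}" for k in db_keys]
    lines += [
        "search:",
        f"  pam: {spec.pam}",
        f"  max_mismatches: {spec.max_mismatches}",
        "  max_dna_bulges: 0",
        "  max_rna_bulges: 0",
        "promoter_window:",
        "  upstream: 499",
        "  downstream: 100",
    ]
    return "\n".join(lines) + "\n"
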