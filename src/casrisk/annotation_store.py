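"""Loading and indexing of annotation layers.

Gene models come from GFF3/GTF (GENCODE-style), interval tracks (promoters,
enhancers, regulator peaks, protein domains, miRNA genes/targets) from
BED3-BED6 with an optional trailing linked-gene column, and gene-level
function tables (phenotypes, cancer genes, TF classes, RBP functions, tissue
expression) from TSV keyed by gene ID.

All coordinates are converted to 0-based half-open internally.  Gene-level
segments (exon union, intron, CDS, UTRs) are derived per gene across all
transcripts.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

TRACK_KINDS = ("promoter", "enhancer", "regulator_peak", "protein_domain",
               "mirna_gene", "mirna_target")

SEGMENTS = ("CDS", "5UTR", "3UTR", "exon", "intron")


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackRecord:
    """One interval of an annotation track (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    linked_gene_id: Optional[str] = None


@dataclass
class AnnotationTrack:
    """A homogeneous set of intervals of one kind (promoter, enhancer, ...)."""

    kind: str
    records: list[TrackRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]          # sorted, non-overlapping
    cds: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class GeneModel:
    """A gene with its transcripts and derived gene-level segments.

    ``segments`` maps segment label (CDS/5UTR/3UTR/exon/intron) to merged
    interval lists.  'exon' is the union of exons over all transcripts;
    'intron' is the gene span minus that union.
    """

    gene_id: str
    gene_name: str
    biotype: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)
    segments: dict[str, list[tuple[int, int]]] = field(default_factory=dict)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals into a sorted union."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def subtract_intervals(span: tuple[int, int],
                       holes: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Half-open set difference: span minus a sorted merged list of holes."""
    out: list[tuple[int, int]] = []
    pos = span[0]
    for s, e in holes:
        if s > pos:
            out.append((pos, min(s, span[1])))
        pos = max(pos, e)
        if pos >= span[1]:
            break
    if pos < span[1]:
        out.append((pos, span[1]))
    return [(s, e) for s, e in out if s < e]


@dataclass
class GeneModelSet:
    """Genes indexed by id, with derived segments ready for intersection."""

    genes: dict[str, GeneModel] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def get(self, gene_id: str) -> Optional[GeneModel]:
        return self.genes.get(gene_id) or self.genes.get(strip_version(gene_id))

    def gene_span_records(self) -> list[TrackRecord]:
        """Gene spans as track-like records (name = gene_id) for intersection."""
        return [TrackRecord(g.chrom, g.start, g.end, g.strand, g.gene_id, g.gene_id)
                for g in self.genes.values()]

    def chroms(self) -> set[str]:
        return {g.chrom for g in self.genes.values()}


@dataclass(frozen=True)
class GeneFunctionRecord:
    """Functional attributes of one gene; all fields may be empty."""

    phenotypes: tuple[str, ...] = ()
    is_cancer_gene: bool = False
    tf_class: str = "none"                # TF | co-TF | none
    rbp_functions: tuple[str, ...] = ()
    expression: Mapping[str, float] = field(default_factory=dict)

    @property
    def has_disease_evidence(self) -> bool:
        return bool(self.phenotypes) or self.is_cancer_gene


EMPTY_FUNCTION_RECORD = GeneFunctionRecord()


@dataclass
class GeneFunctionIndex:
    """Per-gene function lookup; unknown genes yield an all-empty record."""

    records: dict[str, GeneFunctionRecord] = field(default_factory=dict)
    tissues: list[str] = field(default_factory=list)

    def get(self, gene_id: str) -> GeneFunctionRecord:
        gid = strip_version(gene_id)
        return self.records.get(gid, EMPTY_FUNCTION_RECORD)

    def __contains__(self, gene_id: str) -> bool:
        return strip_version(gene_id) in self.records


def strip_version(gene_id: str) -> str:
    """Drop a trailing Ensembl-style '.N' version suffix."""
    base, dot, tail = gene_id.rpartition(".")
    if dot and tail.isdigit():
        return base
    return gene_id


# --------------------------------------------------------------------------
# Genome FASTA
# --------------------------------------------------------------------------

def load_genome(fasta_path: str | Path) -> dict[str, str]:
    """Load a (possibly gzipped) multi-FASTA into {name: sequence}.

    Names are the header words up to the first whitespace.  Duplicate names
    are an error; an empty file is an error.
    """
    fasta_path = Path(fasta_path)
    opener = gzip.open if str(fasta_path).endswith(".gz") else open
    genome: dict[str, str] = {}
    with opener(fasta_path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in genome:
                raise ValueError(f"duplicate sequence name {rec.id!r} in {fasta_path}")
            genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ValueError(f"no FASTA records in {fasta_path}")
    return genome


def write_genome(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# --------------------------------------------------------------------------
# Gene models (GFF3/GTF)
# --------------------------------------------------------------------------

_TRANSCRIPT_TYPES = {"transcript", "mRNA", "lnc_RNA", "ncRNA", "miRNA",
                     "pseudogenic_transcript", "unconfirmed_transcript"}


def _attr(feature: gffutils.Feature, *keys: str, default: str = "") -> str:
    for k in keys:
        if k in feature.attributes:
            v = feature.attributes[k]
            if v:
                return v[0]
    return default


def load_gene_models(path: str | Path) -> GeneModelSet:
    """Load gene models from GFF3 or GTF and derive per-gene segments.

    1-based closed input coordinates become 0-based half-open.  Introns are
    the gene span minus the exon union; UTRs are derived from the exon/CDS
    split, strand-aware: exonic bases 5' of the leftmost CDS base are 5'UTR
    on '+' (3'UTR on '-'), and symmetrically at the right flank.  Genes
    without CDS have no UTRs.
    """
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    gms = GeneModelSet()

    # orphan checks: every exon must reach a transcript, every transcript a gene
    for t in db.features_of_type(tuple(_TRANSCRIPT_TYPES)):
        if not any(p.featuretype == "gene" for p in db.parents(t, level=1)):
            raise ValueError(f"transcript {t.id!r} lacks a gene parent")
    for e in db.features_of_type("exon"):
        parents = [p for p in db.parents(e, level=1) if p.featuretype in _TRANSCRIPT_TYPES]
        if not parents:
            raise ValueError(f"exon at {e.seqid}:{e.start}-{e.end} lacks a transcript parent")

    for g in db.features_of_type("gene"):
        gene_id = strip_version(_attr(g, "gene_id", "ID", default=g.id))
        gene = GeneModel(
            gene_id=gene_id,
            gene_name=_attr(g, "gene_name", "Name", default=gene_id),
            biotype=_attr(g, "gene_biotype", "gene_type", "biotype", default="unknown"),
            chrom=g.seqid, start=g.start - 1, end=g.end, strand=g.strand,
        )
        for t in db.children(g, level=1, featuretype=tuple(_TRANSCRIPT_TYPES)):
            exons = sorted((e.start - 1, e.end) for e in db.children(t, featuretype="exon"))
            cds = sorted((c.start - 1, c.end) for c in db.children(t, featuretype="CDS"))
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping exons in transcript {t.id!r}")
            gene.transcripts.append(Transcript(
                transcript_id=_attr(t, "transcript_id", "ID", default=t.id),
                exons=exons, cds=cds))
        gene.segments = derive_segments(gene)
        gms.genes[gene.gene_id] = gene
    return gms


def derive_segments(gene: GeneModel) -> dict[str, list[tuple[int, int]]]:
    """Gene-level segment intervals: exon union, introns, CDS union, UTRs."""
    exon_union = merge_intervals(iv for t in gene.transcripts for iv in t.exons)
    cds_union = merge_intervals(iv for t in gene.transcripts for iv in t.cds)
    introns = subtract_intervals((gene.start, gene.end), exon_union)
    utr5: list[tuple[int, int]] = []
    utr3: list[tuple[int, int]] = []
    if cds_union:
        cds_lo, cds_hi = cds_union[0][0], cds_union[-1][1]
        left = [(s, min(e, cds_lo)) for s, e in exon_union if s < cds_lo]
        right = [(max(s, cds_hi), e) for s, e in exon_union if e > cds_hi]
        left = [(s, e) for s, e in left if s < e]
        right = [(s, e) for s, e in right if s < e]
        if gene.strand == "-":
            utr5, utr3 = right, left
        else:
            utr5, utr3 = left, right
    return {"exon": exon_union, "intron": introns, "CDS": cds_union,
            "5UTR": utr5, "3UTR": utr3}


# --------------------------------------------------------------------------
# Promoters
# --------------------------------------------------------------------------

def derive_promoters(source: GeneModelSet | Iterable[tuple[str, int, str, str]],
                     upstream: int = 499, downstream: int = 100,
                     chrom_lengths: Optional[Mapping[str, int]] = None) -> AnnotationTrack:
    """Derive promoter windows around transcription start sites.

    ``source`` is either a GeneModelSet (TSS = gene 5' end) or an iterable of
    (chrom, tss_position, strand, gene_id) tuples with 0-based TSS.  For a
    '+' strand TSS at p the window is [p-upstream, p+downstream+1), mirrored
    on '-'; windows are clipped to [0, chrom length) when lengths are given.
    The default window matches the common -499..+100 promoter convention.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be >= 0")
    if isinstance(source, GeneModelSet):
        tss_iter = [(g.chrom, g.start if g.strand != "-" else g.end - 1, g.strand, g.gene_id)
                    for g in source.genes.values()]
    else:
        tss_iter = list(source)
    records: list[TrackRecord] = []
    for chrom, p, strand, gene_id in tss_iter:
        if strand == "-":
            s, e = p - downstream, p + upstream + 1
        else:
            s, e = p - upstream, p + downstream + 1
        s = max(0, s)
        if chrom_lengths is not None and chrom in chrom_lengths:
            e = min(e, chrom_lengths[chrom])
        if s < e:
            records.append(TrackRecord(chrom, s, e, strand,
                                       f"{gene_id}_promoter", gene_id))
    return AnnotationTrack(kind="promoter", records=records)


# --------------------------------------------------------------------------
# BED tracks
# --------------------------------------------------------------------------

def load_track(bed_path: str | Path, kind: str) -> AnnotationTrack:
    """Load a BED3-BED6(+linked-gene column) file as one annotation track.

    Column 7 (if present) is the linked gene id.  Malformed lines (fewer
    than 3 columns, non-integer or inverted coordinates, zero-length
    intervals) raise with the 1-based line number.
    """
    records: list[TrackRecord] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{bed_path} line {lineno}: expected >=3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise ValueError(f"{bed_path} line {lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise ValueError(f"{bed_path} line {lineno}: invalid interval [{start}, {end})")
            name = cols[3] if len(cols) > 3 and cols[3] else "."
            strand = cols[5] if len(cols) > 5 and cols[5] in ("+", "-") else "."
            linked = None
            if len(cols) > 6 and cols[6] not in ("", "."):
                linked = strip_version(cols[6])
            elif kind in ("promoter", "enhancer", "mirna_target") and len(cols) == 4:
                # BED4 with a gene column in place of the name
                linked = strip_version(cols[3])
            records.append(TrackRecord(cols[0], start, end, strand, name, linked))
    return AnnotationTrack(kind=kind, records=records)


def write_track(track: AnnotationTrack, path: str | Path) -> None:
    """Write a track back to BED6+1 (linked gene in column 7, '.' if none)."""
    with open(path, "w") as fh:
        for r in track.records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\t"
                     f"{r.linked_gene_id or '.'}\n")


def check_chrom_consistency(genome_chroms: set[str], *named_sets: tuple[str, set[str]]) -> None:
    """Warn (never raise) when annotation files name chromosomes the genome
    lacks — the classic silent 'chr' prefix mismatch."""
    for label, chroms in named_sets:
        unshared = chroms - genome_chroms
        if unshared:
            logger.warning("chromosome names in %s not present in genome: %s",
                           label, sorted(unshared))


# --------------------------------------------------------------------------
# Gene function tables
# --------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: str = "gene_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if required not in df.columns:
        raise ValueError(f"{path}: missing required column {required!r}")
    df[required] = df[required].map(strip_version)
    return df


def load_function_tables(phenotypes: Optional[str | Path] = None,
                         cancer_genes: Optional[str | Path] = None,
                         tf: Optional[str | Path] = None,
                         rbp: Optional[str | Path] = None,
                         expression: Optional[str | Path] = None) -> GeneFunctionIndex:
    """Merge per-gene function TSVs into one GeneFunctionIndex.

    Expected schemas (tab-separated, header row):
      phenotypes:  gene_id, phenotype
      cancer:      gene_id            (membership list)
      tf:          gene_id, tf_class  (TF | co-TF)
      rbp:         gene_id, function
      expression:  gene_id, <tissue1>, <tissue2>, ...  (wide, numeric)

    Any subset of tables may be given; duplicate gene rows union their
    lists.  Lookups of genes absent from every table return an empty record.
    """
    phen: dict[str, list[str]] = {}
    cancer: set[str] = set()
    tf_class: dict[str, str] = {}
    rbp_fn: dict[str, list[str]] = {}
    expr: dict[str, dict[str, float]] = {}
    tissues: list[str] = []

    if phenotypes is not None:
        df = _read_tsv(phenotypes)
        col = "phenotype" if "phenotype" in df.columns else df.columns[1]
        for gid, val in zip(df["gene_id"], df[col]):
            if pd.notna(val) and val:
                bucket = phen.setdefault(gid, [])
                if val not in bucket:
                    bucket.append(val)
    if cancer_genes is not None:
        cancer.update(_read_tsv(cancer_genes)["gene_id"])
    if tf is not None:
        df = _read_tsv(tf)
        col = "tf_class" if "tf_class" in df.columns else df.columns[1]
        for gid, val in zip(df["gene_id"], df[col]):
            if pd.notna(val) and val in ("TF", "co-TF"):
                tf_class[gid] = val
    if rbp is not None:
        df = _read_tsv(rbp)
        col = "function" if "function" in df.columns else df.columns[1]
        for gid, val in zip(df["gene_id"], df[col]):
            bucket = rbp_fn.setdefault(gid, [])
            if pd.notna(val) and val and val not in bucket:
                bucket.append(val)
    if expression is not None:
        df = _read_tsv(expression)
        tissues = [c for c in df.columns if c != "gene_id"]
        for _, row in df.iterrows():
            expr[row["gene_id"]] = {t: float(row[t]) for t in tissues if pd.notna(row[t])}

    index = GeneFunctionIndex(tissues=tissues)
    for gid in set(phen) | cancer | set(tf_class) | set(rbp_fn) | set(expr):
        index.records[gid] = GeneFunctionRecord(
            phenotypes=tuple(phen.get(gid, ())),
            is_cancer_gene=gid in cancer,
            tf_class=tf_class.get(gid, "none"),
            rbp_functions=tuple(rbp_fn.get(gid, ())),
            expression=expr.get(gid, {}),
        )
    return index
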