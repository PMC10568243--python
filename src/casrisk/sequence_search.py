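"""PAM-aware off-target search.

Finds candidate Cas9 cleavage sites for a guide RNA in a genome by scanning
both strands for protospacer-like sequences adjacent to a PAM, counting
mismatches over the protospacer only (never the PAM) and, optionally,
allowing DNA/RNA bulges in the guide-DNA heteroduplex.

Coordinates are 0-based half-open (BED convention) and cover the protospacer
span only; the PAM is stored separately.  Minus-strand sites are reported in
forward-genome coordinates with ``site_sequence`` read 5'->3' on the targeted
strand (i.e. the reverse complement of the forward slice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Alphabet helpers
# --------------------------------------------------------------------------

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC codes are complemented, other chars kept."""
    return seq.translate(_COMPLEMENT)[::-1]


class InvalidGuideError(ValueError):
    """Raised for guides that are empty or contain non-ACGT characters."""


class MalformedRecordError(ValueError):
    """Raised for unparseable BED records; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GuideRNA:
    """A guide RNA: protospacer (DNA alphabet) plus a PAM pattern.

    The protospacer is stored as DNA (the sequence the genomic target strand
    reads); the PAM pattern is an IUPAC string, ``NGG`` by default, located
    3' of the protospacer for Cas9 (``pam_side='three_prime'``).
    """

    protospacer: str
    pam_pattern: str = "NGG"
    pam_side: str = "three_prime"

    def __post_init__(self) -> None:
        if not self.protospacer:
            raise InvalidGuideError("empty protospacer")
        bad = set(self.protospacer) - set("ACGT")
        if bad:
            raise InvalidGuideError(
                f"protospacer contains non-ACGT characters: {sorted(bad)!r}"
            )
        if not self.pam_pattern:
            raise InvalidGuideError("empty PAM pattern")
        bad = set(self.pam_pattern) - set(IUPAC)
        if bad:
            raise InvalidGuideError(f"PAM pattern has non-IUPAC codes: {sorted(bad)!r}")
        if self.pam_side not in ("three_prime", "five_prime"):
            raise InvalidGuideError(f"pam_side must be three_prime/five_prime, got {self.pam_side!r}")

    def __len__(self) -> int:
        return len(self.protospacer)


@dataclass(frozen=True)
class SearchParams:
    """Search budgets: mismatches over the protospacer, and optional bulges."""

    max_mismatches: int = 4
    max_dna_bulges: int = 0
    max_rna_bulges: int = 0
    both_strands: bool = True

    def __post_init__(self) -> None:
        for name in ("max_mismatches", "max_dna_bulges", "max_rna_bulges"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")


@dataclass(frozen=True)
class OffTargetSite:
    """A candidate cleavage locus.

    ``start``/``end`` span the protospacer only, 0-based half-open on the
    forward genome.  ``mismatches`` is None when unknown (user-supplied BED
    without a mismatch column).
    """

    chrom: str
    start: int
    end: int
    strand: str
    site_sequence: str = ""
    pam_sequence: str = ""
    mismatches: Optional[int] = None
    dna_bulges: int = 0
    rna_bulges: int = 0
    alignment_string: str = ""
    name: Optional[str] = None

    @property
    def is_on_target(self) -> bool:
        return self.mismatches == 0 and self.dna_bulges == 0 and self.rna_bulges == 0

    @property
    def total_bulges(self) -> int:
        return self.dna_bulges + self.rna_bulges


@dataclass(frozen=True)
class GappedAlignment:
    """Result of aligning a guide against a genomic window.

    ``alignment_string`` has one code per alignment column:
    ``M`` match, ``X`` mismatch, ``D`` DNA bulge (extra genome base, gap in
    the guide), ``R`` RNA bulge (extra guide base, gap in the genome).
    """

    mismatches: int
    dna_bulges: int
    rna_bulges: int
    alignment_string: str


# --------------------------------------------------------------------------
# Guide parsing
# --------------------------------------------------------------------------

def parse_guide(raw: str, pam_pattern: str = "NGG", pam_side: str = "three_prime") -> GuideRNA:
    """Normalize and validate a raw guide sequence string."""
    seq = raw.strip().upper()
    if not seq:
        raise InvalidGuideError("empty guide sequence")
    return GuideRNA(protospacer=seq, pam_pattern=pam_pattern.strip().upper(), pam_side=pam_side)


def read_guides(path: str | Path, pam_pattern: str = "NGG",
                pam_side: str = "three_prime") -> list[tuple[str, GuideRNA]]:
    """Read guides from plain text (one per line) or 2-column TSV (name, seq).

    Blank lines and ``#`` comments are skipped.  Returns (name, guide) pairs;
    for plain lists the name is ``guide1``, ``guide2``, ...
    """
    out: list[tuple[str, GuideRNA]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 2:
                name, seq = parts[0], parts[1]
            else:
                name, seq = f"guide{len(out) + 1}", parts[0]
            out.append((name, parse_guide(seq, pam_pattern, pam_side)))
    return out


# --------------------------------------------------------------------------
# PAM matching
# --------------------------------------------------------------------------

def pam_matches(pattern: str, seq: str) -> bool:
    """IUPAC-expanded PAM match. Genome ambiguity codes (N etc.) never match."""
    if len(seq) != len(pattern):
        return False
    for p, s in zip(pattern, seq):
        if s not in IUPAC[p] or s not in "ACGT":
            return False
    return True


# --------------------------------------------------------------------------
# Gapped alignment (DP)
# --------------------------------------------------------------------------

def align_gapped(guide_seq: str, window: str, max_mm: int,
                 max_dna_bulge: int = 0, max_rna_bulge: int = 0) -> Optional[GappedAlignment]:
    """Globally align a guide to a genomic window under bulge/mismatch budgets.

    A DNA bulge consumes a genome base with a gap in the guide; an RNA bulge
    consumes a guide base with a gap in the genome.  Among alignments that
    fit all three budgets, the minimal one under the lexicographic cost
    (total bulges, then mismatches) is returned; ties break deterministically
    by preferring, at the earliest differing column, match/mismatch over a
    DNA bulge over an RNA bulge.  Genome bases outside ACGT (e.g. N) always
    count as mismatches.  Returns None when no alignment fits the budgets.
    """
    if max_mm < 0 or max_dna_bulge < 0 or max_rna_bulge < 0:
        raise ValueError("budgets must be >= 0")
    L, W = len(guide_seq), len(window)
    delta = W - L
    # any alignment needs dna - rna == delta
    if delta > max_dna_bulge or -delta > max_rna_bulge:
        return None

    INF = 10 ** 9
    # mm[i][j][d][r]: min mismatches aligning guide[:i] with window[:j]
    # using d DNA and r RNA bulges.
    D, R = max_dna_bulge, max_rna_bulge
    mm = np.full((L + 1, W + 1, D + 1, R + 1), INF, dtype=np.int64)
    mm[0, 0, 0, 0] = 0
    for i in range(L + 1):
        for j in range(W + 1):
            sub = mm[i, j]
            if not (sub < INF).any():
                continue
            if i < L and j < W:
                cost = 0 if (guide_seq[i] == window[j] and window[j] in "ACGT") else 1
                np.minimum(mm[i + 1, j + 1], sub + cost, out=mm[i + 1, j + 1])
            if j < W and D > 0:  # DNA bulge: extra genome base
                np.minimum(mm[i, j + 1, 1:, :], sub[:-1, :], out=mm[i, j + 1, 1:, :])
            if i < L and R > 0:  # RNA bulge: extra guide base
                np.minimum(mm[i + 1, j, :, 1:], sub[:, :-1], out=mm[i + 1, j, :, 1:])
    best: Optional[tuple[int, int, int, int]] = None  # (bulges, mm, d, r)
    for d in range(D + 1):
        for r in range(R + 1):
            if d - r != delta:
                continue
            m = int(mm[L, W, d, r])
            if m <= max_mm:
                cand = (d + r, m, d, r)
                if best is None or cand[:2] < best[:2]:
                    best = cand
    if best is None:
        return None
    _, m_best, d_best, r_best = best
    aln = _traceback(guide_seq, window, mm, d_best, r_best)
    return GappedAlignment(mismatches=m_best, dna_bulges=d_best,
                           rna_bulges=r_best, alignment_string=aln)


def _traceback(g: str, w: str, mm: np.ndarray, d: int, r: int) -> str:
    """Rebuild the alignment string by walking the exact-count DP table
    backward from (len(g), len(w), d, r); at each step match/mismatch is
    preferred over a DNA bulge over an RNA bulge, giving a deterministic
    canonical alignment."""
    i, j = len(g), len(w)
    cols: list[str] = []
    while i > 0 or j > 0:
        cur = int(mm[i, j, d, r])
        if i > 0 and j > 0:
            cost = 0 if (g[i - 1] == w[j - 1] and w[j - 1] in "ACGT") else 1
            if int(mm[i - 1, j - 1, d, r]) + cost == cur:
                cols.append("M" if cost == 0 else "X")
                i -= 1
                j -= 1
                continue
        if j > 0 and d > 0 and int(mm[i, j - 1, d - 1, r]) == cur:
            cols.append("D")
            j -= 1
            d -= 1
            continue
        if i > 0 and r > 0 and int(mm[i - 1, j, d, r - 1]) == cur:
            cols.append("R")
            i -= 1
            r -= 1
            continue
        raise AssertionError("traceback failed")  # pragma: no cover
    return "".join(reversed(cols))


# --------------------------------------------------------------------------
# Genome scan
# --------------------------------------------------------------------------

def _pam_mask(arr: np.ndarray, pattern: str, n: int) -> np.ndarray:
    """Boolean mask over start positions where the PAM pattern matches."""
    plen = len(pattern)
    if n < plen:
        return np.zeros(0, dtype=bool)
    mask = np.ones(n - plen + 1, dtype=bool)
    for k, p in enumerate(pattern):
        allowed = np.frombuffer(IUPAC[p].encode(), dtype=np.uint8)
        mask &= np.isin(arr[k:n - plen + 1 + k], allowed)
    return mask


def _hamming_profile(arr: np.ndarray, guide: str, n: int) -> np.ndarray:
    """Mismatch count of the guide at every start position (vectorised)."""
    L = len(guide)
    if n < L:
        return np.zeros(0, dtype=np.int64)
    counts = np.zeros(n - L + 1, dtype=np.int64)
    for k, ch in enumerate(guide):
        counts += arr[k:n - L + 1 + k] != ord(ch)
    return counts


def _scan_strand(seq: str, guide: GuideRNA, params: SearchParams,
                 chrom: str, strand: str) -> list[OffTargetSite]:
    """Scan one strand. ``seq`` is the targeted-strand sequence 5'->3'."""
    L = len(guide)
    plen = len(guide.pam_pattern)
    n = len(seq)
    Lc = n  # chromosome length (same for both strands)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    pam_ok = _pam_mask(arr, guide.pam_pattern, n)
    sites: list[OffTargetSite] = []

    def emit(ws: int, we: int, pam: str, aln: GappedAlignment) -> None:
        if strand == "+":
            start, end = ws, we
        else:
            start, end = Lc - we, Lc - ws
        sites.append(OffTargetSite(
            chrom=chrom, start=start, end=end, strand=strand,
            site_sequence=seq[ws:we], pam_sequence=pam,
            mismatches=aln.mismatches, dna_bulges=aln.dna_bulges,
            rna_bulges=aln.rna_bulges, alignment_string=aln.alignment_string))

    no_bulges = params.max_dna_bulges == 0 and params.max_rna_bulges == 0
    if no_bulges and n >= L:
        mm_prof = _hamming_profile(arr, guide.protospacer, n)
        # N (or any non-ACGT) genome base mismatches everything already via
        # byte comparison against concrete ACGT guide bases.
        if guide.pam_side == "three_prime":
            # protospacer at [s, s+L), PAM at [s+L, s+L+plen)
            valid = np.zeros(n - L + 1, dtype=bool)
            lim = n - L - plen + 1
            if lim > 0:
                valid[:lim] = pam_ok[L:L + lim]
            hits = np.nonzero(valid & (mm_prof <= params.max_mismatches))[0]
            for s in hits:
                s = int(s)
                aln = _hamming_alignment(guide.protospacer, seq[s:s + L])
                emit(s, s + L, seq[s + L:s + L + plen], aln)
        else:
            # PAM at [p, p+plen), protospacer at [p+plen, p+plen+L)
            for p in np.nonzero(pam_ok)[0]:
                p = int(p)
                s = p + plen
                if s + L > n:
                    continue
                if mm_prof[s] <= params.max_mismatches:
                    aln = _hamming_alignment(guide.protospacer, seq[s:s + L])
                    emit(s, s + L, seq[p:p + plen], aln)
        return sites

    # general path with bulges: anchor on PAM occurrences
    wlens = range(max(1, L - params.max_rna_bulges), L + params.max_dna_bulges + 1)
    for p in np.nonzero(pam_ok)[0]:
        p = int(p)
        for wl in wlens:
            if guide.pam_side == "three_prime":
                ws, we = p - wl, p
            else:
                ws, we = p + plen, p + plen + wl
            if ws < 0 or we > n:
                continue
            aln = align_gapped(guide.protospacer, seq[ws:we], params.max_mismatches,
                               params.max_dna_bulges, params.max_rna_bulges)
            if aln is not None:
                emit(ws, we, seq[p:p + plen] if guide.pam_side == "five_prime"
                     else seq[we:we + plen], aln)
    return sites


def _hamming_alignment(guide: str, window: str) -> GappedAlignment:
    cols = ["M" if (g == w and w in "ACGT") else "X" for g, w in zip(guide, window)]
    return GappedAlignment(mismatches=cols.count("X"), dna_bulges=0,
                           rna_bulges=0, alignment_string="".join(cols))


def find_offtargets(genome: Mapping[str, str], guide: GuideRNA,
                    params: SearchParams | None = None) -> list[OffTargetSite]:
    """Find all guide-like sites in a genome within the search budgets.

    ``genome`` maps sequence name -> sequence.  Both strands are scanned when
    ``params.both_strands``; results are deduplicated by locus keeping the
    alignment with fewest (bulges, then mismatches) and sorted by
    (chrom, start).
    """
    if params is None:
        params = SearchParams()
    if not genome:
        raise ValueError("empty genome")
    sites: list[OffTargetSite] = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        sites.extend(_scan_strand(seq, guide, params, chrom, "+"))
        if params.both_strands:
            sites.extend(_scan_strand(revcomp(seq), guide, params, chrom, "-"))
    return dedupe_sites(sites)


# --------------------------------------------------------------------------
# Site list IO and dedup
# --------------------------------------------------------------------------

def read_sites_bed(path: str | Path) -> list[OffTargetSite]:
    """Read user-supplied off-target sites from BED6(+mismatch column).

    BED is 0-based half-open.  A missing strand column defaults to ``+`` with
    a logged warning; an optional 7th column supplies the mismatch count,
    otherwise mismatches are recorded as unknown (None).
    """
    sites: list[OffTargetSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise MalformedRecordError(f"expected >=3 columns, got {len(cols)}", lineno)
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise MalformedRecordError(
                    f"non-integer coordinates {cols[1]!r}/{cols[2]!r}", lineno) from None
            if start >= end:
                raise MalformedRecordError(f"start {start} >= end {end}", lineno)
            if start < 0:
                raise MalformedRecordError(f"negative start {start}", lineno)
            name = cols[3] if len(cols) > 3 and cols[3] not in ("", ".") else None
            if len(cols) > 5 and cols[5] in ("+", "-"):
                strand = cols[5]
            else:
                strand = "+"
                logger.warning("%s line %d: missing strand, defaulting to '+'", path, lineno)
            mism: Optional[int] = None
            if len(cols) > 6 and cols[6] not in ("", "."):
                try:
                    mism = int(cols[6])
                except ValueError:
                    raise MalformedRecordError(f"non-integer mismatch column {cols[6]!r}",
                                               lineno) from None
            sites.append(OffTargetSite(chrom=chrom, start=start, end=end,
                                       strand=strand, mismatches=mism, name=name))
    return sites


def write_sites_bed(sites: Sequence[OffTargetSite], path: str | Path) -> None:
    """Write sites as BED6 plus a 7th mismatch column ('.' when unknown)."""
    with open(path, "w") as fh:
        for i, s in enumerate(sites, start=1):
            name = s.name or f"site{i}"
            mm = "." if s.mismatches is None else str(s.mismatches)
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{name}\t0\t{s.strand}\t{mm}\n")


def write_sites_tsv(sites: Sequence[OffTargetSite], path: str | Path) -> None:
    """Extended site table: sequence, PAM, mismatch/bulge counts, alignment."""
    header = ["chrom", "start", "end", "strand", "site_sequence", "pam_sequence",
              "mismatches", "dna_bulges", "rna_bulges", "alignment_string"]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for s in sites:
            mm = "" if s.mismatches is None else str(s.mismatches)
            fh.write("\t".join([s.chrom, str(s.start), str(s.end), s.strand,
                                s.site_sequence, s.pam_sequence, mm,
                                str(s.dna_bulges), str(s.rna_bulges),
                                s.alignment_string]) + "\n")


def fill_site_sequences(sites: Sequence[OffTargetSite], genome: Mapping[str, str],
                        pam_length: int = 3,
                        pam_side: str = "three_prime") -> list[OffTargetSite]:
    """Fill missing site/PAM sequences from genome slices.

    Used when sites come from a BED file (which carries no sequence): the
    protospacer is read 5'->3' on the targeted strand, and the PAM is taken
    from the adjacent bases on that strand.  Sites on unknown chromosomes
    are passed through unchanged.
    """
    out: list[OffTargetSite] = []
    for s in sites:
        seq = genome.get(s.chrom)
        if seq is None or s.site_sequence:
            out.append(s)
            continue
        fwd = seq[s.start:s.end].upper()
        if s.strand == "-":
            site_seq = revcomp(fwd)
            if pam_side == "three_prime":
                pam = revcomp(seq[max(0, s.start - pam_length):s.start].upper())
            else:
                pam = revcomp(seq[s.end:s.end + pam_length].upper())
        else:
            site_seq = fwd
            if pam_side == "three_prime":
                pam = seq[s.end:s.end + pam_length].upper()
            else:
                pam = seq[max(0, s.start - pam_length):s.start].upper()
        out.append(replace(s, site_sequence=site_seq, pam_sequence=pam))
    return out


def dedupe_sites(sites: Iterable[OffTargetSite]) -> list[OffTargetSite]:
    """Deduplicate by (chrom, start, end, strand), keeping the alignment with
    the fewest (total bulges, then mismatches); stable sort by locus."""
    best: dict[tuple[str, int, int, str], OffTargetSite] = {}
    for s in sites:
        key = (s.chrom, s.start, s.end, s.strand)
        cur = best.get(key)
        if cur is None or _site_cost(s) < _site_cost(cur):
            best[key] = s
    return sorted(best.values(), key=lambda s: (s.chrom, s.start, s.end, s.strand))


def _site_cost(s: OffTargetSite) -> tuple[int, float]:
    return (s.total_bulges, float("inf") if s.mismatches is None else s.mismatches)
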