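"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results with the simplest possible
enumeration (per-position Hamming scans, all-pairs interval comparison,
exhaustive gap placement) so they stay independent of the library's search,
alignment and intersection code paths.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import pytest

from casrisk import FixtureSpec, make_fixture
from casrisk.sequence_search import IUPAC

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP.get(b, "N") for b in reversed(seq))


def oracle_scan(genome: dict[str, str], guide: str, pam: str, max_mm: int,
                both_strands: bool = True) -> set[tuple[str, int, int, str, int]]:
    """Exhaustive per-position Hamming + PAM scan on both strands.

    Returns {(chrom, start, end, strand, mismatches)} with protospacer-only
    0-based half-open coordinates on the forward genome.  Genome bases
    outside ACGT never match anything (guide or PAM).
    """
    hits: set[tuple[str, int, int, str, int]] = set()
    L, P = len(guide), len(pam)
    for chrom, seq in genome.items():
        seq = seq.upper()
        n = len(seq)
        strands = [("+", seq)] + ([("-", rc(seq))] if both_strands else [])
        for strand, s in strands:
            for i in range(n - L - P + 1):
                pam_seq = s[i + L:i + L + P]
                ok = all(b in "ACGT" and b in IUPAC[p] for p, b in zip(pam, pam_seq))
                if not ok:
                    continue
                mm = sum(1 for a, b in zip(guide, s[i:i + L])
                         if a != b or b not in "ACGT")
                if mm <= max_mm:
                    if strand == "+":
                        hits.add((chrom, i, i + L, "+", mm))
                    else:
                        hits.add((chrom, n - i - L, n - i, "-", mm))
    return hits


def oracle_align(guide: str, window: str, max_mm: int, max_dna: int,
                 max_rna: int) -> tuple[int, int, int] | None:
    """Exhaustive gap-placement enumeration for short sequences.

    Enumerates every way of choosing d genome positions as DNA bulges and r
    guide positions as RNA bulges (d - r fixed by the length difference),
    scoring each residual as a Hamming comparison; returns the minimal
    (bulges, mismatches) outcome as (mm, d, r), or None.
    """
    best: tuple[int, int, int, int] | None = None  # (bulges, mm, d, r)
    delta = len(window) - len(guide)
    for r in range(max_rna + 1):
        d = delta + r
        if d < 0 or d > max_dna:
            continue
        for gap_w in itertools.combinations(range(len(window)), d):
            w_kept = [window[j] for j in range(len(window)) if j not in gap_w]
            for gap_g in itertools.combinations(range(len(guide)), r):
                g_kept = [guide[i] for i in range(len(guide)) if i not in gap_g]
                assert len(g_kept) == len(w_kept)
                mm = sum(1 for a, b in zip(g_kept, w_kept)
                         if a != b or b not in "ACGT")
                if mm <= max_mm:
                    cand = (d + r, mm, d, r)
                    if best is None or cand[:2] < best[:2]:
                        best = cand
    if best is None:
        return None
    return best[1], best[2], best[3]


def oracle_intersect(sites, records, min_overlap: int = 1):
    """Naive all-pairs overlap comparison (pure Python)."""
    pairs = []
    for si, s in enumerate(sites):
        for ri, r in enumerate(records):
            if s.chrom != r.chrom:
                continue
            bp = min(s.end, r.end) - max(s.start, r.start)
            if bp >= min_overlap:
                pairs.append((si, ri, bp))
    return pairs


@pytest.fixture(scope="session")
def standard_world(tmp_path_factory) -> tuple[Path, "object"]:
    """The standard synthetic world (10 planted sites, histogram
    {0:1, 2:1, 3:3, 4:5}) generated once per session at seed 7."""
    d = tmp_path_factory.mktemp("world")
    manifest = make_fixture(FixtureSpec(), seed=7, out_dir=d)
    return d, manifest
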