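"""Shared fixtures: tiny hand-built genomes, gene models, and an
independent affine-gap alignment oracle."""

from __future__ import annotations

from functools import lru_cache

import pytest

from rlrkit.io_formats import gene_model_from_exons
from rlrkit.pairwise_align import Scoring

NEG_INF = float("-inf")


def affine_dp_oracle(a: str, b: str, scoring: Scoring) -> float:
    """Exhaustive affine-gap global alignment score, by 3-state recursion.

    Independent of the package's alignment engine: a gap of length k
    costs gap_open + k * gap_extend, terminal gaps included.  Only usable
    for short sequences.
    """
    go, ge = scoring.gap_open, scoring.gap_extend

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        # state 0: a[i-1]~b[j-1] aligned; 1: gap in b (a consumed); 2: gap in a
        if i == 0 and j == 0:
            return 0.0 if state == 0 else NEG_INF
        if state == 0:
            if i == 0 or j == 0:
                return NEG_INF
            prev = max(best(i - 1, j - 1, s) for s in (0, 1, 2))
            return prev + scoring.pair_score(a[i - 1], b[j - 1])
        if state == 1:
            if i == 0:
                return NEG_INF
            return max(
                max(best(i - 1, j, s) for s in (0, 2)) - go - ge,
                best(i - 1, j, 1) - ge,
            )
        if j == 0:
            return NEG_INF
        return max(
            max(best(i, j - 1, s) for s in (0, 1)) - go - ge,
            best(i, j - 1, 2) - ge,
        )

    return max(best(len(a), len(b), s) for s in (0, 1, 2))


@pytest.fixture
def two_exon_minus_gene():
    """Hand-spliced two-exon minus-strand toy gene on a 60-nt scaffold."""
    #                 0         1         2         3         4         5
    #                 0123456789012345678901234567890123456789012345678901234
    scaffold = "ACGTACGTAAGGGTTTCCCAAATTTGGGCCCAAAGGGTTTACGTACGTACGTACGTACGT"
    # transcription order on minus strand: exon at (30, 39) first, then (10, 19)
    exons = [(30, 39), (10, 19)]
    gm = gene_model_from_exons("toy-", "s1", "-", exons, scaffold)
    return gm, scaffold


@pytest.fixture
def three_exon_gene():
    """Plus-strand three-exon gene with whole-codon exons."""
    flank = "T" * 10
    e1, e2, e3 = "ATGGCCGCT", "AAAGGGTTTCCC", "GAGTGA"
    i1, i2 = "GTAAGCAG", "GTTTTCAG"
    scaffold = flank + e1 + i1 + e2 + i2 + e3 + flank
    s = len(flank)
    exons = [
        (s, s + len(e1)),
        (s + len(e1) + len(i1), s + len(e1) + len(i1) + len(e2)),
        (s + len(e1) + len(i1) + len(e2) + len(i2),
         s + len(e1) + len(i1) + len(e2) + len(i2) + len(e3)),
    ]
    gm = gene_model_from_exons("toy3", "s3", "+", exons, scaffold)
    return gm, scaffold
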