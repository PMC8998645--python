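"""Deterministic global and local pairwise alignment with affine gaps.

Used for sibling-pair protein comparison, exon homology mapping, and the
DNA-level exonization test.  A gap of length k costs
``gap_open + k * gap_extend``.  Defaults: BLOSUM62 / 10 / 0.5 for protein,
match +2 / mismatch -3 / 5 / 2 for DNA.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import GeneModel

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX*")
DNA_ALPHABET = set("ACGTN")


@dataclass
class Scoring:
    """Substitution scoring + affine gap penalties (penalties positive)."""

    matrix: object  # Bio.Align substitution matrix, or None for match/mismatch
    gap_open: float
    gap_extend: float
    match: float = 2.0
    mismatch: float = -3.0

    @classmethod
    def protein_default(cls) -> "Scoring":
        return cls(substitution_matrices.load("BLOSUM62"), 10.0, 0.5)

    @classmethod
    def dna_default(cls) -> "Scoring":
        return cls(None, 5.0, 2.0, match=2.0, mismatch=-3.0)

    def pair_score(self, x: str, y: str) -> float:
        if self.matrix is not None:
            return float(self.matrix[x, y])
        return self.match if x == y else self.mismatch


@dataclass
class AlignmentResult:
    """One pairwise alignment: equal-length gapped strings plus summary stats.

    ``identity`` is matches over aligned columns excluding double-gap
    columns; ``similarity`` additionally counts positively scoring
    substitutions.  ``coverage_a``/``coverage_b`` are the fractions of each
    input inside the aligned region (1.0 for global alignments).
    """

    aligned_a: str
    aligned_b: str
    score: float
    identity: float
    similarity: float
    coverage_a: float
    coverage_b: float
    mode: str  # "global" | "local"
    start_a: int = 0  # for local: substring coordinates in the inputs
    end_a: int = 0
    start_b: int = 0
    end_b: int = 0


def _check_inputs(a: str, b: str, scoring: Scoring | None) -> None:
    if not a or not b:
        raise ValueError("empty sequence")
    sa, sb = set(a.upper()), set(b.upper())
    if (sa <= DNA_ALPHABET) and (sb <= DNA_ALPHABET):
        return
    # short protein strings can look like DNA; call a sequence DNA only when
    # it is long enough to be unambiguous or the scoring is match/mismatch
    def looks_dna(chars, seq):
        return chars <= DNA_ALPHABET and (
            len(seq) >= 10 or (scoring is not None and scoring.matrix is None)
        )

    if looks_dna(sa, a) != looks_dna(sb, b):
        raise ValueError("mixed alphabets")


def _aligner(scoring: Scoring, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    if scoring.matrix is not None:
        al.substitution_matrix = scoring.matrix
    else:
        al.match_score = scoring.match
        al.mismatch_score = scoring.mismatch
    # first gap position pays open + extend; later positions pay extend
    al.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    al.extend_gap_score = -scoring.gap_extend
    return al


def _stats(ga: str, gb: str, scoring: Scoring) -> tuple[float, float]:
    matches = similar = cols = 0
    for x, y in zip(ga, gb):
        if x == "-" and y == "-":
            continue
        cols += 1
        if x == "-" or y == "-":
            continue
        if x == y:
            matches += 1
            similar += 1
        elif scoring.pair_score(x, y) > 0:
            similar += 1
    if cols == 0:
        return 0.0, 0.0
    return matches / cols, similar / cols


def _format(alignment) -> tuple[str, str]:
    # row indexing yields the gapped sequences (local: aligned region only)
    return str(alignment[0]), str(alignment[1])


def global_align(a: str, b: str, scoring: Scoring | None = None) -> AlignmentResult:
    """Optimal Needleman–Wunsch alignment under affine gaps.

    Deterministic: the engine's first traceback is always returned.
    """
    _check_inputs(a, b, scoring)
    scoring = scoring or Scoring.protein_default()
    al = _aligner(scoring, "global")
    best = al.align(a, b)[0]
    ga, gb = _format(best)
    ident, sim = _stats(ga, gb, scoring)
    return AlignmentResult(
        ga, gb, float(best.score), ident, sim, 1.0, 1.0, "global",
        0, len(a), 0, len(b),
    )


def local_align(a: str, b: str, scoring: Scoring | None = None) -> AlignmentResult:
    """Optimal Smith–Waterman local alignment; empty alignment scores 0."""
    _check_inputs(a, b, scoring)
    scoring = scoring or Scoring.dna_default()
    al = _aligner(scoring, "local")
    alns = al.align(a, b)
    if len(alns) == 0 or alns[0].score <= 0:
        return AlignmentResult("", "", 0.0, 0.0, 0.0, 0.0, 0.0, "local")
    best = alns[0]
    ga, gb = _format(best)
    (sa, ea) = (best.aligned[0][0][0], best.aligned[0][-1][1]) if len(best.aligned[0]) else (0, 0)
    (sb, eb) = (best.aligned[1][0][0], best.aligned[1][-1][1]) if len(best.aligned[1]) else (0, 0)
    ident, sim = _stats(ga, gb, scoring)
    return AlignmentResult(
        ga, gb, float(best.score), ident, sim,
        (ea - sa) / len(a), (eb - sb) / len(b), "local", sa, ea, sb, eb,
    )


@dataclass
class ExonSpan:
    """Alignment-column span of one exon of one side of a pairwise alignment."""

    exon_index: int
    col_start: int  # alignment columns, 0-based half-open, gap columns included
    col_end: int
    aa_start: int  # protein coordinates, 0-based half-open
    aa_end: int
    split_codon_boundary: bool  # True when the exon boundary splits a codon


def exon_protein_spans(gm: GeneModel) -> list[ExonSpan]:
    """Map each exon's CDS interval to protein coordinates.

    An exon covering CDS nucleotides [s, e) maps to residues
    [floor(s/3), ceil(e/3)); a boundary residue whose codon is split
    between two exons is assigned to both spans' arithmetic but flagged,
    and downstream matching treats the 5' exon as its owner.
    """
    spans = []
    pos = 0
    for i, ln in enumerate(gm.exon_lengths_nt):
        s, e = pos, pos + ln
        aa_s, aa_e = s // 3, -(-e // 3)
        aa_e = min(aa_e, len(gm.protein_sequence))
        spans.append(ExonSpan(i, 0, 0, aa_s, aa_e, split_codon_boundary=(e % 3 != 0)))
        pos = e
    return spans


def map_exons_to_alignment(
    gm: GeneModel, aln: AlignmentResult, which: str
) -> list[ExonSpan]:
    """Map a gene's exons to column spans of a global protein alignment.

    ``which`` selects the side of ``aln`` that carries
    ``gm.protein_sequence``.  Spans are contiguous, ordered, and
    non-overlapping except for one shared residue at codon-split
    boundaries (flagged on the 5' span).
    """
    gapped = aln.aligned_a if which == "a" else aln.aligned_b
    if gapped.replace("-", "") != gm.protein_sequence:
        raise ValueError(f"alignment side {which!r} does not match {gm.gene_id} protein")
    # residue index -> first alignment column of that residue
    res2col = []
    for col, ch in enumerate(gapped):
        if ch != "-":
            res2col.append(col)
    res2col.append(len(gapped))
    spans = exon_protein_spans(gm)
    for sp in spans:
        sp.col_start = res2col[sp.aa_start]
        sp.col_end = res2col[sp.aa_end - 1] + 1 if sp.aa_end > sp.aa_start else sp.col_start
    return spans
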