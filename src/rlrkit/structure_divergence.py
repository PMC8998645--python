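"""Classification of exon–intron structural divergence between sibling genes.

Given a pair of sibling paralogs/orthologs (a tree cherry), their gene
models, and genomic windows around each locus, this module decides
whether the pair has diverged in exon–intron structure and, if so, by
which mechanism(s):

* ``GAIN_LOSS`` — an entire exon (or intron) was gained or lost: one gene
  carries an orphan exon with no homologous sequence anywhere in the
  partner locus, or one exon is split in two by an inserted intron.
* ``EXONIZATION_PSEUDOEXONIZATION`` — interchange between exonic and
  non-exonic sequence: an orphan exon of one gene aligns confidently to
  intronic/flanking sequence of the partner.
* ``INTRAEXONIC_INDEL`` — an insertion/deletion strictly inside a pair of
  homologous exons.

The three mechanisms are not mutually exclusive; a single pair can carry
several.  Polarity (which gene gained vs. lost) is not inferred — that
would require an outgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio.Seq import Seq

from .io_formats import GeneModel
from .pairwise_align import (
    AlignmentResult,
    Scoring,
    global_align,
    local_align,
    map_exons_to_alignment,
)

GAIN_LOSS = "GAIN_LOSS"
EXONIZATION = "EXONIZATION_PSEUDOEXONIZATION"
INTRAEXONIC_INDEL = "INTRAEXONIC_INDEL"
MECHANISMS = (GAIN_LOSS, EXONIZATION, INTRAEXONIC_INDEL)


@dataclass
class DivergenceParams:
    """Thresholds of the mechanism classifier (all recorded in output)."""

    tau_overlap: float = 0.5  # reciprocal exon-span overlap for homology
    min_indel_aa: int = 2  # minimum gap run inside an exon pair
    min_flank_cols: int = 5  # aligned columns required on each side of an indel
    id_min: float = 0.40  # DNA identity for "aligned with confidence"
    cov_min: float = 0.60  # orphan coverage for "aligned with confidence"
    min_orphan_aa: int = 10  # shorter orphans are alignment noise
    flank_nt: int = 5000  # genomic flank taken around each locus


@dataclass
class SiblingPair:
    gene_a: str
    gene_b: str
    relation: str  # "paralog" | "ortholog"
    source: str = "tree_cherry"

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError("a sibling pair needs two distinct genes")


def species_tag(leaf_label: str) -> str:
    """Species tag of a leaf label, the prefix before the first underscore."""
    if "_" not in leaf_label:
        raise ValueError(f"leaf label {leaf_label!r} carries no species tag "
                         "(expected '<species>_<gene>')")
    return leaf_label.split("_", 1)[0]


def extract_sibling_pairs(
    tree: dendropy.Tree, genes_of_interest: set[str]
) -> list[SiblingPair]:
    """All cherries of the tree whose two leaves are both of interest.

    A cherry is a pair of leaves sharing an immediate ancestor; it is the
    tree's pair of highest sequence similarity for those genes.  Same
    species tag → paralogs, different → orthologs.
    """
    pairs = []
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        leaves = [c for c in children if c.is_leaf()]
        if len(children) == 2 and len(leaves) == 2:
            a, b = sorted(lf.taxon.label for lf in leaves)
            if a in genes_of_interest and b in genes_of_interest:
                relation = "paralog" if species_tag(a) == species_tag(b) else "ortholog"
                pairs.append(SiblingPair(a, b, relation))
    return pairs


@dataclass
class ExonCorrespondence:
    """1:1 exon homology map between two gene models.

    ``matched`` holds (i_a, i_b, frac_a, frac_b): the reciprocal
    alignment-column overlap fractions of each exon's span.  Unmatched
    exons are orphans; an orphan whose span lies mostly inside a matched
    partner exon's span is a split candidate (intron gain/loss pattern).
    """

    matched: list[tuple[int, int, float, float]]
    orphans_a: list[int]
    orphans_b: list[int]
    split_candidates_a: list[int] = field(default_factory=list)
    split_candidates_b: list[int] = field(default_factory=list)


def _column_exon_index(gm: GeneModel, aln: AlignmentResult, which: str) -> np.ndarray:
    """Per-alignment-column exon index of one side (-1 at gap columns).

    A boundary residue whose codon is split between two exons belongs to
    the 5' exon.
    """
    gapped = aln.aligned_a if which == "a" else aln.aligned_b
    spans = map_exons_to_alignment(gm, aln, which)
    res_exon = np.full(len(gm.protein_sequence), -1, dtype=np.int64)
    for sp in spans:  # 5'→3': earlier exon wins the shared boundary residue
        seg = res_exon[sp.aa_start : sp.aa_end]
        seg[seg == -1] = sp.exon_index
    out = np.full(len(gapped), -1, dtype=np.int64)
    r = 0
    for col, ch in enumerate(gapped):
        if ch != "-":
            out[col] = res_exon[r]
            r += 1
    return out


def pair_exon_homology(
    gm_a: GeneModel,
    gm_b: GeneModel,
    aln: AlignmentResult,
    tau_overlap: float = 0.5,
) -> ExonCorrespondence:
    """Match exons of two genes through their global protein alignment.

    The overlap of exon i of a with exon j of b is the number of columns
    where both sides carry a residue and those residues belong to i and j
    respectively; the reciprocal fractions divide by each exon's residue
    count.  Matching is greedy 5'→3' (crossing forbidden, 1:1) at
    reciprocal overlap ≥ ``tau_overlap``.
    """
    col_a = _column_exon_index(gm_a, aln, "a")
    col_b = _column_exon_index(gm_b, aln, "b")
    n_a, n_b = gm_a.n_exons, gm_b.n_exons
    both = (col_a >= 0) & (col_b >= 0)
    overlap = np.zeros((n_a, n_b), dtype=np.int64)
    np.add.at(overlap, (col_a[both], col_b[both]), 1)
    size_a = np.maximum(1, np.bincount(col_a[col_a >= 0], minlength=n_a))
    size_b = np.maximum(1, np.bincount(col_b[col_b >= 0], minlength=n_b))

    matched: list[tuple[int, int, float, float]] = []
    used_b: set[int] = set()
    next_b = 0  # crossing forbidden: candidate j must be ≥ next_b
    for i in range(n_a):
        best = None
        for j in range(next_b, n_b):
            if j in used_b:
                continue
            fa = overlap[i, j] / size_a[i]
            fb = overlap[i, j] / size_b[j]
            if fa >= tau_overlap and fb >= tau_overlap:
                if best is None or min(fa, fb) > best[2]:
                    best = (j, (fa, fb), min(fa, fb))
        if best is not None:
            j, (fa, fb), _ = best
            matched.append((i, j, fa, fb))
            used_b.add(j)
            next_b = j + 1

    matched_a = {m[0] for m in matched}
    matched_b = {m[1] for m in matched}
    orphans_a = [i for i in range(n_a) if i not in matched_a]
    orphans_b = [j for j in range(n_b) if j not in matched_b]

    def split_candidates(orphans, ov, sizes, matched_other, axis):
        out = []
        for i in orphans:
            row = ov[i] if axis == 0 else ov[:, i]
            for j in matched_other:
                if row[j] / sizes[i] >= tau_overlap:
                    out.append(i)
                    break
        return out

    return ExonCorrespondence(
        matched,
        orphans_a,
        orphans_b,
        split_candidates_a=split_candidates(orphans_a, overlap, size_a, matched_b, 0),
        split_candidates_b=split_candidates(orphans_b, overlap, size_b, matched_a, 1),
    )


def is_structurally_divergent(
    corr: ExonCorrespondence, gm_a: GeneModel, gm_b: GeneModel
) -> bool:
    """Different exon counts, or ≥1 homologous exon pair of unequal nt length."""
    if gm_a.n_exons != gm_b.n_exons:
        return True
    la, lb = gm_a.exon_lengths_nt, gm_b.exon_lengths_nt
    return any(la[i] != lb[j] for i, j, _, _ in corr.matched)


@dataclass
class GenomicWindow:
    """A scaffold slice covering one gene locus plus flanks."""

    scaffold_id: str
    start: int  # genomic coordinate of seq[0], 0-based
    seq: str

    def non_exonic_sequence(self, gm: GeneModel, spacer: int = 20) -> str:
        """Introns + flanks of the window, exons masked out.

        Segments are joined with runs of 'N' so a local alignment cannot
        span two non-adjacent segments.
        """
        exonic = sorted((s - self.start, e - self.start) for s, e in gm.exons)
        segments = []
        pos = 0
        for s, e in exonic:
            s, e = max(0, s), min(len(self.seq), e)
            if s > pos:
                segments.append(self.seq[pos:s])
            pos = max(pos, e)
        if pos < len(self.seq):
            segments.append(self.seq[pos:])
        return ("N" * spacer).join(segments)


@dataclass
class DivergenceCall:
    pair: tuple[str, str]
    structurally_divergent: bool
    mechanisms: set[str]
    evidence: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if self.mechanisms and not self.structurally_divergent:
            raise ValueError("mechanisms imply structural divergence")


def _exon_nt(gm: GeneModel, i: int) -> str:
    pos = 0
    for k, ln in enumerate(gm.exon_lengths_nt):
        if k == i:
            return gm.cds_sequence[pos : pos + ln]
        pos += ln
    raise IndexError(i)


def _indel_evidence(corr, aln, gm_a, gm_b, params):
    """Gap runs strictly inside matched exon pairs."""
    ga, gb = aln.aligned_a, aln.aligned_b
    col_a = _column_exon_index(gm_a, aln, "a")
    col_b = _column_exon_index(gm_b, aln, "b")
    out = []
    for i, j, _, _ in corr.matched:
        # a true indel changes the exon length; equal-length exon pairs can
        # only show balanced gap pairs, which are alignment artifacts
        if gm_a.exon_lengths_nt[i] == gm_b.exon_lengths_nt[j]:
            continue
        cols_i = np.nonzero(col_a == i)[0]
        cols_j = np.nonzero(col_b == j)[0]
        lo = int(max(cols_i[0], cols_j[0]))
        hi = int(min(cols_i[-1], cols_j[-1])) + 1
        c = lo
        while c < hi:
            if (ga[c] == "-") != (gb[c] == "-"):
                side = "a" if ga[c] == "-" else "b"
                run_start = c
                while c < hi and (ga[c] == "-" if side == "a" else gb[c] == "-"):
                    c += 1
            else:
                c += 1
                continue
            run_len = c - run_start
            # strictly internal to both exons, with aligned flanks
            if run_len < params.min_indel_aa:
                continue
            if run_start <= lo or c >= hi:
                continue
            left = sum(
                1 for k in range(lo, run_start) if ga[k] != "-" and gb[k] != "-"
            )
            right = sum(1 for k in range(c, hi) if ga[k] != "-" and gb[k] != "-")
            if left >= params.min_flank_cols and right >= params.min_flank_cols:
                out.append(
                    {
                        "mechanism": INTRAEXONIC_INDEL,
                        "exon_a": i,
                        "exon_b": j,
                        "gap_side": side,
                        "indel_aa": run_len,
                        "columns": [run_start, c],
                    }
                )
    return out


def _orphan_evidence(orphans, splits, gm_self, gm_other, window_other, side, params):
    """Classify orphan exons by homology to the partner's non-exonic sequence."""
    out = []
    non_exonic = window_other.non_exonic_sequence(gm_other) if window_other else None
    for i in orphans:
        aa_len = gm_self.exon_lengths_nt[i] // 3
        if i in splits:
            out.append(
                {
                    "mechanism": GAIN_LOSS,
                    "subtype": "intron_gain_loss",
                    "orphan_exon": i,
                    "orphan_side": side,
                    "orphan_aa": aa_len,
                }
            )
            continue
        if aa_len < params.min_orphan_aa:
            continue
        if non_exonic is None:
            raise ValueError(
                f"orphan exon in {gm_self.gene_id} but no genomic window for "
                f"{gm_other.gene_id}"
            )
        exon_nt = _exon_nt(gm_self, i)
        best = None
        for query in (exon_nt, str(Seq(exon_nt).reverse_complement())):
            res = local_align(query, non_exonic, Scoring.dna_default())
            if best is None or res.score > best.score:
                best = res
        hit = best.identity >= params.id_min and best.coverage_a >= params.cov_min
        out.append(
            {
                "mechanism": EXONIZATION if hit else GAIN_LOSS,
                "subtype": "exon_gain_loss" if not hit else None,
                "orphan_exon": i,
                "orphan_side": side,
                "orphan_aa": aa_len,
                "intronic_identity": round(float(best.identity), 4),
                "intronic_coverage": round(float(best.coverage_a), 4),
            }
        )
    return out


def classify_mechanisms(
    gm_a: GeneModel,
    gm_b: GeneModel,
    corr: ExonCorrespondence,
    aln: AlignmentResult,
    genomic_a: GenomicWindow | None,
    genomic_b: GenomicWindow | None,
    params: DivergenceParams | None = None,
) -> DivergenceCall:
    """Assign divergence mechanism(s) to one sibling pair.

    Symmetric in (a, b): swapping the genes swaps evidence sides but not
    the mechanism set.
    """
    params = params or DivergenceParams()
    divergent = is_structurally_divergent(corr, gm_a, gm_b)
    evidence = []
    evidence += _indel_evidence(corr, aln, gm_a, gm_b, params)
    evidence += _orphan_evidence(
        corr.orphans_a, set(corr.split_candidates_a), gm_a, gm_b, genomic_b, "a", params
    )
    evidence += _orphan_evidence(
        corr.orphans_b, set(corr.split_candidates_b), gm_b, gm_a, genomic_a, "b", params
    )
    mechanisms = {ev["mechanism"] for ev in evidence}
    if mechanisms:
        divergent = True
    return DivergenceCall((gm_a.gene_id, gm_b.gene_id), divergent, mechanisms, evidence)


def compare_pair(
    gm_a: GeneModel,
    gm_b: GeneModel,
    window_a: GenomicWindow | None = None,
    window_b: GenomicWindow | None = None,
    params: DivergenceParams | None = None,
) -> DivergenceCall:
    """Full pipeline for one pair: align proteins, map exons, classify."""
    params = params or DivergenceParams()
    aln = global_align(gm_a.protein_sequence, gm_b.protein_sequence,
                       Scoring.protein_default())
    corr = pair_exon_homology(gm_a, gm_b, aln, params.tau_overlap)
    return classify_mechanisms(gm_a, gm_b, corr, aln, window_a, window_b, params)


def mechanism_census(calls: list[DivergenceCall]) -> dict[str, int]:
    """Number of pairs whose call includes each mechanism (overlaps allowed)."""
    census = {m: 0 for m in MECHANISMS}
    for call in calls:
        for m in call.mechanisms:
            census[m] += 1
    return census
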