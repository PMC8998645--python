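# Methods

## Scope and data model

rlrkit analyses protein-coding gene families whose members differ in
N-terminal domain content, exon–intron structure, expression, and
selective regime.  Internal coordinates are 0-based half-open everywhere;
GFF3's 1-based inclusive convention is converted at the I/O boundary.
Gene models are built from CDS features only — the structures being
compared are protein-coding exon diagrams, so UTR exons are ignored.  A
terminal stop codon is trimmed from the protein; an internal stop flags
the model but does not reject it, because pseudoexonization can
legitimately create one.

## Pairwise alignment

Global (Needleman–Wunsch) and local (Smith–Waterman) alignment with
affine gaps; a gap of length k costs `gap_open + k·gap_extend`.
Defaults: BLOSUM62 with 10/0.5 for protein, +2/−3 with 5/2 for DNA.  The
engine is Biopython's C `PairwiseAligner`; the first traceback is taken,
which is deterministic for fixed inputs.  Reported `identity` excludes
double-gap columns from the denominator; `similarity` additionally counts
positively scoring substitutions, since "percent similarity" in the
literature is ambiguous between the two.  Correctness is checked against
a hand-written exhaustive three-state dynamic program on short sequences;
the oracle shares no code with the engine.

## Architecture typing

The screening rule requires DEXDc, HELICc and RD present in that order.
The N-terminal pattern (domains preceding DEXDc) is looked up in a
taxonomy table keyed by (clade, pattern).  Four labels are fixed by
well-established biology: V1 = CARD-CARD, V2 = empty N-terminus,
C = single CARD, A1 = Death; among the lophotrochozoan types, L2 = DED
and L4 = IG are likewise anchored.  The remaining lineage-specific labels
(L1, L3, L5, L6) are **editable table entries, not ground truth**: the
shipped defaults (L1 = a lophotrochozoan-specific CARD arrangement,
L3 = CASc, L5 = SAM, L6 = lophotrochozoan Death) keep the mapping total
and deterministic, and `taxonomy_version` is recorded in every output so
a revised table is distinguishable.  Runs of a repeated domain collapse
to one copy for lookup *after* exact-pattern lookup fails (so CARD-CARD
still types V1 while IG×4 types L4), with copy numbers kept as metadata.
Anything unmatched maps to X carrying the pattern string as evidence.

## Tandem arrays

An array is a maximal run of ≥2 RLR genes on one scaffold in which
consecutive RLRs are separated by ≤ `max_intervening` non-RLR genes.  The
default 3 reflects how published array diagrams interleave a few
unrelated genes; no base-pair distance cap is applied, and the flag is
CLI-exposed.  Placing more genes in arrays is monotone in
`max_intervening`.

## Structural-divergence classification

For a sibling pair (tree cherry; same species tag → paralogs):

1. **Exon homology.**  The global protein alignment is computed and each
   exon mapped to alignment columns (an exon covering CDS nucleotides
   [s, e) maps to residues [⌊s/3⌋, ⌈e/3⌉); a codon-split boundary residue
   belongs to the 5′ exon and is flagged).  The overlap between exon i of
   one gene and exon j of the other is counted only over columns where
   *both* sides carry a residue of those exons — raw column spans are
   stretched by ambiguous gap placement and misattribute homology.
   Matching is greedy 5′→3′, 1:1, non-crossing, at reciprocal overlap
   ≥ `tau_overlap` (default 0.5).  Unmatched exons are orphans; an orphan
   lying mostly inside a matched partner exon's span is a split
   candidate (intron gain/loss pattern).
2. **Divergence test.**  A pair is structurally divergent when exon
   counts differ or some matched exon pair has unequal nucleotide length.
3. **Mechanisms.**
   * *Intraexonic indel*: a gap run of ≥ `min_indel_aa` (2) columns
     strictly inside a matched exon pair with ≥ 5 aligned columns on each
     side.  The matched exons must differ in nucleotide length: a genuine
     indel changes the length, whereas balanced insertion+deletion gap
     pairs in equal-length exons are alignment artifacts ("gap wander")
     and are discarded.
   * *Orphan classification*: each orphan of ≥ `min_orphan_aa` (10) aa is
     locally aligned (both strands) against the partner's non-exonic
     sequence (introns + flanks, segments separated by N runs so hits
     cannot span them).  Identity ≥ `id_min` (0.40) over coverage
     ≥ `cov_min` (0.60) — the quantified reading of "aligned with
     confidence", since no published threshold exists — calls
     exonization/pseudoexonization; otherwise exon gain/loss.  Both
     thresholds are CLI-exposed and recorded in output.
   * Split candidates call gain/loss with subtype `intron_gain_loss`.

   Mechanisms may co-occur; the call is symmetric under swapping the two
   genes.  Polarity (which gene gained) is not inferred — that requires
   an outgroup.  Orphans shorter than 10 aa are treated as alignment
   noise and ignored.

## Expression

FPKM[g,s] = counts · 10⁹ / (library_size · gene_length), with
gene_length = spliced CDS length (the transcript-vs-CDS choice is
unstandardized; CDS is what the gene models define).  Differential
expression uses a conditional NB exact test: with common dispersion φ and
counts scaled to a common library size, the group-A sum given the pooled
total follows a beta-binomial with shapes n_a/φ and n_b/φ; φ = 0 reduces
to the exact binomial (Poisson) test, and the two-sided p-value sums all
outcomes no more likely than the observed one.  φ is a single
method-of-moments estimate across genes (median of per-gene
(var − mean)/mean²).  This is a transparent stand-in for an edgeR-style
analysis; **equivalence to edgeR is not claimed**.  log₂FC uses mean FPKM
with pseudocount 0.01.  The default "significant" flag requires both
|log₂FC| ≥ 1.5 and BH FDR ≤ 0.05; `fc_only` mode reproduces the common
looser "upregulated, log₂FC > 1.5" screen, because the two rules coexist
in practice and conflate different questions.

## Codon models

GY94 over the 61 sense codons with F3x4 codon frequencies (products of
position-specific nucleotide frequencies; a small floor keeps them
positive).  ω bounds are [10⁻⁴, 999] (extreme branch estimates are
reported saturated, as codeml does); κ ∈ [10⁻³, 100].  Site models: M0;
M1a (ω0 < 1, 1); M2a (+ω2 > 1); M7 (Beta(p,q) discretized into K = 10
equal-probability categories at their midpoints); M8 (+ω_s > 1); and a
two-ratio branch model with a named foreground edge set.

**Normalization.**  A single scale factor per model makes the expected
substitution rate 1 averaged over the site-class mixture, so ω > 1
classes genuinely evolve faster (per-class normalization would erase the
rate contrast that gives the site tests their power).  Branch models
normalize each matrix separately, keeping branch lengths in expected
substitutions per codon on each branch.

Likelihood is computed by Felsenstein pruning with alignment-column
pattern compression and per-node scaling; transition matrices come from
the symmetrized eigendecomposition of the reversible generator; gaps are
missing data (partial likelihood 1).  Fitting maximizes lnL over κ, the
ω-parameters and all branch lengths with L-BFGS-B on log/logistic
transforms, `ftol` 10⁻⁶, from the input tree's lengths plus seeded random
restarts (default 3).  Nested pairs (M1a⊂M2a, M7⊂M8, M0⊂branch2) are
fitted with an extra start that embeds the null optimum (extra class at
vanishing weight), guaranteeing the nesting inequality to optimizer
tolerance (~10⁻³ lnL) while a default start retains power; LRT p-values
are χ² upper tails (df 2 for the site pairs, 1 for the branch pair) with
negative statistics clamped to zero.

Positively selected sites use **naive empirical Bayes** at the MLEs
(posterior of the ω > 1 class > 0.90).  Full Bayes empirical Bayes, which
integrates over parameter uncertainty, is deliberately not implemented —
NEB is anticonservative when parameters are poorly estimated, so site
flags on small alignments should be read cautiously.

## Synthetic data

Generators emit the exact formats the parsers read, plus truth records.
Gene loci are random sequence: exons are stop-free random codons (40–200
aa by default), introns and flanks uniform random DNA (introns 400–1200
nt, flanks 500 nt).  Background divergence is i.i.d. nucleotide
substitution at the given rate with a 2:1 transition bias, applied
independently to each descendant, with substitutions that would create an
in-frame stop reverted; there are **no background indels**, so planted
truth labels stay unambiguous.  Planted events: exon gain inserts a novel
random exon into an intron; exonization recruits an intron stretch (stops
repaired) as a new exon, leaving the homologous stretch intronic in the
partner; intraexonic deletion removes a whole-codon block with ≥10-aa
intact flanks, capped at 40% of the host exon so the pair remains
recognizably homologous; intron gain splits an exon at a codon boundary.
Planted exon-event sizes default to 100–300 aa, matching documented
single-exon domain-gain events in invertebrate immune receptors; indels
are capped at 60 aa.  Counts are NB with log-normal baseline means,
per-sample depth factors in [0.85, 1.2], and planted genes' group-B means
multiplied by 2^log2FC.

What the generators do **not** emulate: repeats, GC heterogeneity, splice
signals, alignment-guided gene-model error, background indels,
overdispersion trends with expression level, or codon usage bias beyond
F3x4.  Passing recovery tests therefore demonstrates the algorithms are
correct under their stated assumptions, not that real annotations of
comparable divergence will be classified with the same accuracy.

## Validation problem sizes

The recovery and calibration studies use 200 sibling pairs per mechanism
at background divergence 0.1; 500 random protein pairs (length ≤ 12)
against the exhaustive alignment oracle; M0 recovery at 500 codons / 6
taxa over 20 replicates; type-I calibration of M1a-vs-M2a over 200 null
simulations at 80 codons / 4 taxa with one optimizer start; and
differential-expression calibration at 2000 genes, 3 vs 3 replicates,
dispersion 0.1.  These sizes give stable estimates of each rate while
keeping a full validation run to minutes on a single core.

## Known limitations

* Exon matching is greedy and 1:1; reciprocal-overlap ties are broken by
  the larger overlap, then the earlier partner exon.
* Pseudoexonization is reported identically to exonization (no polarity).
* The NB exact test assumes one common dispersion; strongly
  gene-dependent dispersion will miscalibrate extreme counts.
* NEB rather than BEB site identification (above).
* The taxonomy's unanchored labels (L1, L3, L5, L6, X1–X4 structure) are
  configuration, not inference.
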