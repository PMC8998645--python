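# rlrkit

Molecular-evolution analysis of **RIG-I-like receptor (RLR)** gene
families, aimed at invertebrate (especially lophotrochozoan) genomes where
these cytoplasmic viral-RNA sensors have expanded and acquired unusual
N-terminal signaling domains.  The package is for comparative genomicists
who have gene models, domain annotations, gene trees, and RNA-seq counts
in hand and want to ask *how* a duplicated receptor family diversified:

* **Domain-architecture typing** — screen proteins for the RLR core
  (DEXDc + HELICc helicase followed by the C-terminal regulatory domain,
  RD) and classify each gene's ordered N-terminal domain pattern
  (CARD, Death, DED, CASc, IG, SAM, …) into an 11-type repertoire
  taxonomy (A1, V1, V2, C, L1–L6, X).
* **Tandem-array detection** — maximal runs of RLRs along a scaffold with
  at most `max_intervening` unrelated genes between consecutive members.
* **Exon–intron structural divergence** (the core algorithm) — for each
  pair of sibling paralogs/orthologs (a cherry in the gene tree), align
  the proteins, map exons onto the alignment, and classify the
  mechanism(s) that reshaped the gene structure:
  - *gain/loss of exon/intron* — an orphan exon with no homologous
    sequence anywhere in the partner locus, or an exon split by a new
    intron;
  - *exonization/pseudoexonization* — an orphan exon whose sequence
    aligns confidently to **intronic/flanking** sequence of the partner
    (identity ≥ 0.40 over ≥ 0.60 coverage by default);
  - *intraexonic insertion/deletion* — an indel strictly inside a matched
    exon pair.
* **Expression profiling** — FPKM = counts · 10⁹ / (library size · gene
  length), and differential-expression calls from a conditional
  negative-binomial exact test with BH correction at |log₂FC| ≥ 1.5,
  FDR ≤ 0.05.
* **Positive selection** — Goldman–Yang (GY94) codon models: M0, a
  two-ratio branch model, and the site-model pairs M1a/M2a and M7/M8 with
  χ² likelihood-ratio tests; positively selected sites flagged by naive
  empirical Bayes posterior P(ω > 1) > 0.90.

A first-class synthetic-data module generates every input with planted
truth labels (gene structures with planted events, domain tables, scaffold
orders, NB count matrices, codon alignments evolved under known κ/ω), so
each stage is verifiable end to end without downloading any genome.

## Worked example

```python
from rlrkit.synthetic_data import gen_sibling_pair
from rlrkit.structure_divergence import compare_pair

gm_a, gm_b, win_a, win_b, truth = gen_sibling_pair(
    mechanism="EXONIZATION", background_divergence=0.1, seed=3
)
call = compare_pair(gm_a, gm_b, win_a, win_b)
print(sorted(call.mechanisms))
print(call.evidence[0])
```

prints

```
['EXONIZATION_PSEUDOEXONIZATION']
{'mechanism': 'EXONIZATION_PSEUDOEXONIZATION', 'subtype': None,
 'orphan_exon': 2, 'orphan_side': 'a', 'orphan_aa': 125,
 'intronic_identity': 0.7956, 'intronic_coverage': 0.9653}
```

The generator recruited a 125-codon stretch of intron as a new exon in one
descendant; the classifier finds the orphan exon, locally aligns its DNA
against the partner's introns and flanks, and — because the homologous
stretch is still intronic there (80% identity after 2 × 10% background
divergence) — calls exonization rather than exon gain.

The same stages run from the shell:

```bash
rlrkit --seed 1 --out run1 all        # simulate → type → tandem → divergence → expression
rlrkit --seed 1 --out run1 selection --alignment codons.fasta --tree tree.nwk
```

`run1/report.md` ends with a truth-vs-call scorecard, e.g. typing 9/9,
divergence 125/125 pairs, planted-DEG recall 0.90.

## Documentation

`docs/methods.md` describes the models, thresholds, and design decisions,
including what the synthetic generators do and do not emulate about real
genomes.
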