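"""Readers and writers for the external formats the pipeline touches.

Internal coordinates are 0-based half-open throughout; GFF3 (1-based
inclusive) is converted at the boundary.  Only CDS features define the
exons of a :class:`GeneModel` — the analyses downstream compare
protein-coding exon structures, so UTR exons are deliberately ignored.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

# Controlled vocabulary of domain names used by the architecture typing
# stage.  Anything else passes through flagged non-canonical.
CANONICAL_DOMAINS = frozenset(
    ["CARD", "Death", "DED", "CASc", "IG", "SAM", "DEXDc", "HELICc", "RD"]
)

# Core domains shared by every RLR; everything N-terminal of DEXDc is the
# variable region the typing stage classifies.
CORE_DOMAINS = ("DEXDc", "HELICc", "RD")


class GeneModelError(ValueError):
    """A gene record violates a GeneModel invariant."""


@dataclass
class GeneModel:
    """A protein-coding gene: ordered coding exons plus derived sequences.

    ``exons`` are genomic ``(start, end)`` intervals, 0-based half-open,
    listed in transcription (5'→3') order — descending genomic coordinate
    on the minus strand.  ``cds_sequence`` is the spliced,
    strand-corrected coding sequence and ``protein_sequence`` its
    translation with the terminal stop trimmed.
    """

    gene_id: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds_sequence: str
    protein_sequence: str
    has_internal_stop: bool = False

    @property
    def exon_lengths_nt(self) -> list[int]:
        return [e - s for s, e in self.exons]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def validate(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise GeneModelError(f"{self.gene_id}: no exons")
        for s, e in self.exons:
            if s >= e:
                raise GeneModelError(f"{self.gene_id}: empty exon ({s},{e})")
        starts = [s for s, _ in self.exons]
        ordered = sorted(starts) if self.strand == "+" else sorted(starts, reverse=True)
        if starts != ordered:
            raise GeneModelError(f"{self.gene_id}: exons not in transcription order")
        # non-overlap in genomic space
        by_pos = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(by_pos, by_pos[1:]):
            if e1 > s2:
                raise GeneModelError(f"{self.gene_id}: overlapping exons")
        if len(self.cds_sequence) != sum(self.exon_lengths_nt):
            raise GeneModelError(f"{self.gene_id}: CDS length != sum of exon lengths")
        if len(self.cds_sequence) % 3 != 0:
            raise GeneModelError(
                f"{self.gene_id}: CDS length {len(self.cds_sequence)} not divisible by 3"
            )
        expected = translate_cds(self.cds_sequence)[0]
        if expected != self.protein_sequence:
            raise GeneModelError(f"{self.gene_id}: protein does not match CDS translation")


def translate_cds(cds: str) -> tuple[str, bool]:
    """Translate a CDS; trim one terminal stop.  Returns (protein, has_internal_stop)."""
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    internal = "*" in prot
    return prot, internal


def gene_model_from_exons(
    gene_id: str,
    scaffold_id: str,
    strand: str,
    exons: list[tuple[int, int]],
    scaffold_seq: str,
) -> GeneModel:
    """Build and validate a GeneModel by splicing exons out of a scaffold.

    ``exons`` may be given in any order; they are sorted into
    transcription order here.  Minus-strand exons are reverse-complemented
    before splicing.
    """
    exons = sorted(exons, reverse=(strand == "-"))
    parts = []
    for s, e in exons:
        if e > len(scaffold_seq) or s < 0:
            raise GeneModelError(f"{gene_id}: exon ({s},{e}) outside scaffold")
        chunk = scaffold_seq[s:e]
        if strand == "-":
            chunk = str(Seq(chunk).reverse_complement())
        parts.append(chunk)
    cds = "".join(parts)
    if len(cds) % 3 != 0:
        raise GeneModelError(f"{gene_id}: CDS length {len(cds)} not divisible by 3")
    prot, internal = translate_cds(cds)
    gm = GeneModel(gene_id, scaffold_id, strand, exons, cds, prot, internal)
    gm.validate()
    if internal:
        warnings.warn(f"{gene_id}: internal stop codon in CDS", stacklevel=2)
    return gm


def read_fasta(text: str) -> dict[str, str]:
    """Parse FASTA text into an id → sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(io.StringIO(text), "fasta")}


def write_fasta(seqs: dict[str, str]) -> str:
    out = []
    for name, seq in seqs.items():
        out.append(f">{name}")
        for i in range(0, len(seq), 70):
            out.append(seq[i : i + 70])
    return "\n".join(out) + "\n"


def parse_gff3_gene_models(gff3_text: str, genome: dict[str, str] | str) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/CDS features into validated GeneModels.

    GFF3 coordinates (1-based inclusive) are converted to internal 0-based
    half-open.  A missing scaffold is a hard error; a CDS whose total
    length is not divisible by 3 rejects that record with a
    :class:`GeneModelError` naming the gene.  Internal stop codons flag
    the model but do not reject it (pseudoexonization can create them).
    """
    if isinstance(genome, str):
        genome = read_fasta(genome)
    db = gffutils.create_db(
        gff3_text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parents = mrnas if mrnas else [gene]
        # one model per gene: take the first mRNA (synthetic data emits one)
        parent = parents[0]
        cds_feats = sorted(db.children(parent, featuretype="CDS"), key=lambda f: f.start)
        if not cds_feats:
            continue
        scaffold = gene.seqid
        if scaffold not in genome:
            raise KeyError(f"scaffold {scaffold!r} absent from genome FASTA")
        exons = [(f.start - 1, f.end) for f in cds_feats]
        models.append(
            gene_model_from_exons(gene.id, scaffold, gene.strand, exons, genome[scaffold])
        )
    return models


def write_gff3(models: list[GeneModel]) -> str:
    """Emit GeneModels as GFF3 (gene + mRNA + CDS rows, 1-based inclusive)."""
    lines = ["##gff-version 3"]
    for gm in models:
        lo = min(s for s, _ in gm.exons) + 1
        hi = max(e for _, e in gm.exons)
        lines.append(
            f"{gm.scaffold_id}\trlrkit\tgene\t{lo}\t{hi}\t.\t{gm.strand}\t.\tID={gm.gene_id}"
        )
        mid = f"{gm.gene_id}.t1"
        lines.append(
            f"{gm.scaffold_id}\trlrkit\tmRNA\t{lo}\t{hi}\t.\t{gm.strand}\t.\t"
            f"ID={mid};Parent={gm.gene_id}"
        )
        for i, (s, e) in enumerate(sorted(gm.exons)):
            lines.append(
                f"{gm.scaffold_id}\trlrkit\tCDS\t{s + 1}\t{e}\t.\t{gm.strand}\t0\t"
                f"ID={mid}.cds{i};Parent={mid}"
            )
    return "\n".join(lines) + "\n"


@dataclass
class DomainAnnotation:
    """One named domain on a protein, 1-based inclusive aa coordinates."""

    gene_id: str
    domain_name: str
    aa_start: int
    aa_end: int
    canonical: bool = True

    def __post_init__(self):
        if not (1 <= self.aa_start <= self.aa_end):
            raise ValueError(
                f"{self.gene_id}/{self.domain_name}: bad coordinates "
                f"({self.aa_start}, {self.aa_end})"
            )
        self.canonical = self.domain_name in CANONICAL_DOMAINS


def parse_domain_table(tsv_text: str) -> list[DomainAnnotation]:
    """Parse a SMART/Pfam-style domain TSV (gene_id, domain_name, aa_start, aa_end).

    Rows with aa_start > aa_end are rejected with a warning; names outside
    the controlled vocabulary pass through flagged non-canonical.
    Output is sorted by (gene_id, aa_start).
    """
    df = pd.read_csv(
        io.StringIO(tsv_text),
        sep="\t",
        header=None,
        names=["gene_id", "domain_name", "aa_start", "aa_end"],
        comment="#",
        skip_blank_lines=True,
    )
    # tolerate a header row
    if len(df) and str(df.iloc[0]["gene_id"]).lower() == "gene_id":
        df = df.iloc[1:]
    anns = []
    for _, row in df.iterrows():
        start, end = int(row.aa_start), int(row.aa_end)
        if start > end:
            warnings.warn(
                f"domain row rejected (aa_start > aa_end): "
                f"{row.gene_id}/{row.domain_name} {start}>{end}",
                stacklevel=2,
            )
            continue
        anns.append(DomainAnnotation(str(row.gene_id), str(row.domain_name), start, end))
    anns.sort(key=lambda a: (a.gene_id, a.aa_start, a.aa_end))
    return anns


def write_domain_table(anns: list[DomainAnnotation]) -> str:
    return (
        "\n".join(f"{a.gene_id}\t{a.domain_name}\t{a.aa_start}\t{a.aa_end}" for a in anns)
        + "\n"
    )


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a newick tree; duplicate leaf labels are a hard error.

    Branch lengths missing from the input default to 1.0 with a warning.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate leaf labels in tree: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate leaf labels in tree: {dup}")
    missing = [e for e in tree.edges() if e.length is None and e.head_node.parent_node]
    if missing:
        warnings.warn("tree has edges without branch lengths; defaulting to 1.0", stacklevel=2)
        for e in missing:
            e.length = 1.0
    for e in tree.edges():
        if e.length is not None and (not np.isfinite(e.length) or e.length < 0):
            raise ValueError(f"invalid branch length {e.length}")
    return tree


@dataclass
class CountMatrix:
    """Read counts (genes × samples) with per-gene lengths and library sizes.

    Library sizes are mapped-library totals and may exceed the column sums
    of the annotated genes.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    gene_length_nt: np.ndarray
    library_size: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.gene_length_nt = np.asarray(self.gene_length_nt, dtype=np.int64)
        self.library_size = np.asarray(self.library_size, dtype=np.int64)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match gene/sample ids")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.gene_length_nt <= 0).any():
            raise ValueError("non-positive gene length")
        if (self.library_size <= 0).any():
            raise ValueError("non-positive library size")


def parse_counts(
    tsv_text: str, library_size: np.ndarray | list[int] | None = None
) -> CountMatrix:
    """Parse a counts TSV with columns gene_id, length, <sample...>.

    If ``library_size`` is not given it defaults to the column sums (a
    lower bound on the mapped-library totals).
    """
    df = pd.read_csv(io.StringIO(tsv_text), sep="\t", index_col=0)
    if "length" not in df.columns:
        raise ValueError("counts TSV must carry a 'length' column")
    lengths = df.pop("length").to_numpy()
    counts = df.to_numpy()
    if (counts < 0).any():
        raise ValueError("negative counts")
    if library_size is None:
        library_size = np.maximum(counts.sum(axis=0), 1)
    return CountMatrix(
        gene_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        counts=counts,
        gene_length_nt=lengths,
        library_size=np.asarray(library_size),
    )


def write_counts(cm: CountMatrix) -> str:
    df = pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.sample_ids)
    df.insert(0, "length", cm.gene_length_nt)
    df.index.name = "gene_id"
    return df.to_csv(sep="\t")
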