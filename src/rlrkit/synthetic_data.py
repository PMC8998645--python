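"""Synthetic-data generators with planted truth for every pipeline stage.

Each generator emits exactly the formats the pipeline consumes (gene
models + genomic windows, domain tables, scaffold gene orders, count
matrices, codon alignments) together with a truth record sufficient to
score the downstream stage.  Background sequence divergence is applied
as i.i.d. nucleotide substitution with a 2:1 transition bias and no
indels outside the planted event, so truth labels stay unambiguous.
Planted exon-event sizes default to 100–300 aa, the size range of
documented single-exon domain-gain events in invertebrate immune
receptors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .architecture_typing import DEFAULT_TAXONOMY
from .io_formats import CountMatrix, DomainAnnotation, GeneModel, gene_model_from_exons
from .structure_divergence import (
    EXONIZATION,
    GAIN_LOSS,
    INTRAEXONIC_INDEL,
    GenomicWindow,
)
from .tandem_arrays import ScaffoldGeneOrder

_STOPS = ("TAA", "TAG", "TGA")
_NUCS = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _random_codons(rng: np.random.Generator, n_aa: int) -> str:
    """Random stop-free coding sequence of n_aa codons."""
    out = []
    while len(out) < n_aa:
        codon = "".join(rng.choice(list(_NUCS), 3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_NUCS), n))


def _strip_stops(rng: np.random.Generator, seq: str) -> str:
    """Replace in-frame stop codons with random sense codons."""
    codons = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    for i, c in enumerate(codons):
        while codons[i] in _STOPS:
            codons[i] = "".join(rng.choice(list(_NUCS), 3))
    return "".join(codons) + seq[len(codons) * 3 :]


def mutate(
    rng: np.random.Generator, seq: str, rate: float, ts_bias: float = 2.0
) -> str:
    """i.i.d. substitutions at ``rate`` per site with transition:transversion bias."""
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    p_ts = ts_bias / (ts_bias + 1.0)  # transitions vs both transversions combined
    for i in hits:
        base = arr[i]
        if base not in _TRANSITION:
            continue
        if rng.random() < p_ts:
            arr[i] = _TRANSITION[base]
        else:
            choices = [n for n in _NUCS if n != base and n != _TRANSITION[base]]
            arr[i] = choices[rng.integers(len(choices))]
    return "".join(arr)


# ------------------------------------------------------------ gene structures


@dataclass
class _Locus:
    """A gene locus in window coordinates (plus strand)."""

    window_seq: str
    exons: list[tuple[int, int]]  # window coordinates, sorted

    def gene_model(self, gene_id: str, scaffold_id: str) -> GeneModel:
        return gene_model_from_exons(gene_id, scaffold_id, "+", list(self.exons),
                                     self.window_seq)

    def window(self, scaffold_id: str) -> GenomicWindow:
        return GenomicWindow(scaffold_id, 0, self.window_seq)


def gen_ancestral_gene(
    n_exons: int = 5,
    exon_len_aa_range: tuple[int, int] = (40, 200),
    intron_len_range: tuple[int, int] = (400, 1200),
    flank: int = 500,
    seed: int = 0,
) -> tuple[GeneModel, GenomicWindow]:
    """A random multi-exon gene embedded in a random scaffold window.

    Exon lengths are whole codons and the spliced CDS is stop-free, so
    the derived protein is clean by construction.
    """
    if n_exons < 1:
        raise ValueError("n_exons must be ≥ 1")
    rng = np.random.default_rng(seed)
    locus = _make_locus(rng, n_exons, exon_len_aa_range, intron_len_range, flank)
    return locus.gene_model("anc", "anc_w"), locus.window("anc_w")


def _make_locus(rng, n_exons, exon_len_aa_range, intron_len_range, flank) -> _Locus:
    parts = [_random_dna(rng, flank)]
    exons = []
    pos = flank
    for i in range(n_exons):
        aa = int(rng.integers(exon_len_aa_range[0], exon_len_aa_range[1] + 1))
        exon = _random_codons(rng, aa)
        exons.append((pos, pos + len(exon)))
        parts.append(exon)
        pos += len(exon)
        if i < n_exons - 1:
            ilen = int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
            parts.append(_random_dna(rng, ilen))
            pos += ilen
    parts.append(_random_dna(rng, flank))
    return _Locus("".join(parts), exons)


def _diverge(rng: np.random.Generator, locus: _Locus, rate: float) -> _Locus:
    """Background-substitute a locus, keeping the CDS free of stops."""
    seq = mutate(rng, locus.window_seq, rate)
    chars = list(seq)
    # revert any substitution that created an in-frame stop inside an exon
    cds_pos = 0
    for s, e in locus.exons:
        i = s + (3 - cds_pos % 3) % 3  # first complete codon of this exon
        while i + 3 <= e:
            if "".join(chars[i : i + 3]) in _STOPS:
                chars[i : i + 3] = list(locus.window_seq[i : i + 3])
            i += 3
        cds_pos += e - s
    return _Locus("".join(chars), list(locus.exons))


def _shift_exons(exons, at, delta):
    return [
        (s + delta if s >= at else s, e + delta if e > at else e) for s, e in exons
    ]


def _plant_gain(rng, locus: _Locus, event_aa: int) -> tuple[_Locus, int]:
    """Insert a novel-sequence exon into the middle of a random intron."""
    introns = _introns(locus)
    usable = [iv for iv in introns if iv[1] - iv[0] >= 80]
    s, e = usable[rng.integers(len(usable))]
    point = int(rng.integers(s + 30, e - 30))
    new_exon = _random_codons(rng, event_aa)
    seq = locus.window_seq[:point] + new_exon + locus.window_seq[point:]
    exons = _shift_exons(locus.exons, point, len(new_exon))
    exons.append((point, point + len(new_exon)))
    return _Locus(seq, sorted(exons)), event_aa


def _plant_exonization(rng, locus: _Locus, event_aa: int) -> tuple[_Locus, int]:
    """Recruit a stretch of an existing intron as a new coding exon.

    The event is clamped to the largest intron that can host it.
    """
    introns = _introns(locus)
    longest = max(iv[1] - iv[0] for iv in introns)
    event_aa = min(event_aa, (longest - 61) // 3)
    if event_aa < 1:
        raise ValueError("no intron can host an exonization event")
    need = 3 * event_aa
    usable = [iv for iv in introns if iv[1] - iv[0] >= need + 61]
    s, e = usable[rng.integers(len(usable))]
    start = int(rng.integers(s + 30, e - 30 - need + 1))
    stretch = _strip_stops(rng, locus.window_seq[start : start + need])
    seq = locus.window_seq[:start] + stretch + locus.window_seq[start + need :]
    exons = sorted(locus.exons + [(start, start + need)])
    return _Locus(seq, exons), event_aa


def _plant_indel(rng, locus: _Locus, event_aa: int) -> tuple[_Locus, int]:
    """Delete a whole-codon block strictly inside an exon.

    The deletion is clamped to ≤ 40% of the host exon (with 10-aa intact
    flanks) so the exon pair stays recognizably homologous — intraexonic
    indels modify an exon rather than replace most of it.
    """
    longest = max(e - s for s, e in locus.exons)
    event_aa = min(event_aa, (longest - 60) // 3, int(0.4 * longest / 3))
    if event_aa < 2:
        raise ValueError("no exon can host an intraexonic indel")
    need = 3 * event_aa
    candidates = [
        iv for iv in locus.exons
        if iv[1] - iv[0] >= need + 60 and need <= 0.4 * (iv[1] - iv[0])
    ]
    s, e = candidates[rng.integers(len(candidates))]
    lo = s + 30 + (3 - (s + 30) % 3) % 3  # keep codon frame of the window
    hi = e - 30 - need
    start = lo + 3 * int(rng.integers(0, max(1, (hi - lo) // 3 + 1)))
    seq = locus.window_seq[:start] + locus.window_seq[start + need :]
    exons = []
    for xs, xe in locus.exons:
        if (xs, xe) == (s, e):
            exons.append((xs, xe - need))
        else:
            exons.append(
                (xs - need if xs >= start else xs, xe - need if xe > start else xe)
            )
    return _Locus(seq, sorted(exons)), event_aa


def _plant_split(rng, locus: _Locus, intron_len: int = 400) -> _Locus:
    """Insert an intron into the middle of an exon (intron gain)."""
    candidates = [iv for iv in locus.exons if iv[1] - iv[0] >= 180]
    if not candidates:
        candidates = [max(locus.exons, key=lambda iv: iv[1] - iv[0])]
    s, e = candidates[rng.integers(len(candidates))]
    mid = (s + e) // 2
    point = mid - (mid - s) % 3  # codon-boundary split
    intron = _random_dna(rng, intron_len)
    seq = locus.window_seq[:point] + intron + locus.window_seq[point:]
    exons = []
    for xs, xe in locus.exons:
        if (xs, xe) == (s, e):
            exons.append((xs, point))
            exons.append((point + intron_len, xe + intron_len))
        else:
            exons.append(
                (xs + intron_len if xs >= point else xs,
                 xe + intron_len if xe > point else xe)
            )
    return _Locus(seq, sorted(exons))


def _introns(locus: _Locus) -> list[tuple[int, int]]:
    out = []
    for (s1, e1), (s2, e2) in zip(locus.exons, locus.exons[1:]):
        out.append((e1, s2))
    return out


MECHANISM_CHOICES = ("GAIN_LOSS", "EXONIZATION", "INTRAEXONIC_INDEL", "NONE", "SPLIT")


@dataclass
class SiblingTruth:
    mechanism: str  # one of MECHANISM_CHOICES
    expected_call: set[str]  # expected classifier mechanism set
    event_aa: int | None
    carrier: str  # "a" | "b" | ""
    background_divergence: float


def gen_sibling_pair(
    mechanism: str = "EXONIZATION",
    background_divergence: float = 0.1,
    event_aa_range: tuple[int, int] = (100, 300),
    n_exons: int = 5,
    seed: int = 0,
) -> tuple[GeneModel, GeneModel, GenomicWindow, GenomicWindow, SiblingTruth]:
    """Two descendants of a common ancestral gene with one planted event.

    Both descendants carry independent background substitutions at
    ``background_divergence`` per site; the named structural event is
    planted in exactly one of them.
    """
    if mechanism not in MECHANISM_CHOICES:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    if not 0 <= background_divergence <= 0.5:
        raise ValueError("background divergence must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    ancestor = _make_locus(rng, n_exons, (40, 200), (400, 1200), 500)
    loc_a = _diverge(rng, ancestor, background_divergence)
    loc_b = _diverge(rng, ancestor, background_divergence)
    event_aa = int(rng.integers(event_aa_range[0], event_aa_range[1] + 1))
    carrier = "a" if rng.random() < 0.5 else "b"
    target = loc_a if carrier == "a" else loc_b

    if mechanism == "GAIN_LOSS":
        planted, event_aa = _plant_gain(rng, target, event_aa)
        expected = {GAIN_LOSS}
    elif mechanism == "EXONIZATION":
        planted, event_aa = _plant_exonization(rng, target, event_aa)
        expected = {EXONIZATION}
    elif mechanism == "INTRAEXONIC_INDEL":
        # indels live inside one exon, so they are smaller than exon gains
        planted, event_aa = _plant_indel(rng, target, min(event_aa, 60))
        expected = {INTRAEXONIC_INDEL}
    elif mechanism == "SPLIT":
        planted = _plant_split(rng, target)
        expected = {GAIN_LOSS}
        event_aa = None
    else:  # NONE
        planted = target
        expected = set()
        event_aa = None
        carrier = ""

    if carrier == "a":
        loc_a = planted
    elif carrier == "b":
        loc_b = planted
    gm_a = loc_a.gene_model("sib_a", "w_a")
    gm_b = loc_b.gene_model("sib_b", "w_b")
    truth = SiblingTruth(mechanism, expected, event_aa, carrier, background_divergence)
    return gm_a, gm_b, loc_a.window("w_a"), loc_b.window("w_b"), truth


# ------------------------------------------------------------ repertoires

# representative N-terminal pattern for each plantable type label
_LABEL_PATTERNS: dict[str, tuple[str, ...]] = {}
for (_clade, _pat), _label in DEFAULT_TAXONOMY.items():
    _LABEL_PATTERNS.setdefault(_label, _pat)
_LABEL_PATTERNS["X"] = ("SAM", "IG")  # not in the taxonomy → maps to X
_LABEL_CLADES = {"L1": "lophotrochozoa", "L6": "lophotrochozoa"}

_DOMAIN_AA = {"CARD": 90, "Death": 85, "DED": 80, "CASc": 250, "IG": 80, "SAM": 70,
              "DEXDc": 200, "HELICc": 150, "RD": 120}


@dataclass
class RepertoireTruth:
    type_of_gene: dict[str, str]  # gene_id -> planted label
    arrays: list[list[str]]  # planted tandem arrays (member gene ids)
    clade_of_gene: dict[str, str] = field(default_factory=dict)


def gen_repertoire(
    species_spec: dict[str, dict[str, int]],
    tandem_spec: dict[str, list[tuple[int, int]]] | None = None,
    seed: int = 0,
) -> tuple[list[DomainAnnotation], list[ScaffoldGeneOrder], RepertoireTruth]:
    """Domain tables + scaffold gene orders for planted RLR repertoires.

    ``species_spec`` maps species → {type label → count}.  ``tandem_spec``
    maps species → list of (n_members, n_intervening_decoys) arrays; RLRs
    not placed in an array sit isolated on their own scaffold.
    """
    rng = np.random.default_rng(seed)
    tandem_spec = tandem_spec or {}
    domains: list[DomainAnnotation] = []
    orders: list[ScaffoldGeneOrder] = []
    truth = RepertoireTruth({}, [])

    for species, type_counts in sorted(species_spec.items()):
        gene_ids = []
        for label in sorted(type_counts):
            for k in range(type_counts[label]):
                gid = f"{species}_{label}{k + 1}"
                gene_ids.append(gid)
                truth.type_of_gene[gid] = label
                truth.clade_of_gene[gid] = _LABEL_CLADES.get(label, "*")
                pattern = _LABEL_PATTERNS[label] + ("DEXDc", "HELICc", "RD")
                pos = 1
                for name in pattern:
                    ln = _DOMAIN_AA[name]
                    domains.append(DomainAnnotation(gid, name, pos, pos + ln - 1))
                    pos += ln + int(rng.integers(5, 40))
        # genomic placement
        queue = list(gene_ids)
        scaffold_n = 0
        for n_members, n_decoy in tandem_spec.get(species, []):
            members = [queue.pop(0) for _ in range(n_members)]
            truth.arrays.append(members)
            scaffold_n += 1
            ids, starts, flags = [], [], []
            pos = 10_000
            for i, gid in enumerate(members):
                ids.append(gid), starts.append(pos), flags.append(True)
                pos += 20_000
                if i < len(members) - 1:
                    for d in range(n_decoy):
                        ids.append(f"{species}_dec{scaffold_n}_{i}_{d}")
                        starts.append(pos)
                        flags.append(False)
                        pos += 20_000
            orders.append(ScaffoldGeneOrder(f"{species}_sc{scaffold_n}", ids, starts, flags))
        for gid in queue:  # isolated RLRs, flanked by decoys
            scaffold_n += 1
            orders.append(
                ScaffoldGeneOrder(
                    f"{species}_sc{scaffold_n}",
                    [f"{species}_decL{scaffold_n}", gid, f"{species}_decR{scaffold_n}"],
                    [10_000, 30_000, 50_000],
                    [False, True, False],
                )
            )
    return domains, orders, truth


# ------------------------------------------------------------ count matrices


@dataclass
class CountsTruth:
    planted_log2fc: dict[str, float]  # gene_id -> true log2 fold change (B vs A)
    dispersion: float


def gen_counts(
    n_genes: int = 2000,
    n_rep_a: int = 3,
    n_rep_b: int = 3,
    dispersion: float = 0.1,
    planted: dict[int, float] | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, CountsTruth]:
    """Negative-binomial count matrix with planted fold changes.

    Baseline means are log-normal across genes; planted genes multiply
    their group-B mean by 2**log2FC.  Dispersion 0 gives Poisson counts.
    """
    rng = np.random.default_rng(seed)
    planted = planted or {}
    base = np.exp(rng.normal(4.0, 1.5, size=n_genes))
    depth = rng.uniform(0.85, 1.2, size=n_rep_a + n_rep_b)
    mean = np.tile(base[:, None], (1, n_rep_a + n_rep_b)) * depth[None, :]
    for g, lfc in planted.items():
        mean[g, n_rep_a:] *= 2.0 ** lfc

    if dispersion > 0:
        r = 1.0 / dispersion
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mean)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    sample_ids = [f"A{i + 1}" for i in range(n_rep_a)] + [
        f"B{i + 1}" for i in range(n_rep_b)
    ]
    lengths = 3 * rng.integers(100, 1000, size=n_genes)
    lib = np.maximum(counts.sum(axis=0), 1)
    cm = CountMatrix(gene_ids, sample_ids, counts, lengths, lib)
    truth = CountsTruth({gene_ids[g]: lfc for g, lfc in planted.items()}, dispersion)
    return cm, truth
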