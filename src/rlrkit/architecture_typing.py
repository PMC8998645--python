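"""Screening and typing of RLR domain architectures.

An RLR is a protein carrying the helicase core (DEXDc + HELICc) followed
by the C-terminal regulatory domain (RD).  The N-terminal region ahead of
DEXDc is the variable part: its ordered domain pattern is looked up in an
editable taxonomy table to give one of the 11 repertoire types
(A1, V1, V2, C, L1–L6) or X for an unmatched architecture.

Only four of the eleven labels are hard-anchored by the biology
(V1 = CARD-CARD, V2 = empty N-terminus, C = single CARD, A1 = Death in
sponges; L2 = DED and L4 = IG among lophotrochozoan types); the remaining
lineage-specific labels are configurable table entries, and every output
records the taxonomy version used.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import CORE_DOMAINS, DomainAnnotation

RLR_TYPE_LABELS = ("A1", "V1", "V2", "C", "L1", "L2", "L3", "L4", "L5", "L6", "X")

# (clade, n_terminal_pattern) -> label; "*" matches any clade.
# Lineage-restricted entries let the same pattern resolve differently in
# lophotrochozoans (L1/L6) than elsewhere (V1/A1).
DEFAULT_TAXONOMY: dict[tuple[str, tuple[str, ...]], str] = {
    ("*", ()): "V2",
    ("*", ("CARD", "CARD")): "V1",
    ("lophotrochozoa", ("CARD", "CARD", "CARD")): "L1",
    ("*", ("CARD",)): "C",
    ("*", ("Death",)): "A1",
    ("lophotrochozoa", ("Death", "Death")): "L6",
    ("*", ("DED",)): "L2",
    ("*", ("CASc",)): "L3",
    ("*", ("IG",)): "L4",
    ("*", ("SAM",)): "L5",
}
DEFAULT_TAXONOMY_VERSION = "rlrkit-default-1"


@dataclass
class Architecture:
    """Ordered domain architecture of one gene's protein."""

    gene_id: str
    ordered_domains: list[str]
    clade: str | None = None

    @property
    def n_terminal_domains(self) -> list[str]:
        """Domains preceding the first DEXDc, core domains excluded."""
        out = []
        for name in self.ordered_domains:
            if name == "DEXDc":
                break
            if name not in CORE_DOMAINS:
                out.append(name)
        return out


@dataclass
class RLRType:
    label: str
    taxonomy_version: str
    evidence: str = ""  # for X: the unmatched architecture string
    n_terminal_copy_numbers: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in RLR_TYPE_LABELS:
            raise ValueError(f"unknown RLR type label {self.label!r}")


def architecture_from_domains(
    domains: list[DomainAnnotation], clade: str | None = None
) -> Architecture:
    """Build an Architecture from one gene's domain annotations."""
    if not domains:
        raise ValueError("no domains")
    gene_ids = {d.gene_id for d in domains}
    if len(gene_ids) != 1:
        raise ValueError(f"domains from multiple genes: {sorted(gene_ids)}")
    ordered = sorted(domains, key=lambda d: (d.aa_start, d.aa_end))
    return Architecture(domains[0].gene_id, [d.domain_name for d in ordered], clade)


def is_rlr(domains: list[DomainAnnotation]) -> bool:
    """True iff DEXDc, HELICc and RD are all present, in that order.

    This is the screening rule: an intermediate DEAD/DEAH-box helicase
    (DEXDc + HELICc) followed by the C-terminal RD.
    """
    if not domains:
        return False
    ordered = [d.domain_name for d in sorted(domains, key=lambda d: (d.aa_start, d.aa_end))]
    pos = 0
    for want in CORE_DOMAINS:
        try:
            pos = ordered.index(want, pos) + 1
        except ValueError:
            return False
    return True


def _collapse_runs(pattern: tuple[str, ...]) -> tuple[str, ...]:
    out: list[str] = []
    for name in pattern:
        if not out or out[-1] != name:
            out.append(name)
    return tuple(out)


def classify_rlr_type(
    arch: Architecture,
    taxonomy: dict[tuple[str, tuple[str, ...]], str] | None = None,
    taxonomy_version: str = DEFAULT_TAXONOMY_VERSION,
) -> RLRType:
    """Deterministic lookup of the N-terminal pattern in the taxonomy.

    Lookup order: exact pattern under the gene's clade, exact pattern
    under "*", then the same two lookups with runs of a repeated domain
    collapsed to a single copy (copy numbers kept as metadata).  No match
    maps to X with the architecture string as evidence.
    """
    taxonomy = DEFAULT_TAXONOMY if taxonomy is None else taxonomy
    pattern = tuple(arch.n_terminal_domains)
    collapsed = _collapse_runs(pattern)
    copy_numbers = {name: pattern.count(name) for name in collapsed}
    clade = arch.clade or "*"
    for key in ((clade, pattern), ("*", pattern), (clade, collapsed), ("*", collapsed)):
        if key in taxonomy:
            return RLRType(taxonomy[key], taxonomy_version,
                           n_terminal_copy_numbers=copy_numbers)
    return RLRType(
        "X", taxonomy_version, evidence="-".join(pattern) or "(none)",
        n_terminal_copy_numbers=copy_numbers,
    )


def summarize_repertoire(per_species: dict[str, list[RLRType]]) -> pd.DataFrame:
    """Species × type count table with a total column."""
    rows = {}
    for species, types in per_species.items():
        row = {label: 0 for label in RLR_TYPE_LABELS}
        for t in types:
            row[t.label] += 1
        row["total"] = len(types)
        rows[species] = row
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=int)
    df = df.reindex(columns=list(RLR_TYPE_LABELS) + ["total"], fill_value=0)
    df.index.name = "species"
    return df


def parse_taxonomy_table(tsv_text: str) -> dict[tuple[str, tuple[str, ...]], str]:
    """Read a taxonomy TSV with columns clade, n_terminal_pattern, label.

    Patterns are '-'-joined domain names; '(none)' denotes the empty
    N-terminus.
    """
    df = pd.read_csv(io.StringIO(tsv_text), sep="\t", comment="#",
                     names=["clade", "pattern", "label"])
    tax = {}
    for _, row in df.iterrows():
        pat = () if row.pattern in ("(none)", "") else tuple(str(row.pattern).split("-"))
        tax[(str(row.clade), pat)] = str(row.label)
    return tax


def write_taxonomy_table(taxonomy: dict[tuple[str, tuple[str, ...]], str]) -> str:
    lines = []
    for (clade, pat), label in taxonomy.items():
        lines.append(f"{clade}\t{'-'.join(pat) or '(none)'}\t{label}")
    return "\n".join(lines) + "\n"
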