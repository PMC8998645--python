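"""Detection of local tandem-duplication arrays from scaffold gene orders.

A tandem array is a maximal run of ≥2 RLR genes on one scaffold in which
consecutive RLRs are separated by at most ``max_intervening`` non-RLR
genes (default 3, matching depictions of arrays interleaved with a few
unrelated genes).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class ScaffoldGeneOrder:
    """Genes of one scaffold in genomic order with an is_rlr flag each."""

    scaffold_id: str
    gene_ids: list[str]
    starts: list[int]
    is_rlr: list[bool]

    def __post_init__(self):
        if not (len(self.gene_ids) == len(self.starts) == len(self.is_rlr)):
            raise ValueError("ragged scaffold gene order")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"{self.scaffold_id}: duplicate gene ids")
        if sorted(self.starts) != list(self.starts):
            order = sorted(range(len(self.starts)), key=lambda i: self.starts[i])
            self.gene_ids = [self.gene_ids[i] for i in order]
            self.starts = [self.starts[i] for i in order]
            self.is_rlr = [self.is_rlr[i] for i in order]


@dataclass
class TandemArray:
    scaffold_id: str
    member_gene_ids: list[str]  # ≥2, in genomic order
    intervening_gene_counts: list[int]  # between consecutive members

    def __post_init__(self):
        if len(self.member_gene_ids) < 2:
            raise ValueError("tandem array needs ≥2 members")
        if len(self.intervening_gene_counts) != len(self.member_gene_ids) - 1:
            raise ValueError("intervening counts mismatch")


def detect_tandem_arrays(
    orders: list[ScaffoldGeneOrder], max_intervening: int = 3
) -> list[TandemArray]:
    """Maximal runs of RLRs separated by ≤ max_intervening non-RLR genes."""
    if max_intervening < 0:
        raise ValueError("max_intervening must be ≥ 0")
    arrays: list[TandemArray] = []
    for order in orders:
        rlr_idx = [i for i, flag in enumerate(order.is_rlr) if flag]
        run: list[int] = []
        for idx in rlr_idx:
            if run and idx - run[-1] - 1 > max_intervening:
                if len(run) >= 2:
                    arrays.append(_make_array(order, run))
                run = []
            run.append(idx)
        if len(run) >= 2:
            arrays.append(_make_array(order, run))
    return arrays


def _make_array(order: ScaffoldGeneOrder, run: list[int]) -> TandemArray:
    return TandemArray(
        order.scaffold_id,
        [order.gene_ids[i] for i in run],
        [b - a - 1 for a, b in zip(run, run[1:])],
    )


def arrays_to_tsv(arrays: list[TandemArray]) -> str:
    lines = ["scaffold_id\tn_members\tmembers\tintervening"]
    for arr in arrays:
        lines.append(
            f"{arr.scaffold_id}\t{len(arr.member_gene_ids)}\t"
            f"{','.join(arr.member_gene_ids)}\t"
            f"{','.join(map(str, arr.intervening_gene_counts))}"
        )
    return "\n".join(lines) + "\n"
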