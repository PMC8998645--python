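"""FPKM expression profiles and differential-expression calling.

Expression is summarised as FPKM = counts · 10^9 / (library_size ·
gene_length).  Differential expression between two groups of replicates
uses a conditional negative-binomial exact test with a single
moment-estimated common dispersion — a transparent stand-in for the
edgeR-style analysis this kind of study runs; equivalence to edgeR is
not claimed.  Significance uses |log2FC| ≥ 1.5 and BH FDR ≤ 0.05 by
default; a fold-change-only mode reproduces the looser
"upregulated, Log2(FC) > 1.5" call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix


@dataclass
class ExpressionProfile:
    gene_ids: list[str]
    sample_ids: list[str]
    fpkm: np.ndarray  # genes × samples
    sample_labels: dict[str, str] | None = None  # sample -> tissue/condition

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fpkm, index=self.gene_ids, columns=self.sample_ids)
        df.index.name = "gene_id"
        return df

    def to_long(self) -> pd.DataFrame:
        """Heatmap-ready long format: gene_id, sample_id, tissue, fpkm."""
        df = self.to_frame().reset_index().melt(
            id_vars="gene_id", var_name="sample_id", value_name="fpkm"
        )
        labels = self.sample_labels or {}
        df["tissue"] = df["sample_id"].map(lambda s: labels.get(s, s))
        return df


def compute_fpkm(
    cm: CountMatrix, sample_labels: dict[str, str] | None = None
) -> ExpressionProfile:
    """FPKM[g,s] = counts[g,s] · 1e9 / (library_size[s] · gene_length[g])."""
    if (cm.gene_length_nt <= 0).any() or (cm.library_size <= 0).any():
        raise ValueError("gene lengths and library sizes must be positive")
    fpkm = (
        cm.counts * 1e9
        / (cm.library_size[None, :].astype(float) * cm.gene_length_nt[:, None].astype(float))
    )
    return ExpressionProfile(cm.gene_ids, cm.sample_ids, fpkm, sample_labels)


def estimate_common_dispersion(
    counts_a: np.ndarray, counts_b: np.ndarray
) -> float:
    """Method-of-moments common NB dispersion across genes.

    For NB, var = μ + φ μ²; we estimate φ per gene within each group and
    take the median of the positive estimates across genes.
    """
    phis = []
    for grp in (np.atleast_2d(counts_a), np.atleast_2d(counts_b)):
        if grp.shape[1] < 2:
            continue
        mu = grp.mean(axis=1)
        var = grp.var(axis=1, ddof=1)
        ok = mu > 0
        phis.append((var[ok] - mu[ok]) / mu[ok] ** 2)
    if not phis:
        return 0.0
    pooled = np.concatenate(phis)
    if pooled.size == 0:
        return 0.0
    return float(max(0.0, np.median(pooled)))


def nb_exact_test(
    counts_a: np.ndarray | list[int],
    counts_b: np.ndarray | list[int],
    dispersion: float = 0.0,
) -> float:
    """Two-sided exact test for a difference in NB means between groups.

    Conditions on the pooled sum: with common dispersion φ and equal
    effective library sizes, Y_a | Y_a + Y_b = s follows a beta-binomial
    with shape parameters n_a/φ and n_b/φ.  φ = 0 reduces to the exact
    binomial (Poisson) test.  The two-sided p-value sums the
    probabilities of all outcomes no more likely than the observed one.
    All-zero genes return p = 1.
    """
    a = np.asarray(counts_a, dtype=float).ravel()
    b = np.asarray(counts_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs ≥1 replicate")
    ya, yb = int(round(a.sum())), int(round(b.sum()))
    s = ya + yb
    if s == 0:
        return 1.0
    if dispersion < 0:
        raise ValueError("dispersion must be ≥ 0")
    if dispersion == 0:
        pmf = stats.binom.pmf(np.arange(s + 1), s, a.size / (a.size + b.size))
    else:
        r_a, r_b = a.size / dispersion, b.size / dispersion
        y = np.arange(s + 1)
        logp = stats.betabinom.logpmf(y, s, r_a, r_b)
        pmf = np.exp(logp - logp.max())
        pmf /= pmf.sum()
    p = float(pmf[pmf <= pmf[ya] * (1 + 1e-12)].sum())
    return min(1.0, p)


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0,1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    gene_ids: list[str]
    log2fc: np.ndarray  # group B vs group A
    p_value: np.ndarray
    fdr: np.ndarray
    significant_de: np.ndarray  # |log2FC| ≥ threshold AND fdr ≤ alpha
    upregulated: np.ndarray  # log2FC > threshold (AND fdr ≤ alpha unless fc_only)
    dispersion: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "log2fc": self.log2fc,
                "p_value": self.p_value,
                "fdr": self.fdr,
                "significant_de": self.significant_de,
                "upregulated": self.upregulated,
            },
            index=pd.Index(self.gene_ids, name="gene_id"),
        )


def differential_expression(
    cm: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    dispersion: float | None = None,
    lfc_threshold: float = 1.5,
    alpha: float = 0.05,
    pseudocount: float = 0.01,
    fc_only: bool = False,
) -> DEResult:
    """Per-gene NB exact test + BH correction + threshold flags.

    log2FC is computed on mean FPKM (group B over group A) with a small
    pseudocount.  ``fc_only`` reproduces the fold-change-only
    "upregulated" rule (no FDR requirement on the upregulated flag).
    """
    idx_a = [cm.sample_ids.index(s) for s in group_a]
    idx_b = [cm.sample_ids.index(s) for s in group_b]
    counts_a, counts_b = cm.counts[:, idx_a], cm.counts[:, idx_b]
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts_a, counts_b)

    # equalize library sizes so the conditional test's symmetry assumption holds
    lib_a, lib_b = cm.library_size[idx_a], cm.library_size[idx_b]
    ref = stats.gmean(np.concatenate([lib_a, lib_b]).astype(float))
    scaled_a = np.rint(counts_a * (ref / lib_a)[None, :]).astype(np.int64)
    scaled_b = np.rint(counts_b * (ref / lib_b)[None, :]).astype(np.int64)

    p = np.array(
        [
            nb_exact_test(scaled_a[g], scaled_b[g], dispersion)
            for g in range(cm.counts.shape[0])
        ]
    )
    fdr = bh_adjust(p)

    prof = compute_fpkm(cm)
    mean_a = prof.fpkm[:, idx_a].mean(axis=1)
    mean_b = prof.fpkm[:, idx_b].mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    significant = (np.abs(log2fc) >= lfc_threshold) & (fdr <= alpha)
    if fc_only:
        up = log2fc > lfc_threshold
    else:
        up = (log2fc > lfc_threshold) & (fdr <= alpha)
    return DEResult(cm.gene_ids, log2fc, p, fdr, significant, up, dispersion)


def call_degs(
    de: DEResult, lfc_threshold: float = 1.5, alpha: float = 0.05, fc_only: bool = False
) -> pd.DataFrame:
    """Re-apply threshold flags to an existing DEResult."""
    significant = (np.abs(de.log2fc) >= lfc_threshold) & (de.fdr <= alpha)
    if fc_only:
        up = de.log2fc > lfc_threshold
    else:
        up = (de.log2fc > lfc_threshold) & (de.fdr <= alpha)
    return pd.DataFrame(
        {"log2fc": de.log2fc, "fdr": de.fdr, "significant_de": significant,
         "upregulated": up},
        index=pd.Index(de.gene_ids, name="gene_id"),
    )
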