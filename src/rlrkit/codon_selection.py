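"""Goldman–Yang codon-substitution models and positive-selection tests.

The GY94 model describes substitution between the 61 sense codons of the
standard genetic code with instantaneous rates

    q_ij = 0                     more than one nucleotide change
         ∝ π_j                   synonymous transversion
         ∝ κ π_j                 synonymous transition
         ∝ ω π_j                 nonsynonymous transversion
         ∝ ω κ π_j               nonsynonymous transition

scaled so the expected number of substitutions per codon site is 1 at
stationarity.  ω = dN/dS measures selective pressure; ω > 1 is positive
selection.  Site models let ω vary over sites:

* M0 — one ω for all sites
* M1a — nearly neutral: classes ω0 < 1 and ω = 1
* M2a — positive selection: M1a plus a class ω2 > 1
* M7 — ω ~ Beta(p, q), discretized into K equal-probability categories
* M8 — M7 plus a class ω_s > 1
* branch2 — one ω on a foreground branch set, another elsewhere

M1a-vs-M2a and M7-vs-M8 likelihood-ratio tests (χ², 2 df) detect
positively selected sites; sites are then flagged by naive empirical
Bayes (NEB) posterior probability > 0.90 of the ω > 1 class.
Codon frequencies use F3x4 (products of position-specific nucleotide
frequencies).  Likelihoods are computed by Felsenstein pruning with
alignment-column pattern compression; gaps are missing data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import linalg, optimize, stats
from Bio.Data import CodonTable

# ---------------------------------------------------------------- genetic code

_TABLE = CodonTable.unambiguous_dna_by_id[1]
NUCS = "TCAG"
SENSE_CODONS = tuple(
    c for c in ("".join(p) for p in itertools.product(NUCS, repeat=3))
    if c not in _TABLE.stop_codons
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61
AA_OF = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}
_PURINES = {"A", "G"}


def _is_transition(x: str, y: str) -> bool:
    return (x in _PURINES) == (y in _PURINES)


# precompute the single-nucleotide-change structure of the codon graph
_SINGLE_DIFF: list[tuple[int, int, bool, bool]] = []
for _i, _ci in enumerate(SENSE_CODONS):
    for _j, _cj in enumerate(SENSE_CODONS):
        if _i >= _j:
            continue
        diffs = [k for k in range(3) if _ci[k] != _cj[k]]
        if len(diffs) == 1:
            k = diffs[0]
            _SINGLE_DIFF.append(
                (_i, _j, _is_transition(_ci[k], _cj[k]), AA_OF[_ci] == AA_OF[_cj])
            )

GAP_STATE = -1

# ---------------------------------------------------------------- alignment


@dataclass
class CodonAlignment:
    """Aligned coding sequences; gaps in whole-codon units, no in-frame stops."""

    taxa: list[str]
    sequences: list[str]

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa/sequence count mismatch")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("sequences have unequal lengths")
        (ln,) = lengths
        if ln % 3 != 0:
            raise ValueError("alignment length not divisible by 3")
        for taxon, seq in zip(self.taxa, self.sequences):
            for i in range(0, ln, 3):
                codon = seq[i : i + 3].upper()
                if codon == "---":
                    continue
                if "-" in codon:
                    raise ValueError(f"{taxon}: gap not in whole-codon units at {i}")
                if codon in _TABLE.stop_codons:
                    raise ValueError(f"{taxon}: internal stop codon {codon} at {i}")

    @property
    def n_sites(self) -> int:
        return len(self.sequences[0]) // 3

    def encode(self) -> np.ndarray:
        """(ntaxa × nsites) codon-state matrix; gaps/ambiguity → -1."""
        out = np.full((len(self.taxa), self.n_sites), GAP_STATE, dtype=np.int64)
        for t, seq in enumerate(self.sequences):
            su = seq.upper()
            for s in range(self.n_sites):
                out[t, s] = CODON_INDEX.get(su[3 * s : 3 * s + 3], GAP_STATE)
        return out


def f3x4_frequencies(aln: CodonAlignment, floor: float = 1e-6) -> np.ndarray:
    """F3x4 codon frequencies: products of per-position nucleotide freqs."""
    counts = np.full((3, 4), floor)
    nuc_idx = {n: i for i, n in enumerate(NUCS)}
    for seq in aln.sequences:
        su = seq.upper()
        for i in range(0, len(su), 3):
            codon = su[i : i + 3]
            if "-" in codon or "N" in codon:
                continue
            for k in range(3):
                counts[k, nuc_idx[codon[k]]] += 1
    f = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([f[0, nuc_idx[c[0]]] * f[1, nuc_idx[c[1]]] * f[2, nuc_idx[c[2]]]
                   for c in SENSE_CODONS])
    return pi / pi.sum()


# ---------------------------------------------------------------- rate matrix


def gy94_rate_matrix(
    kappa: float, omega: float, pi: np.ndarray, scale: bool = True
) -> np.ndarray:
    """GY94 generator over the 61 sense codons.

    Rows sum to zero; the chain is reversible with stationary ``pi``.
    With ``scale`` the matrix is normalized to 1 expected substitution
    per codon site at stationarity — correct for single-ω models.  Site
    mixtures must instead share one normalization across classes (see
    :func:`mixture_eigens`), so high-ω classes evolve faster than
    purifying ones rather than being rescaled to the same speed.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,) or (pi <= 0).any():
        raise ValueError("pi must be 61 positive frequencies")
    if kappa <= 0 or omega <= 0:
        raise ValueError("kappa and omega must be > 0")
    q = np.zeros((N_CODONS, N_CODONS))
    for i, j, is_ts, is_syn in _SINGLE_DIFF:
        rate = (kappa if is_ts else 1.0) * (1.0 if is_syn else omega)
        q[i, j] = rate * pi[j]
        q[j, i] = rate * pi[i]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if scale:
        return q / -float(pi @ np.diag(q))
    return q


@dataclass
class _Eigen:
    """Reversible-Q eigendecomposition for fast P(t) = exp(Qt)."""

    inv_sqrt_pi: np.ndarray
    sqrt_pi: np.ndarray
    vectors: np.ndarray
    values: np.ndarray

    @classmethod
    def of(cls, q: np.ndarray, pi: np.ndarray) -> "_Eigen":
        sq = np.sqrt(pi)
        b = (q * sq[:, None]) / sq[None, :]
        w, v = linalg.eigh((b + b.T) / 2.0)
        return cls(1.0 / sq, sq, v, w)

    def transition(self, t: float) -> np.ndarray:
        p = (self.vectors * np.exp(self.values * t)) @ self.vectors.T
        p = p * self.inv_sqrt_pi[:, None] * self.sqrt_pi[None, :]
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------- model specs

SITE_MODELS = ("M0", "M1a", "M2a", "M7", "M8")
MODELS = SITE_MODELS + ("branch2",)
OMEGA_MIN, OMEGA_MAX = 1e-4, 999.0


@dataclass
class CodonModelSpec:
    """Parameters of one codon model (only the fields its model uses)."""

    model: str
    kappa: float = 2.0
    pi: np.ndarray | None = None
    omega: float = 0.4  # M0 / branch2 background
    omega_fg: float = 1.0  # branch2 foreground
    foreground: frozenset = frozenset()  # leaf-set signatures of foreground edges
    p0: float = 0.5  # M1a/M2a/M8 first-class weight
    p1: float = 0.3  # M2a neutral-class weight
    omega0: float = 0.1  # M1a/M2a purifying class (< 1)
    omega2: float = 3.0  # M2a positive class (> 1)
    beta_p: float = 0.5
    beta_q: float = 1.5
    omega_s: float = 3.0  # M8 positive class (> 1)
    ncat: int = 10

    def site_classes(self) -> tuple[np.ndarray, np.ndarray]:
        """(probabilities, omegas) of the site-class mixture."""
        if self.model == "M0":
            return np.array([1.0]), np.array([self.omega])
        if self.model == "branch2":
            return np.array([1.0]), np.array([self.omega])  # per-branch handled separately
        if self.model == "M1a":
            return np.array([self.p0, 1 - self.p0]), np.array([self.omega0, 1.0])
        if self.model == "M2a":
            p2 = 1 - self.p0 - self.p1
            return (np.array([self.p0, self.p1, p2]),
                    np.array([self.omega0, 1.0, self.omega2]))
        if self.model in ("M7", "M8"):
            k = self.ncat
            quantiles = (np.arange(k) + 0.5) / k
            cats = stats.beta.ppf(quantiles, self.beta_p, self.beta_q)
            cats = np.clip(cats, OMEGA_MIN, 1.0)
            if self.model == "M7":
                return np.full(k, 1.0 / k), cats
            probs = np.concatenate([np.full(k, self.p0 / k), [1 - self.p0]])
            return probs, np.concatenate([cats, [self.omega_s]])
        raise ValueError(f"unknown model {self.model!r}")

    def positive_class_mask(self) -> np.ndarray:
        _, omegas = self.site_classes()
        return omegas > 1.0


# ---------------------------------------------------------------- tree plumbing


class _FlatTree:
    """Postorder edge list extracted from a dendropy tree."""

    def __init__(self, tree: dendropy.Tree, taxa: list[str]):
        taxon_pos = {t: i for i, t in enumerate(taxa)}
        self.n_leaves = len(taxa)
        nodes = list(tree.postorder_node_iter())
        self.node_id = {id(nd): k for k, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.children: list[list[int]] = [[] for _ in nodes]
        self.leaf_state_row: list[int | None] = [None] * len(nodes)
        self.edge_length: list[float] = [0.0] * len(nodes)  # edge above each node
        self.edge_leafset: list[frozenset] = [frozenset()] * len(nodes)
        self.root = len(nodes) - 1
        leafsets: dict[int, frozenset] = {}
        seen = set()
        for k, nd in enumerate(nodes):
            if nd.is_leaf():
                label = nd.taxon.label
                if label not in taxon_pos:
                    raise ValueError(f"tree leaf {label!r} not in alignment taxa")
                seen.add(label)
                self.leaf_state_row[k] = taxon_pos[label]
                leafsets[k] = frozenset([label])
            else:
                kids = [self.node_id[id(c)] for c in nd.child_nodes()]
                self.children[k] = kids
                leafsets[k] = frozenset().union(*(leafsets[c] for c in kids))
            self.edge_length[k] = float(nd.edge.length or 0.0)
            self.edge_leafset[k] = leafsets[k]
        if seen != set(taxa):
            raise ValueError(f"alignment taxa missing from tree: {set(taxa) - seen}")
        # edges with free lengths: every node except the root
        self.free_edges = [k for k in range(self.n_nodes) if k != self.root]


def _prune_class(
    flat: _FlatTree,
    states: np.ndarray,  # ntaxa × npatterns
    eig_for_edge: list[_Eigen],
    lengths: np.ndarray,
    pi: np.ndarray,
) -> np.ndarray:
    """Per-pattern site likelihood under one ω class (Felsenstein pruning)."""
    npat = states.shape[1]
    partial = {}
    log_scale = np.zeros(npat)
    for k in range(flat.n_nodes):
        if flat.leaf_state_row[k] is not None:
            continue
        prod = np.ones((npat, N_CODONS))
        for c in flat.children[k]:
            p = eig_for_edge[c].transition(lengths[c])
            if flat.leaf_state_row[c] is not None:
                obs = states[flat.leaf_state_row[c]]
                down = np.ones((npat, N_CODONS))
                known = obs != GAP_STATE
                down[known] = p[:, obs[known]].T
            else:
                down = partial.pop(c) @ p.T
            prod *= down
        mx = prod.max(axis=1)
        mx[mx == 0] = 1.0
        prod /= mx[:, None]
        log_scale += np.log(mx)
        partial[k] = prod
    site_like = partial[flat.root] @ pi
    return np.log(np.maximum(site_like, 1e-300)) + log_scale


def _pattern_compress(states: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    patterns, inverse, weights = np.unique(
        states, axis=1, return_inverse=True, return_counts=True
    )
    return patterns, inverse.ravel(), weights.astype(float)


def mixture_eigens(
    spec: CodonModelSpec, probs: np.ndarray, omegas: np.ndarray, pi: np.ndarray
) -> list[_Eigen]:
    """One eigensystem per site class under a common mixture normalization.

    The single scale factor makes branch lengths mean expected
    substitutions per codon averaged over site classes, so ω > 1 classes
    evolve faster than purifying ones.
    """
    qs = [gy94_rate_matrix(spec.kappa, float(om), pi, scale=False) for om in omegas]
    rates = np.array([-float(pi @ np.diag(q)) for q in qs])
    scale = float(probs @ rates)
    return [_Eigen.of(q / scale, pi) for q in qs]


def _class_edge_eigens(
    flat: _FlatTree, spec: CodonModelSpec, pi: np.ndarray,
    probs: np.ndarray, omegas: np.ndarray,
) -> list[list[_Eigen]]:
    """Per-class list of per-edge eigensystems (branch2: per-edge ω)."""
    if spec.model == "branch2":
        eig_bg = _Eigen.of(gy94_rate_matrix(spec.kappa, spec.omega, pi), pi)
        eig_fg = _Eigen.of(gy94_rate_matrix(spec.kappa, spec.omega_fg, pi), pi)
        per_edge = [
            eig_fg if flat.edge_leafset[k] in spec.foreground else eig_bg
            for k in range(flat.n_nodes)
        ]
        return [per_edge]
    eigs = mixture_eigens(spec, probs, omegas, pi)
    return [[e] * flat.n_nodes for e in eigs]


def site_log_likelihoods(
    aln: CodonAlignment, tree: dendropy.Tree, spec: CodonModelSpec,
    lengths: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site log-likelihood and per-site per-class posteriors' ingredients.

    Returns (site_lnL over all sites, class_site_loglike matrix
    (n_classes × n_sites)).
    """
    if spec.pi is None:
        spec.pi = f3x4_frequencies(aln)
    flat = _FlatTree(tree, aln.taxa)
    if lengths is None:
        lengths = np.array(flat.edge_length)
    states = aln.encode()
    patterns, inverse, _ = _pattern_compress(states)
    probs, omegas = spec.site_classes()
    per_class = _class_edge_eigens(flat, spec, spec.pi, probs, omegas)
    class_logl = np.empty((len(per_class), patterns.shape[1]))
    for c, eigs in enumerate(per_class):
        class_logl[c] = _prune_class(flat, patterns, eigs, lengths, spec.pi)
    m = class_logl.max(axis=0)
    mix = np.log(np.exp(class_logl - m).T @ probs) + m
    return mix[inverse], class_logl[:, inverse]


def log_likelihood(
    aln: CodonAlignment, tree: dendropy.Tree, spec: CodonModelSpec
) -> float:
    """Total lnL of the alignment on the tree under one model spec."""
    site_lnl, _ = site_log_likelihoods(aln, tree, spec)
    return float(site_lnl.sum())


# ---------------------------------------------------------------- fitting


@dataclass
class CodonModelFit:
    model: str
    lnl: float
    spec: CodonModelSpec
    branch_lengths: dict[frozenset, float]
    aln: CodonAlignment = field(repr=False)
    tree: dendropy.Tree = field(repr=False)
    n_restarts: int = 1
    converged: bool = True
    trace: list = field(default_factory=list, repr=False)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    p = min(max(p, 1e-6), 1 - 1e-6)
    return float(np.log(p / (1 - p)))


class _Parameterization:
    """Pack/unpack unconstrained optimizer vectors into a CodonModelSpec."""

    def __init__(self, model: str, flat: _FlatTree, foreground: frozenset):
        self.model = model
        self.flat = flat
        self.foreground = foreground
        names = {"M0": ["log_omega"],
                 "branch2": ["log_omega", "log_omega_fg"],
                 "M1a": ["sig_omega0", "logit_p0"],
                 "M2a": ["sig_omega0", "logit_p0", "logit_p1", "log_omega2m1"],
                 "M7": ["log_p", "log_q"],
                 "M8": ["log_p", "log_q", "logit_p0", "log_omegasm1"]}
        self.names = names[model]
        self.n_model = len(self.names) + 1  # + log kappa

    def pack(self, spec: CodonModelSpec, lengths: np.ndarray) -> np.ndarray:
        x = [np.log(spec.kappa)]
        m = self.model
        if m in ("M0", "branch2"):
            x.append(np.log(spec.omega))
        if m == "branch2":
            x.append(np.log(spec.omega_fg))
        if m in ("M1a", "M2a"):
            x += [_logit(spec.omega0), _logit(spec.p0)]
        if m == "M2a":
            x += [_logit(spec.p1 / max(1e-9, 1 - spec.p0)), np.log(max(1e-6, spec.omega2 - 1))]
        if m in ("M7", "M8"):
            x += [np.log(spec.beta_p), np.log(spec.beta_q)]
        if m == "M8":
            x += [_logit(spec.p0), np.log(max(1e-6, spec.omega_s - 1))]
        free = np.log(np.maximum(lengths[self.flat.free_edges], 1e-6))
        return np.concatenate([np.asarray(x, dtype=float), free])

    def unpack(self, x: np.ndarray, pi: np.ndarray) -> tuple[CodonModelSpec, np.ndarray]:
        m = self.model
        kappa = float(np.clip(np.exp(x[0]), 1e-3, 100.0))
        spec = CodonModelSpec(model=m, kappa=kappa, pi=pi, foreground=self.foreground)
        i = 1
        if m in ("M0", "branch2"):
            spec.omega = float(np.clip(np.exp(x[i]), OMEGA_MIN, OMEGA_MAX))
            i += 1
        if m == "branch2":
            spec.omega_fg = float(np.clip(np.exp(x[i]), OMEGA_MIN, OMEGA_MAX))
            i += 1
        if m in ("M1a", "M2a"):
            spec.omega0 = float(np.clip(_sigmoid(x[i]), OMEGA_MIN, 1 - 1e-6))
            spec.p0 = float(np.clip(_sigmoid(x[i + 1]), 1e-6, 1 - 1e-6))
            i += 2
        if m == "M2a":
            rest = 1 - spec.p0
            spec.p1 = float(np.clip(_sigmoid(x[i]) * rest, 1e-9, rest - 1e-9))
            spec.omega2 = float(np.clip(1 + np.exp(x[i + 1]), 1 + 1e-6, OMEGA_MAX))
            i += 2
        if m in ("M7", "M8"):
            spec.beta_p = float(np.clip(np.exp(x[i]), 5e-3, 99.0))
            spec.beta_q = float(np.clip(np.exp(x[i + 1]), 5e-3, 99.0))
            i += 2
        if m == "M8":
            spec.p0 = float(np.clip(_sigmoid(x[i]), 1e-6, 1 - 1e-6))
            spec.omega_s = float(np.clip(1 + np.exp(x[i + 1]), 1 + 1e-6, OMEGA_MAX))
            i += 2
        lengths = np.array(self.flat.edge_length)
        lengths[self.flat.free_edges] = np.clip(np.exp(x[i:]), 1e-8, 50.0)
        return spec, lengths


def fit_model(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    model: str,
    foreground_branches: set[frozenset] | None = None,
    n_restarts: int = 3,
    seed: int = 0,
    init: CodonModelSpec | None = None,
    tol: float = 1e-6,
) -> CodonModelFit:
    """Maximum-likelihood fit of one codon model by bounded quasi-Newton.

    Branch lengths, κ, and the model's ω parameters are optimized jointly
    from the input tree's lengths plus ``n_restarts - 1`` seeded random
    perturbations; deterministic given the seed.  ``foreground_branches``
    (branch2 only) is a set of frozensets of leaf labels, each naming the
    edge subtending exactly those leaves.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if model == "branch2" and not foreground_branches:
        raise ValueError("branch2 requires a nonempty foreground branch set")
    foreground = frozenset(
        frozenset(b) for b in (foreground_branches or ())
    )
    pi = f3x4_frequencies(aln)
    flat = _FlatTree(tree, aln.taxa)
    if model == "branch2":
        known = set(flat.edge_leafset)
        for b in foreground:
            if b not in known:
                raise ValueError(f"no edge subtends leaf set {sorted(b)}")
    states = aln.encode()
    patterns, _, weights = _pattern_compress(states)
    par = _Parameterization(model, flat, foreground)

    def negloglik(x: np.ndarray) -> float:
        spec, lengths = par.unpack(x, pi)
        probs, omegas = spec.site_classes()
        try:
            per_class = _class_edge_eigens(flat, spec, pi, probs, omegas)
            class_logl = np.empty((len(per_class), patterns.shape[1]))
            for c, eigs in enumerate(per_class):
                class_logl[c] = _prune_class(flat, patterns, eigs, lengths, pi)
        except (linalg.LinAlgError, FloatingPointError):
            return 1e10
        m = class_logl.max(axis=0)
        mix = np.log(np.exp(class_logl - m).T @ probs) + m
        val = -float(mix @ weights)
        return val if np.isfinite(val) else 1e10

    base_spec = init or CodonModelSpec(model=model, pi=pi, foreground=foreground)
    lengths0 = np.maximum(np.array(flat.edge_length), 1e-4)
    x0 = par.pack(base_spec, lengths0)
    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(x0 + rng.normal(0, 0.3, size=x0.shape))

    best = None
    trace = []
    for x_start in starts:
        res = optimize.minimize(
            negloglik, x_start, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": tol, "eps": 1e-6},
        )
        trace.append({"lnl": -float(res.fun), "nit": int(res.nit),
                      "converged": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e10:
        raise RuntimeError(f"{model} fit failed to converge: {trace}")
    spec, lengths = par.unpack(best.x, pi)
    bl = {flat.edge_leafset[k]: float(lengths[k]) for k in flat.free_edges}
    return CodonModelFit(
        model=model, lnl=-float(best.fun), spec=spec, branch_lengths=bl,
        aln=aln, tree=tree, n_restarts=len(starts),
        converged=any(t["converged"] for t in trace), trace=trace,
    )


_NESTED_DF = {("M1a", "M2a"): 2, ("M7", "M8"): 2, ("M0", "branch2"): 1}


def fit_nested_pair(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    null_model: str,
    alt_model: str,
    foreground_branches: set[frozenset] | None = None,
    n_restarts: int = 3,
    seed: int = 0,
) -> tuple[CodonModelFit, CodonModelFit, float]:
    """Fit a nested model pair and run its LRT.

    The alternative's first start point embeds the fitted null (the extra
    class gets vanishing weight and the null's branch lengths are
    installed on the tree), so lnL(alt) ≥ lnL(null) up to optimizer
    tolerance by construction.
    """
    if (null_model, alt_model) not in _NESTED_DF:
        raise ValueError(f"not a supported nested pair: {null_model} ⊂ {alt_model}")
    fit0 = fit_model(aln, tree, null_model, foreground_branches=foreground_branches,
                     n_restarts=n_restarts, seed=seed)
    alt_tree = tree.clone(depth=1)
    flat = _FlatTree(tree, aln.taxa)
    leafsets = {}
    nodes_alt = list(alt_tree.postorder_node_iter())
    for nd in nodes_alt:
        if nd.is_leaf():
            leafsets[id(nd)] = frozenset([nd.taxon.label])
        else:
            leafsets[id(nd)] = frozenset().union(
                *(leafsets[id(c)] for c in nd.child_nodes())
            )
        if nd.parent_node is not None and leafsets[id(nd)] in fit0.branch_lengths:
            nd.edge.length = fit0.branch_lengths[leafsets[id(nd)]]
    s0 = fit0.spec
    if alt_model == "M2a":
        init = CodonModelSpec(model="M2a", kappa=s0.kappa, omega0=s0.omega0,
                              p0=s0.p0, p1=(1 - s0.p0) * (1 - 1e-4), omega2=2.0)
    elif alt_model == "M8":
        init = CodonModelSpec(model="M8", kappa=s0.kappa, beta_p=s0.beta_p,
                              beta_q=s0.beta_q, p0=1 - 1e-4, omega_s=2.0)
    else:  # branch2
        init = CodonModelSpec(model="branch2", kappa=s0.kappa, omega=s0.omega,
                              omega_fg=s0.omega)
    # the embedded start guarantees nesting; the default start keeps power
    # when the extra class carries real weight (the embedded one can stall
    # in the flat region around zero weight)
    fit1 = fit_model(aln, alt_tree, alt_model, foreground_branches=foreground_branches,
                     n_restarts=1, seed=seed, init=init)
    fit1b = fit_model(aln, alt_tree, alt_model, foreground_branches=foreground_branches,
                      n_restarts=n_restarts, seed=seed)
    if fit1b.lnl > fit1.lnl:
        fit1 = fit1b
    return fit0, fit1, lrt(fit0.lnl, fit1.lnl, _NESTED_DF[(null_model, alt_model)])


def lrt(lnl_null: float, lnl_alt: float, df: int) -> float:
    """χ² likelihood-ratio test p-value; negative statistics clamp to 0."""
    if df not in (1, 2):
        raise ValueError("df must be 1 or 2")
    stat = max(0.0, 2.0 * (lnl_alt - lnl_null))
    return float(stats.chi2.sf(stat, df))


def neb_sites(fit: CodonModelFit, threshold: float = 0.90) -> np.ndarray:
    """Naive-empirical-Bayes flags: posterior P(ω>1 class) > threshold per site.

    Only valid for site models with a positive-selection class (M2a, M8).
    """
    if fit.model not in ("M2a", "M8"):
        raise ValueError(f"NEB site identification needs M2a or M8, got {fit.model}")
    flat = _FlatTree(fit.tree, fit.aln.taxa)
    lengths = np.array(flat.edge_length)
    for k in flat.free_edges:
        lengths[k] = fit.branch_lengths[flat.edge_leafset[k]]
    _, class_logl = site_log_likelihoods(fit.aln, fit.tree, fit.spec, lengths)
    probs, _ = fit.spec.site_classes()
    m = class_logl.max(axis=0)
    post = probs[:, None] * np.exp(class_logl - m)
    post /= post.sum(axis=0, keepdims=True)
    pos = post[fit.spec.positive_class_mask()].sum(axis=0)
    return pos > threshold


def positive_site_posteriors(fit: CodonModelFit) -> np.ndarray:
    """Per-site posterior probability of the ω > 1 class (NEB)."""
    flat = _FlatTree(fit.tree, fit.aln.taxa)
    lengths = np.array(flat.edge_length)
    for k in flat.free_edges:
        lengths[k] = fit.branch_lengths[flat.edge_leafset[k]]
    _, class_logl = site_log_likelihoods(fit.aln, fit.tree, fit.spec, lengths)
    probs, _ = fit.spec.site_classes()
    m = class_logl.max(axis=0)
    post = probs[:, None] * np.exp(class_logl - m)
    post /= post.sum(axis=0, keepdims=True)
    return post[fit.spec.positive_class_mask()].sum(axis=0)


# ---------------------------------------------------------------- simulation


def simulate_codon_alignment(
    tree: dendropy.Tree,
    spec: CodonModelSpec,
    n_codons: int,
    seed: int = 0,
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve codon sequences root→tips under the spec; returns truth classes.

    Each site draws one ω class at the root and keeps it across the whole
    tree (site models), or uses the per-branch ω (branch2).  The returned
    truth vector holds each site's class index.
    """
    rng = np.random.default_rng(seed)
    if spec.pi is None:
        pi = np.full(N_CODONS, 1.0 / N_CODONS)
    else:
        pi = np.asarray(spec.pi, dtype=float)
    probs, omegas = spec.site_classes()
    classes = rng.choice(len(probs), size=n_codons, p=probs / probs.sum())
    root_states = rng.choice(N_CODONS, size=n_codons, p=pi / pi.sum())

    class_eigs = mixture_eigens(spec, probs, omegas, pi)
    if spec.model == "branch2":
        fg_eig = _Eigen.of(gy94_rate_matrix(spec.kappa, spec.omega_fg, pi), pi)
        bg_eig = _Eigen.of(gy94_rate_matrix(spec.kappa, spec.omega, pi), pi)

    leafsets: dict[int, frozenset] = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            leafsets[id(nd)] = frozenset([nd.taxon.label])
        else:
            leafsets[id(nd)] = frozenset().union(
                *(leafsets[id(c)] for c in nd.child_nodes())
            )

    node_states: dict[int, np.ndarray] = {}
    taxa, seqs = [], []
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            node_states[id(nd)] = root_states.copy()
        else:
            parent = node_states[id(nd.parent_node)]
            t = float(nd.edge.length or 0.0)
            child = parent.copy()
            if t > 0:
                if spec.model == "branch2":
                    fg = leafsets[id(nd)] in spec.foreground
                    site_eigs = {0: fg_eig if fg else bg_eig}
                    site_class = np.zeros(n_codons, dtype=np.int64)
                else:
                    site_eigs = dict(enumerate(class_eigs))
                    site_class = classes
                for c, eig in site_eigs.items():
                    p = eig.transition(t)
                    cum = p.cumsum(axis=1)
                    idx = np.where(site_class == c)[0]
                    u = rng.random(idx.size)
                    child[idx] = np.array(
                        [np.searchsorted(cum[parent[i]], ui) for i, ui in zip(idx, u)],
                        dtype=np.int64,
                    ) if idx.size else child[idx]
                np.clip(child, 0, N_CODONS - 1, out=child)
            node_states[id(nd)] = child
        if nd.is_leaf():
            taxa.append(nd.taxon.label)
            seqs.append("".join(SENSE_CODONS[s] for s in node_states[id(nd)]))
    return CodonAlignment(taxa, seqs), classes
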