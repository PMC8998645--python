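import numpy as np
import pytest

from rlrkit.codon_selection import (
    CODON_INDEX,
    N_CODONS,
    CodonAlignment,
    CodonModelSpec,
    _Eigen,
    f3x4_frequencies,
    fit_model,
    fit_nested_pair,
    gy94_rate_matrix,
    log_likelihood,
    lrt,
    neb_sites,
    simulate_codon_alignment,
)
from rlrkit.io_formats import parse_newick

LNL_TOL = 1e-3  # optimizer convergence tolerance on lnL


@pytest.fixture(scope="module")
def random_pi():
    rng = np.random.default_rng(123)
    pi = rng.dirichlet(np.ones(N_CODONS))
    return np.maximum(pi, 1e-5) / np.maximum(pi, 1e-5).sum()


class TestRateMatrix:
    def test_rows_sum_to_zero(self, random_pi):
        q = gy94_rate_matrix(3.1, 0.7, random_pi)
        assert np.abs(q.sum(axis=1)).max() < 1e-12

    def test_uniform_neutral_case_has_equal_entries(self):
        pi = np.full(N_CODONS, 1.0 / N_CODONS)
        q = gy94_rate_matrix(1.0, 1.0, pi)
        off = q[q > 0]
        assert np.allclose(off, off[0])

    def test_detailed_balance(self, random_pi):
        rng = np.random.default_rng(5)
        for _ in range(3):
            kappa, omega = rng.uniform(0.5, 5), rng.uniform(0.05, 3)
            q = gy94_rate_matrix(kappa, omega, random_pi)
            flux = random_pi[:, None] * q
            assert np.abs(flux - flux.T).max() < 1e-14

    def test_scaled_to_one_substitution(self, random_pi):
        q = gy94_rate_matrix(2.0, 0.5, random_pi)
        assert -(random_pi @ np.diag(q)) == pytest.approx(1.0)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            gy94_rate_matrix(2.0, 0.5, np.ones(10))


class TestLikelihood:
    def test_two_taxon_closed_form(self, random_pi):
        tree = parse_newick("(x:0.15,y:0.25);")
        aln = CodonAlignment(["x", "y"], ["ATGAAA", "ATGCCC"])
        spec = CodonModelSpec(model="M0", kappa=2.0, omega=0.5, pi=random_pi)
        lnl = log_likelihood(aln, tree, spec)
        q = gy94_rate_matrix(2.0, 0.5, random_pi)
        e = _Eigen.of(q, random_pi)
        p1, p2 = e.transition(0.15), e.transition(0.25)
        closed = 0.0
        for ca, cb in (("ATG", "ATG"), ("AAA", "CCC")):
            i, j = CODON_INDEX[ca], CODON_INDEX[cb]
            closed += np.log(np.sum(random_pi * p1[:, i] * p2[:, j]))
        assert lnl == pytest.approx(closed, abs=1e-8)

    def test_zero_branch_identical_sequences_limit(self, random_pi):
        tree = parse_newick("(x:0.0,y:0.0);")
        aln = CodonAlignment(["x", "y"], ["ATGAAA", "ATGAAA"])
        spec = CodonModelSpec(model="M0", kappa=2.0, omega=0.5, pi=random_pi)
        expected = sum(
            np.log(random_pi[CODON_INDEX[c]]) for c in ("ATG", "AAA")
        )
        assert log_likelihood(aln, tree, spec) == pytest.approx(expected, abs=1e-6)

    def test_rerooting_leaves_lnl_unchanged(self):
        """Pulley principle: a reversible model ignores root placement."""
        nwk = "((a:0.1,b:0.2):0.05,(c:0.15,d:0.1):0.07);"
        spec0 = CodonModelSpec(model="M0", kappa=2.0, omega=0.3)
        aln, _ = simulate_codon_alignment(parse_newick(nwk), spec0, 60, seed=4)
        pi = f3x4_frequencies(aln)
        vals = []
        for edge_leaves in (["a"], ["c"], ["a", "b"]):
            tree = parse_newick(nwk)
            node = tree.mrca(taxon_labels=edge_leaves)
            tree.reroot_at_edge(node.edge, length1=node.edge.length / 2,
                                length2=node.edge.length / 2,
                                update_bipartitions=False)
            spec = CodonModelSpec(model="M0", kappa=2.0, omega=0.3, pi=pi)
            vals.append(log_likelihood(aln, tree, spec))
        assert np.ptp(vals) < 1e-8

    def test_leaf_taxa_mismatch_is_error(self):
        tree = parse_newick("(x:0.1,z:0.1);")
        aln = CodonAlignment(["x", "y"], ["ATGAAA", "ATGCCC"])
        spec = CodonModelSpec(model="M0")
        with pytest.raises(ValueError):
            log_likelihood(aln, tree, spec)

    def test_gap_codons_are_missing_data(self):
        tree = parse_newick("(x:0.1,y:0.2);")
        spec = CodonModelSpec(
            model="M0", kappa=2.0, omega=0.5,
            pi=np.full(N_CODONS, 1.0 / N_CODONS),
        )
        with_gap = CodonAlignment(["x", "y"], ["ATG---", "ATGCCC"])
        only_site1 = CodonAlignment(["x", "y"], ["ATG", "ATG"])
        # site 2's partner is unobserved: its contribution is log pi-marginal
        lnl_gap = log_likelihood(with_gap, tree, spec)
        lnl_1 = log_likelihood(only_site1, tree, spec)
        assert lnl_gap == pytest.approx(lnl_1 + np.log(1.0 / N_CODONS), abs=1e-9)


class TestAlignmentValidation:
    def test_partial_codon_gap_rejected(self):
        with pytest.raises(ValueError, match="whole-codon"):
            CodonAlignment(["x", "y"], ["ATG-A-", "ATGCCC"])

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment(["x", "y"], ["ATGTAA", "ATGCCC"])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            CodonAlignment(["x", "y"], ["ATGAAA", "ATG"])


class TestFitting:
    NWK6 = "((a:0.1,b:0.15):0.08,(c:0.12,d:0.1):0.06,(e:0.2,f:0.05):0.1);"

    def test_m0_omega_and_kappa_recovery(self):
        errs_w, errs_k = [], []
        for seed in range(3):
            spec = CodonModelSpec(model="M0", kappa=2.0, omega=0.2)
            aln, _ = simulate_codon_alignment(
                parse_newick(self.NWK6), spec, 500, seed=40 + seed
            )
            fit = fit_model(aln, parse_newick(self.NWK6), "M0",
                            n_restarts=1, seed=0)
            errs_w.append(fit.spec.omega)
            errs_k.append(fit.spec.kappa)
        assert abs(np.mean(errs_w) - 0.2) / 0.2 <= 0.20
        assert abs(np.mean(errs_k) - 2.0) / 2.0 <= 0.25

    def test_nesting_inequality_m1a_m2a(self):
        spec = CodonModelSpec(model="M1a", kappa=2.0, omega0=0.2, p0=0.7)
        nwk = "((a:0.2,b:0.15):0.1,(c:0.12,d:0.18):0.1);"
        aln, _ = simulate_codon_alignment(parse_newick(nwk), spec, 80, seed=3)
        f1, f2, p = fit_nested_pair(aln, parse_newick(nwk), "M1a", "M2a",
                                    n_restarts=1, seed=0)
        assert f2.lnl >= f1.lnl - LNL_TOL
        assert 0.0 <= p <= 1.0

    def test_branch2_with_all_foreground_equals_m0(self):
        nwk = "((a:0.2,b:0.15):0.1,c:0.3);"
        spec0 = CodonModelSpec(model="M0", kappa=2.0, omega=0.4)
        aln, _ = simulate_codon_alignment(parse_newick(nwk), spec0, 120, seed=9)
        tree = parse_newick(nwk)
        all_edges = {
            frozenset(lf.taxon.label for lf in nd.leaf_iter())
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None
        }
        fit_m0 = fit_model(aln, parse_newick(nwk), "M0", n_restarts=1, seed=0)
        fit_b2 = fit_model(aln, parse_newick(nwk), "branch2",
                           foreground_branches=all_edges, n_restarts=1, seed=0)
        assert fit_b2.lnl == pytest.approx(fit_m0.lnl, abs=0.05)

    def test_branch2_requires_foreground(self):
        aln = CodonAlignment(["a", "b"], ["ATGAAA", "ATGCCC"])
        with pytest.raises(ValueError, match="foreground"):
            fit_model(aln, parse_newick("(a:0.1,b:0.1);"), "branch2")

    def test_unknown_foreground_edge_rejected(self):
        nwk = "((a:0.2,b:0.15):0.1,c:0.3);"
        spec0 = CodonModelSpec(model="M0")
        aln, _ = simulate_codon_alignment(parse_newick(nwk), spec0, 30, seed=1)
        with pytest.raises(ValueError, match="no edge"):
            fit_model(aln, parse_newick(nwk), "branch2",
                      foreground_branches={frozenset(["a", "c"])})


class TestLRT:
    def test_zero_delta_gives_p_one(self):
        assert lrt(-100.0, -100.0, 2) == 1.0

    def test_chi2_quantile_df2(self):
        assert lrt(-100.0, -100.0 + 5.99 / 2, 2) == pytest.approx(0.05, abs=2e-3)

    def test_negative_statistic_clamped(self):
        assert lrt(-100.0, -100.5, 2) == 1.0

    def test_bad_df_rejected(self):
        with pytest.raises(ValueError):
            lrt(-10, -9, 3)


class TestNEB:
    def test_wrong_model_is_error(self):
        nwk = "(a:0.1,b:0.1);"
        spec0 = CodonModelSpec(model="M0")
        aln, _ = simulate_codon_alignment(parse_newick(nwk), spec0, 30, seed=2)
        fit = fit_model(aln, parse_newick(nwk), "M0", n_restarts=1, seed=0)
        with pytest.raises(ValueError, match="M2a or M8"):
            neb_sites(fit)

    def test_planted_positive_sites_recovered(self):
        nwk = ("(((a:0.3,b:0.3):0.15,(c:0.3,d:0.3):0.15):0.1,"
               "((e:0.3,f:0.3):0.15,(g:0.3,h:0.3):0.15):0.1);")
        spec = CodonModelSpec(model="M2a", kappa=2.0, omega0=0.1, p0=0.7,
                              p1=0.2, omega2=5.0)
        aln, classes = simulate_codon_alignment(parse_newick(nwk), spec, 200, seed=5)
        _, fit2, p = fit_nested_pair(aln, parse_newick(nwk), "M1a", "M2a",
                                     n_restarts=1, seed=0)
        flags = neb_sites(fit2)
        planted = classes == 2
        assert p < 0.01
        assert (flags & planted).sum() >= 0.5 * planted.sum()
        # false positives rare
        assert (flags & ~planted).sum() <= 0.02 * (~planted).sum() + 1


class TestSimulator:
    def test_zero_branch_lengths_copy_root(self):
        nwk = "((a:0,b:0):0,c:0);"
        spec = CodonModelSpec(model="M0", kappa=2.0, omega=0.5)
        aln, _ = simulate_codon_alignment(parse_newick(nwk), spec, 50, seed=8)
        assert aln.sequences[0] == aln.sequences[1] == aln.sequences[2]

    def test_seed_determinism(self):
        nwk = "((a:0.1,b:0.1):0.1,c:0.1);"
        spec = CodonModelSpec(model="M7", beta_p=0.5, beta_q=1.5)
        a1, c1 = simulate_codon_alignment(parse_newick(nwk), spec, 40, seed=13)
        a2, c2 = simulate_codon_alignment(parse_newick(nwk), spec, 40, seed=13)
        assert a1.sequences == a2.sequences
        assert np.array_equal(c1, c2)

    def test_codon_frequencies_converge_to_pi(self, random_pi):
        """Law of large numbers: simulated root codons follow π."""
        nwk = "(a:0.01,b:0.01);"
        spec = CodonModelSpec(model="M0", kappa=2.0, omega=1.0, pi=random_pi)
        aln, _ = simulate_codon_alignment(parse_newick(nwk), spec, 10_000, seed=3)
        enc = aln.encode()
        freq = np.bincount(enc[0], minlength=N_CODONS) / enc.shape[1]
        assert np.abs(freq - random_pi).max() < 0.012

    def test_site_class_mixture_respected(self):
        nwk = "(a:0.2,b:0.2);"
        spec = CodonModelSpec(model="M2a", p0=0.6, p1=0.3, omega2=4.0)
        _, classes = simulate_codon_alignment(parse_newick(nwk), spec, 5000, seed=6)
        props = np.bincount(classes, minlength=3) / classes.size
        np.testing.assert_allclose(props, [0.6, 0.3, 0.1], atol=0.03)
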