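"""Substitution models, pruning likelihood, optimization, rank-sum test."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import mannwhitneyu

from plastedit.phylo import (
    ProteinAlignment,
    SubstitutionModel,
    Tree5,
    branch_length_contrast,
    discrete_gamma_rates,
    log_likelihood,
    optimize_branch_lengths,
    pairwise_distance,
    read_tree5,
    run_category_contrast,
    transition_probabilities,
    wilcoxon_rank_sum,
    MIN_BRANCH_LENGTH,
)
from plastedit.simulate import simulate_alignment

AA = "ARNDCQEGHILKMFPSTWYV"


@pytest.fixture(scope="module", params=["poisson", "lg", "wag"])
def model(request):
    return SubstitutionModel.named(request.param)


def brute_force_lnl(aln, tree, model):
    """Likelihood by direct summation over all internal-node states."""
    codes = aln.encoded()
    order = [aln.taxa.index(t) for t in tree.taxa]
    codes = codes[order]
    bl = tree.branch_lengths
    lik = np.zeros(aln.n_sites)
    for rate in model.category_rates():
        ps = [model.transition_matrix(b, rate) for b in bl]
        tip = [
            np.hstack([p, np.ones((20, 1))])[:, c] for p, c in zip(ps, codes)
        ]
        lik += np.einsum(
            "r,ra,rb,an,bn,rn->n",
            model.frequencies, ps[5], ps[6],
            tip[0] * tip[1], tip[2] * tip[3], tip[4],
        ) / len(model.category_rates())
    return float(np.log(lik).sum())


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self, model):
        assert np.allclose(transition_probabilities(model, 0.0), np.eye(20))

    def test_long_time_converges_to_frequencies(self, model):
        p = transition_probabilities(model, 100.0)
        assert np.abs(p - model.frequencies[None, :]).max() < 1e-6

    def test_rows_sum_to_one(self, model):
        p = transition_probabilities(model, 0.37)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_poisson_closed_form_and_expm_oracle(self):
        m = SubstitutionModel.poisson()
        t = 0.1
        p = transition_probabilities(m, t)
        closed = 1 / 20 + (19 / 20) * np.exp(-20 * t / 19)
        assert p[0, 0] == pytest.approx(closed, abs=1e-12)
        assert np.abs(p - expm(m.rate_matrix * t)).max() < 1e-10

    def test_chapman_kolmogorov(self, model):
        rng = np.random.default_rng(1)
        for _ in range(3):
            t1, t2 = rng.uniform(0.01, 1.5, size=2)
            lhs = transition_probabilities(model, t1) @ transition_probabilities(
                model, t2
            )
            assert np.abs(lhs - transition_probabilities(model, t1 + t2)).max() < 1e-8

    def test_detailed_balance(self, model):
        p = transition_probabilities(model, 0.4)
        pi = model.frequencies
        assert np.abs(pi[:, None] * p - (pi[:, None] * p).T).max() < 1e-12

    def test_negative_time_errors(self, model):
        with pytest.raises(ValueError):
            transition_probabilities(model, -0.1)

    def test_category_rate_scales_time(self, model):
        a = transition_probabilities(model, 0.2, category_rate=2.0)
        b = transition_probabilities(model, 0.4)
        assert np.allclose(a, b)


def test_discrete_gamma_rates_have_mean_one():
    for alpha in (0.1, 0.5, 1.0, 5.0):
        for k in (2, 4, 8):
            r = discrete_gamma_rates(alpha, k)
            assert r.mean() == pytest.approx(1.0, abs=1e-10)
            assert np.all(np.diff(r) > 0)


class TestLikelihood:
    def _tree(self, rng):
        return Tree5(tuple("abcde"), rng.uniform(0.02, 0.6, size=7))

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        tree = self._tree(rng)
        model = SubstitutionModel.lg(gamma_shape=0.8)
        aln = simulate_alignment(tree, model, 40, seed=9)
        assert log_likelihood(aln, tree, model) == pytest.approx(
            brute_force_lnl(aln, tree, model), abs=1e-8
        )

    def test_gaps_treated_as_missing(self):
        tree = Tree5(tuple("abcde"), np.full(7, 0.1))
        model = SubstitutionModel.poisson()
        aln = ProteinAlignment("x", list("abcde"), ["A-", "AA", "A-", "AX", "A-"])
        # column 2 carries information only for taxon b; still finite
        assert np.isfinite(log_likelihood(aln, tree, model))
        assert log_likelihood(aln, tree, model) == pytest.approx(
            brute_force_lnl(aln, tree, model), abs=1e-8
        )

    def test_pulley_principle_cherry_and_role_swaps(self):
        """Relabeling that preserves the unrooted shape preserves lnL."""
        rng = np.random.default_rng(3)
        bl = rng.uniform(0.05, 0.5, size=7)
        model = SubstitutionModel.lg()
        tree = Tree5(tuple("abcde"), bl)
        aln = simulate_alignment(tree, model, 60, seed=11)
        ref = log_likelihood(aln, tree, model)
        # swap within a cherry
        t2 = Tree5(("b", "a", "c", "d", "e"), bl[[1, 0, 2, 3, 4, 5, 6]])
        # swap the two cherries
        t3 = Tree5(("c", "d", "a", "b", "e"), bl[[2, 3, 0, 1, 4, 6, 5]])
        assert log_likelihood(aln, t2, model) == pytest.approx(ref, abs=1e-8)
        assert log_likelihood(aln, t3, model) == pytest.approx(ref, abs=1e-8)

    def test_taxon_mismatch_lists_missing_labels(self):
        tree = Tree5(tuple("abcde"))
        aln = ProteinAlignment("x", ["a", "b", "c", "d", "zzz"], ["A"] * 5)
        with pytest.raises(ValueError, match="e"):
            log_likelihood(aln, tree, SubstitutionModel.poisson())


class TestOptimization:
    def test_identical_sequences_drive_branches_to_lower_bound(self):
        aln = ProteinAlignment("x", list("abcde"), ["ADKLMW"] * 5)
        tree, info = optimize_branch_lengths(aln, SubstitutionModel.lg(), "e")
        assert np.all(tree.branch_lengths < 1e-6)
        assert info["converged"]

    def test_two_taxon_poisson_matches_closed_form(self):
        rng = np.random.default_rng(4)
        model = SubstitutionModel.poisson()
        n = 4000
        a = "".join(AA[i] for i in rng.integers(0, 20, n))
        b = list(a)
        for i in rng.choice(n, size=600, replace=False):
            b[i] = AA[(AA.index(b[i]) + rng.integers(1, 20)) % 20]
        b = "".join(b)
        p_hat = sum(x != y for x, y in zip(a, b)) / n
        closed = -(19 / 20) * np.log(1 - (20 / 19) * p_hat)
        assert pairwise_distance(a, b, model) == pytest.approx(closed, abs=1e-4)

    def test_recovers_simulated_branch_lengths(self):
        truth = np.array([0.05, 0.07, 0.06, 0.04, 0.5, 0.03, 0.02])
        tree = Tree5(tuple("abcde"), truth)
        model = SubstitutionModel.lg()
        aln = simulate_alignment(tree, model, 5000, seed=42)
        fit, info = optimize_branch_lengths(aln, model, "e")
        assert info["converged"]
        assert np.all(np.abs(fit.branch_lengths - truth) / truth < 0.15)

    def test_local_optimality_after_convergence(self):
        tree = Tree5(tuple("abcde"), np.full(7, 0.15))
        model = SubstitutionModel.poisson()
        aln = simulate_alignment(tree, model, 800, seed=8)
        fit, _ = optimize_branch_lengths(aln, model, "e")
        best = log_likelihood(aln, fit, model)
        for k in range(7):
            for eps in (-1e-3, 1e-3):
                bl = fit.branch_lengths.copy()
                bl[k] = np.clip(bl[k] + eps, MIN_BRANCH_LENGTH, 10.0)
                assert log_likelihood(aln, Tree5(fit.taxa, bl), model) <= best + 1e-7


class TestContrastStatistic:
    def test_equal_branches(self):
        tree = Tree5(tuple("abcde"), np.full(7, 0.1))
        r, d = branch_length_contrast(tree)
        assert r == pytest.approx(1 / 6)
        assert d == pytest.approx(-0.5)

    def test_long_focal_branch(self):
        tree = Tree5(tuple("abcde"), np.array([0.1] * 4 + [1.0] + [0.1] * 2))
        r, d = branch_length_contrast(tree)
        assert r == pytest.approx(1.0 / 0.6)
        assert d == pytest.approx(0.4)

    def test_zero_focal_branch(self):
        tree = Tree5(tuple("abcde"), np.array([0.1] * 4 + [0.0] + [0.1] * 2))
        r, d = branch_length_contrast(tree)
        assert r == 0.0


class TestWilcoxon:
    def test_fully_separated_small_samples_exact(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_large_separation_normal_mode(self):
        _, p = wilcoxon_rank_sum(list(range(1, 31)), list(range(31, 51)),
                                 mode="normal")
        assert p < 1e-8

    def test_exact_matches_scipy_enumeration(self):
        rng = np.random.default_rng(6)
        for m in range(2, 7):
            for n in range(2, 7):
                x = rng.permutation(100)[: m + n].astype(float)
                y = x[m:]
                x = x[:m]
                _, p = wilcoxon_rank_sum(x, y, mode="exact")
                p_scipy = mannwhitneyu(x, y, alternative="two-sided",
                                       method="exact").pvalue
                assert p == pytest.approx(p_scipy, abs=1e-12)

    def test_ratio_and_difference_are_order_isomorphic_at_fixed_s(self):
        # with S constant across proteins, the rank-sum p is identical
        # whether the ratio or the difference variant is used
        rng = np.random.default_rng(7)
        s = 0.6
        bf_x = rng.uniform(0.1, 2.0, size=8)
        bf_y = rng.uniform(0.1, 2.0, size=6)
        rx, dx = bf_x / s, bf_x - s
        ry, dy = bf_y / s, bf_y - s
        assert wilcoxon_rank_sum(rx, ry) == wilcoxon_rank_sum(dx, dy)


class TestCategoryContrast:
    def _panel(self, mult, n_sites=300, seed=0):
        from plastedit.simulate import AlignmentSpec, simulate_protein_set

        spec = AlignmentSpec(
            rate_multiplier={"photosynthetic": 1.0, "non_photosynthetic": mult},
            n_proteins={"photosynthetic": 4, "non_photosynthetic": 4},
            n_sites=n_sites,
        )
        return simulate_protein_set(spec, SubstitutionModel.poisson(), seed=seed)

    def test_strong_effect_detected_and_direction_reported(self):
        alns, cats, _ = self._panel(4.0, n_sites=500, seed=3)
        res = run_category_contrast(
            alns, cats, SubstitutionModel.poisson(), "peDino"
        )
        assert res.p_two_sided < 0.05
        assert res.direction == "non_photosynthetic > photosynthetic"
        assert res.n == {"photosynthetic": 4, "non_photosynthetic": 4}

    def test_empty_category_errors(self):
        alns, cats, _ = self._panel(1.0)
        cats = {k: "photosynthetic" for k in cats}
        with pytest.raises(ValueError, match="non-empty"):
            run_category_contrast(
                alns, cats, SubstitutionModel.poisson(), "peDino"
            )

    def test_uncategorized_protein_errors(self):
        alns, cats, _ = self._panel(1.0)
        del cats[alns[0].name]
        with pytest.raises(ValueError, match="category"):
            run_category_contrast(
                alns, cats, SubstitutionModel.poisson(), "peDino"
            )


def test_read_tree5_checks_topology(tmp_path):
    good = "((Pm:0.1,Pt:0.2):0.05,(Mars:0.1,YPF:0.1):0.04,peDino:0.9);"
    tree = read_tree5(good, "peDino")
    assert tree.focal_taxon == "peDino"
    assert tree.focal_branch_length == pytest.approx(0.9)
    assert sorted(tree.taxa[:2]) == ["Pm", "Pt"]
    bad = "((Pm:0.1,peDino:0.2):0.05,(Mars:0.1,YPF:0.1):0.04,Pt:0.9);"
    with pytest.raises(ValueError, match="topology"):
        read_tree5(bad, "peDino")
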