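"""Clonal-relatedness likelihood test: statistic properties and calibration."""

import math

import numpy as np
import pytest

from lynchevo.clonality import (
    ReferenceFrequencies,
    _max_loglik_batch,
    _mixture_terms,
    _sample_conditional_bernoulli,
    clonality_lr,
    clonality_p,
    estimate_reference_frequencies,
)


def make_ref(p_values):
    p = np.asarray(p_values, dtype=float)
    return ReferenceFrequencies(
        genes=tuple(f"G{i}" for i in range(len(p))),
        p=p, n_reference_samples=100, smoothing=0.5,
    )


class TestReferenceFrequencies:
    def test_pseudocount_arithmetic(self):
        ref = estimate_reference_frequencies(
            (np.array([[1]] * 5 + [[0]] * 5), ["G"]), pseudocount=0.5
        )
        assert ref.p[0] == pytest.approx(5.5 / 11)

    def test_unobserved_gene_smoothed(self):
        ref = estimate_reference_frequencies(
            (np.zeros((10, 1), dtype=int), ["G"]), pseudocount=0.5
        )
        assert ref.p[0] == pytest.approx(0.5 / 11)

    def test_zero_pseudocount_with_zero_hits_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            estimate_reference_frequencies(
                (np.zeros((10, 1), dtype=int), ["G"]), pseudocount=0.0
            )

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_reference_frequencies((np.zeros((3, 0)), []))


class TestLikelihoodRatio:
    def test_disjoint_profiles_give_zero(self):
        ref = make_ref([0.1] * 10)
        lr, xi = clonality_lr({"G0", "G1"}, {"G2", "G3"}, ref)
        assert lr == 0.0 and xi == 0.0

    def test_shared_rare_mutation_closed_form(self):
        # one shared mutation, nothing else: xi_hat -> 1 and
        # lr = -2 log p for marginal probability p
        for p in (0.01, 0.1, 0.5):
            ref = make_ref([p, 0.3, 0.3])
            lr, xi = clonality_lr({"G0"}, {"G0"}, ref)
            assert lr == pytest.approx(-2 * math.log(p), abs=1e-5)
            assert xi > 0.99

    def test_rarer_sharing_gives_larger_statistic(self):
        lr_rare, _ = clonality_lr(
            set(f"G{i}" for i in range(5)), set(f"G{i}" for i in range(5)),
            make_ref([0.01] * 5 + [0.5] * 5),
        )
        lr_common, _ = clonality_lr(
            set(f"G{i}" for i in range(5, 10)), set(f"G{i}" for i in range(5, 10)),
            make_ref([0.01] * 5 + [0.5] * 5),
        )
        assert lr_rare > lr_common > 0

    def test_symmetric_under_tumor_relabeling(self):
        ref = make_ref([0.05, 0.2, 0.4, 0.1])
        a, b = {"G0", "G2"}, {"G0", "G3"}
        assert clonality_lr(a, b, ref) == clonality_lr(b, a, ref)

    def test_statistic_never_negative(self):
        rng = np.random.default_rng(3)
        ref = make_ref(rng.uniform(0.02, 0.4, 12))
        for _ in range(50):
            a = {f"G{i}" for i in range(12) if rng.random() < 0.25}
            b = {f"G{i}" for i in range(12) if rng.random() < 0.25}
            lr, xi = clonality_lr(a, b, ref)
            assert lr >= 0.0
            assert (xi == 0.0) == (lr == 0.0)

    def test_mismatched_universe_rejected(self):
        ref = make_ref([0.1, 0.1])
        with pytest.raises(ValueError, match="universe"):
            clonality_lr({"NOT_A_GENE"}, {"G0"}, ref)

    def test_maximizer_matches_exhaustive_grid_on_three_genes(self):
        # grid search over xi with step 1e-4 agrees to 1e-6 in log-likelihood
        rng = np.random.default_rng(17)
        grid = np.linspace(0.0, 1.0, 10_001)
        for _ in range(20):
            p = rng.uniform(0.02, 0.5, 3)
            a = (rng.random(3) < 0.5).astype(int)
            b = (rng.random(3) < 0.5).astype(int)
            C0, C1 = _mixture_terms(a, b, p)
            ll_max, _, _ = _max_loglik_batch(C0, C1)
            with np.errstate(divide="ignore"):
                ll_grid = np.log(C0[0] + grid[:, None] * C1[0]).sum(axis=1).max()
            assert ll_max[0] == pytest.approx(ll_grid, abs=1e-6)


class TestConditionalBernoulli:
    def test_counts_exactly_preserved(self):
        rng = np.random.default_rng(0)
        p = np.geomspace(0.02, 0.3, 20)
        draws = _sample_conditional_bernoulli(p, 6, 500, rng)
        assert (draws.sum(axis=1) == 6).all()

    def test_inclusion_probabilities_track_weights(self):
        # conditional on the total, rarer genes must be included less often
        rng = np.random.default_rng(1)
        p = np.array([0.05, 0.05, 0.3, 0.3])
        draws = _sample_conditional_bernoulli(p, 2, 4000, rng)
        freq = draws.mean(axis=0)
        assert freq[2] > freq[0] + 0.2
        # exact check against enumeration for k=2 of 4
        w = p / (1 - p)
        states = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        weights = np.array([w[i] * w[j] for i, j in states])
        weights /= weights.sum()
        expected = np.zeros(4)
        for (i, j), wt in zip(states, weights):
            expected[i] += wt
            expected[j] += wt
        assert np.allclose(freq, expected, atol=0.03)


class TestMonteCarloP:
    def test_zero_statistic_gives_p_near_one(self):
        ref = make_ref([0.1] * 10)
        verdict = clonality_p({"G0"}, {"G1"}, ref, n_sim=999, seed=2)
        assert verdict.lr_statistic == 0.0
        assert verdict.p_value > 0.5

    def test_plus_one_correction_keeps_p_positive(self):
        ref = make_ref([0.01] * 30)
        verdict = clonality_p(
            set(f"G{i}" for i in range(8)), set(f"G{i}" for i in range(8)),
            ref, n_sim=999, seed=3,
        )
        assert verdict.p_value >= 1 / 1000
        assert verdict.p_value == pytest.approx(1 / 1000)

    def test_n_sim_floor_enforced(self):
        ref = make_ref([0.1])
        with pytest.raises(ValueError, match="999"):
            clonality_p({"G0"}, {"G0"}, ref, n_sim=99, seed=0)

    def test_seed_reproducibility(self):
        ref = make_ref(np.geomspace(0.02, 0.3, 15))
        a = {f"G{i}" for i in (0, 3, 7)}
        b = {f"G{i}" for i in (0, 3, 9)}
        v1 = clonality_p(a, b, ref, n_sim=999, seed=42)
        v2 = clonality_p(a, b, ref, n_sim=999, seed=42)
        assert v1 == v2
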