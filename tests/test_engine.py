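"""Subset construction, utility mapping, Xi scoring, search and
permutation verification."""

import numpy as np
import pytest
from scipy import stats as sps

from tetractivity.alphabet import random_tetra_space
from tetractivity.engine import (
    make_subsets,
    permutation_verify,
    search,
    utility,
    xi_score,
)
from tetractivity.features import feature_matrix, variant_grid
from tetractivity.profiles import builtin_profiles
from tetractivity.simulate import SyntheticSpec, generate


class TestUtility:
    def test_reference_and_saturation(self):
        assert utility(0.05) == 0.0
        assert utility(1e-6) == 1.0
        assert utility(1e-9) == 1.0  # saturated
        assert utility(1.0) == -1.0

    def test_unfavourable_is_capped_negation(self):
        # a violated assumption (small alpha) costs utility ...
        assert utility(1e-6, "unfavourable") == -1.0
        assert utility(0.01, "unfavourable") == -utility(0.01)
        # ... but merely passing one earns nothing
        assert utility(0.5, "unfavourable") == 0.0
        assert utility(1.0, "unfavourable") == 0.0
        assert utility(0.05, "unfavourable") == 0.0

    def test_monotone_decreasing_in_alpha(self):
        alphas = np.logspace(-10, 0, 50)
        values = [utility(a) for a in alphas]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            utility(0.0)
        with pytest.raises(ValueError):
            utility(1.5)


def _planted_dataset(planted, seed, n=24, slope=2.0, snr=5.0):
    if snr is None:
        spec = SyntheticSpec(
            n=n, L=22, planted=planted, slope=slope, noise_sd=1.0, seed=seed
        )
    else:
        spec = SyntheticSpec(
            n=n, L=22, planted=planted, slope=slope, noise_sd=None, snr=snr, seed=seed
        )
    return generate(spec)


class TestSubsets:
    def test_sizes(self, planted_variant):
        ds, truth = _planted_dataset(planted_variant, 5, n=12)
        subs = make_subsets(ds, truth.feature_values)
        assert [len(s.indices) for s in subs] == [12, 6, 6, 6, 6, 6, 6]
        ds17, truth17 = _planted_dataset(planted_variant, 5, n=17)
        subs17 = make_subsets(ds17, truth17.feature_values)
        assert [len(s.indices) for s in subs17][1:] == [9] * 6

    def test_low_high_split_covers_everything(self, planted_variant):
        ds, truth = _planted_dataset(planted_variant, 6, n=12)
        f = truth.feature_values + np.arange(12) * 1e-9  # force distinct
        subs = make_subsets(ds, f)
        assert set(subs[1].indices) | set(subs[2].indices) == set(range(12))

    def test_selection_semantics(self, planted_variant):
        ds, truth = _planted_dataset(planted_variant, 7, n=12)
        f = truth.feature_values
        subs = make_subsets(ds, f)
        k = 6
        assert set(subs[1].indices) == set(np.argsort(f, kind="stable")[:k])
        assert set(subs[5].indices) == set(np.argsort(-ds.activity, kind="stable")[:k])
        near = np.argsort(np.abs(ds.activity - ds.activity.mean()), kind="stable")[:k]
        assert set(subs[6].indices) == set(near)

    def test_too_small(self, planted_variant):
        ds, truth = _planted_dataset(planted_variant, 5, n=12)
        small = ds.with_activity(ds.activity)
        small.records = small.records[:5]
        small.activity = small.activity[:5]
        with pytest.raises(ValueError):
            make_subsets(small, truth.feature_values[:5])


class TestXiScore:
    def test_xi_is_exact_mean_of_grid(self, planted_variant):
        ds, truth = _planted_dataset(planted_variant, 11)
        ub = xi_score(ds, truth.feature_values)
        assert ub.alphas.shape == ub.utilities.shape == (7, 11)
        assert ub.xi == pytest.approx(ub.utilities.mean(), abs=1e-12)
        assert -1.0 <= ub.xi <= 1.0

    def test_constant_feature_scores_minus_one(self, planted_variant):
        ds, _ = _planted_dataset(planted_variant, 12)
        assert xi_score(ds, np.full(len(ds), 3.0)).xi == -1.0

    def test_planted_signal_scores_positive(self, planted_variant):
        ds, truth = _planted_dataset(planted_variant, 13, n=20, snr=10.0)
        assert xi_score(ds, truth.feature_values).xi > 0


def _small_space(planted, n_tetras=120, n_profiles=4, seed=11):
    tetras = random_tetra_space(n_tetras, seed, include=[planted.tetra])
    profiles = builtin_profiles(22)[:: 360 // max(1, n_profiles - 1)][:n_profiles - 1]
    return variant_grid(tetras, profiles + [planted.profile])


class TestSearch:
    def test_recovers_planted_feature(self, planted_variant):
        variants = _small_space(planted_variant)
        ds, truth = _planted_dataset(planted_variant, 3)
        res = search(ds, variants, screen_top_k=20)
        assert res.useful
        r = np.corrcoef(truth.feature_values, res.best.feature)[0, 1]
        assert res.best.variant.tetra == planted_variant.tetra or abs(r) >= 0.8

    def test_deterministic(self, planted_variant):
        variants = _small_space(planted_variant)
        ds, _ = _planted_dataset(planted_variant, 4)
        res1 = search(ds, variants, screen_top_k=15)
        res2 = search(ds, variants, screen_top_k=15)
        assert [rv.variant for rv in res1.ranked] == [rv.variant for rv in res2.ranked]
        assert [rv.xi for rv in res1.ranked] == [rv.xi for rv in res2.ranked]

    def test_staged_equals_exhaustive_on_small_space(self, planted_variant):
        variants = _small_space(planted_variant, n_tetras=60, n_profiles=3)
        ds, _ = _planted_dataset(planted_variant, 5)
        staged = search(ds, variants, screen_top_k=25)
        exhaustive = search(ds, variants, screen_top_k=len(variants))
        assert staged.best.variant == exhaustive.best.variant

    def test_ranking_sorted_and_tiebreak_deterministic(self, planted_variant):
        variants = _small_space(planted_variant)
        ds, _ = _planted_dataset(planted_variant, 6)
        res = search(ds, variants, screen_top_k=30)
        xis = [rv.xi for rv in res.ranked]
        assert xis == sorted(xis, reverse=True)

    def test_null_data_reports_no_useful_correlation(self, planted_variant):
        variants = _small_space(planted_variant)
        ds, _ = _planted_dataset(planted_variant, 7, slope=0.0, snr=None)
        # slope=0: activity is pure noise, independent of sequence
        res = search(ds, variants, screen_top_k=20)
        assert res.ranked[0].xi == max(rv.xi for rv in res.ranked)
        # spurious best-of-space scores should not look useful
        assert not res.useful

    def test_empty_space_rejected(self, planted_variant):
        ds, _ = _planted_dataset(planted_variant, 8)
        with pytest.raises(ValueError):
            search(ds, [])


class TestPermutationVerify:
    def test_binomial_alpha_closed_form(self, planted_variant):
        variants = _small_space(planted_variant, n_tetras=40, n_profiles=2)
        ds, _ = _planted_dataset(planted_variant, 9)
        fm = feature_matrix(ds, variants)
        res = search(ds, precomputed=fm, screen_top_k=10)
        out = permutation_verify(ds, res.best, fm, cycles=30, screen_top_k=5, seed=2)
        assert out.alpha == pytest.approx(
            sps.binom.cdf(out.recurrences, 30, 0.05), abs=1e-12
        )
        if out.recurrences == 0:
            assert out.alpha == pytest.approx(0.95**30, rel=1e-9)

    def test_planted_signal_survives_permutation(self, planted_variant):
        variants = _small_space(planted_variant, n_tetras=80, n_profiles=3)
        ds, _ = _planted_dataset(planted_variant, 10)
        fm = feature_matrix(ds, variants)
        res = search(ds, precomputed=fm, screen_top_k=15)
        assert res.useful
        out = permutation_verify(ds, res.best, fm, cycles=60, screen_top_k=10, seed=3)
        assert out.significant
        assert out.recurrences <= 2

    def test_single_cycle_not_significant(self, planted_variant):
        variants = _small_space(planted_variant, n_tetras=30, n_profiles=2)
        ds, _ = _planted_dataset(planted_variant, 11)
        fm = feature_matrix(ds, variants)
        res = search(ds, precomputed=fm, screen_top_k=5)
        out = permutation_verify(ds, res.best, fm, cycles=1, screen_top_k=5, seed=4)
        if out.recurrences == 0:
            assert out.alpha == pytest.approx(0.95)
        assert not out.significant
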