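"""CV partitions, AUC / max-TSS scoring against brute-force oracles,
the mean+SD/2 model filter, binarization and committee averaging."""

import itertools

import numpy as np
import pytest

from ensemblesdm.ensemble import (
    FitRecord,
    auc,
    binarize_projection,
    committee_average,
    cutoff_from_moments,
    cv_partitions,
    filter_models,
    max_tss,
    selection_cutoff,
)
from ensemblesdm.geo import GridSpec

try:
    from hypothesis import given
    from hypothesis import strategies as st

    HAVE_HYPOTHESIS = True
except ImportError:  # pragma: no cover
    HAVE_HYPOTHESIS = False


def auc_brute(scores, labels):
    """Independent oracle: count concordant (presence, absence) pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def tss_brute(scores, labels):
    """Independent oracle: exhaustive scan over all threshold positions."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    best = -np.inf
    uniq = np.unique(scores)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]])
    for t in cands:
        pred = scores >= t
        sens = np.sum(pred & (labels == 1)) / labels.sum()
        spec = np.sum(~pred & (labels == 0)) / (labels == 0).sum()
        best = max(best, sens + spec - 1)
    return best


class TestCvPartitions:
    def test_eight_samples_four_folds_of_two(self):
        assign = cv_partitions(8, folds=4, runs=1, seed=0)[0]
        assert sorted(np.bincount(assign)) == [2, 2, 2, 2]

    def test_partition_property(self):
        for assign in cv_partitions(37, folds=4, runs=5, seed=1):
            sizes = np.bincount(assign, minlength=4)
            assert sizes.sum() == 37
            assert sizes.max() - sizes.min() <= 1

    def test_stratified_by_label(self):
        labels = np.array([1] * 20 + [0] * 100)
        assign = cv_partitions(120, folds=4, runs=1, seed=2, labels=labels)[0]
        for f in range(4):
            assert np.sum((assign == f) & (labels == 1)) == 5

    def test_runs_are_distinct_but_reproducible(self):
        runs_a = cv_partitions(40, runs=10, seed=3)
        runs_b = cv_partitions(40, runs=10, seed=3)
        assert all(np.array_equal(a, b) for a, b in zip(runs_a, runs_b))
        assert any(not np.array_equal(runs_a[0], r) for r in runs_a[1:])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            cv_partitions(3, folds=4)


class TestAuc:
    def test_worked_pair_count(self):
        # presences {0.9, 0.4}, absences {0.6, 0.2}: 3 of 4 pairs concordant
        scores = [0.9, 0.4, 0.6, 0.2]
        labels = [1, 1, 0, 0]
        assert auc(scores, labels) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = rng.choice(np.linspace(0, 1, 20), size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        assert auc(scores, labels) == pytest.approx(auc_brute(scores, labels))


class TestMaxTss:
    def test_worked_example(self):
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        labels = [1, 1, 1, 0, 0, 0]
        t, tss = max_tss(scores, labels)
        assert tss == pytest.approx(2.0 / 3.0)
        # thresholds 0.35 and 0.75 tie at TSS = 2/3; smallest wins
        assert t == pytest.approx(0.35)

    def test_perfect_separation(self):
        _, tss = max_tss([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert tss == pytest.approx(1.0)

    def test_identical_scores_give_zero(self):
        _, tss = max_tss([0.4] * 8, [1, 1, 1, 1, 0, 0, 0, 0])
        assert tss == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(8, 200))
        scores = rng.choice(np.linspace(0, 1, 15), size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        _, tss = max_tss(scores, labels)
        assert tss == pytest.approx(tss_brute(scores, labels))

    def test_smallest_threshold_wins_ties(self):
        # thresholds 0.2 and 0.8 both reach TSS = 0.5; the smaller is returned
        scores = [0.9, 0.7, 0.3, 0.1]
        labels = [1, 0, 1, 0]
        t, tss = max_tss(scores, labels)
        assert tss == pytest.approx(0.5)
        assert t == pytest.approx(0.2)


class TestSelectionCutoff:
    def test_mean_plus_half_sd(self):
        vals = [0.9, 1.0, 0.8, 0.95]
        expected = np.mean(vals) + np.std(vals, ddof=1) / 2
        assert selection_cutoff(vals) == pytest.approx(expected)

    def test_constant_values_give_the_constant(self):
        assert selection_cutoff([0.7, 0.7, 0.7]) == pytest.approx(0.7)

    def test_moments_form(self):
        assert cutoff_from_moments(0.5, 0.2) == pytest.approx(0.6)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            selection_cutoff([0.9])


def _record(algo, auc_v, tss_v, run=1, fold=1, thr=0.5):
    return FitRecord(algo, run, fold, auc_v, tss_v, thr)


class TestFilterModels:
    def test_clear_winner_selected(self):
        records = [_record("a", 1.0, 1.0), _record("b", 0.5, 0.5)]
        selected = filter_models(records)
        assert [r.algorithm for r in selected] == ["a"]

    def test_identical_records_trigger_fallback(self):
        records = [_record("a", 0.9, 0.8), _record("b", 0.9, 0.8)]
        with pytest.warns(UserWarning, match="best-TSS"):
            selected = filter_models(records)
        assert len(selected) == 1

    def test_conjunction_of_both_metrics(self):
        records = [
            _record("good", 0.99, 0.95),
            _record("auc_only", 0.98, 0.40),
            _record("neither", 0.60, 0.41),
            _record("low", 0.55, 0.42),
        ]
        selected = filter_models(records)
        assert [r.algorithm for r in selected] == ["good"]


class TestBinarizeAndCommittee:
    def test_threshold_at_half(self):
        rec = _record("a", 0.9, 0.8, thr=0.5)
        out = binarize_projection(np.array([[0.4, 0.6]]), rec)
        assert out.tolist() == [[0.0, 1.0]]

    def test_threshold_at_minimum_keeps_all(self):
        rec = _record("a", 0.9, 0.8, thr=0.1)
        surface = np.array([[0.1, 0.5, np.nan]])
        out = binarize_projection(surface, rec)
        assert out[0, 0] == 1.0 and out[0, 1] == 1.0 and np.isnan(out[0, 2])

    def test_threshold_consistent_with_max_tss_example(self):
        scores = np.array([0.9, 0.8, 0.4, 0.7, 0.3, 0.2])
        labels = np.array([1, 1, 1, 0, 0, 0])
        t, tss = max_tss(scores, labels)
        rec = _record("a", 0.9, tss, thr=t)
        binary = binarize_projection(scores[None, :], rec)
        # t = 0.35 (smallest of the tied maximizers) keeps all three
        # presences and the 0.7 absence -- hand enumeration
        assert binary.tolist() == [[1.0, 1.0, 1.0, 1.0, 0.0, 0.0]]

    def test_out_of_range_threshold_warns_but_applies(self):
        rec = _record("a", 0.9, 0.8, thr=0.99)
        with pytest.warns(UserWarning, match="outside"):
            out = binarize_projection(np.array([[0.1, 0.2]]), rec)
        assert out.tolist() == [[0.0, 0.0]]

    def _grid(self, shape):
        return GridSpec(0.0, float(shape[0]), 1.0, *shape)

    def test_half_agreement_gives_half(self):
        # cell 0 splits 2-2; cells 1 and 2 are unanimous so the committee
        # already spans [0, 1] and normalization is the identity
        grid = self._grid((1, 3))
        binaries = [np.array([[1.0, 1.0, 0.0]]), np.array([[1.0, 1.0, 0.0]]),
                    np.array([[0.0, 1.0, 0.0]]), np.array([[0.0, 1.0, 0.0]])]
        surf = committee_average(binaries, grid)
        assert surf.raster.values[0, 0] == pytest.approx(0.5)
        assert surf.raster.values[0, 1] == 1.0
        assert surf.raster.values[0, 2] == 0.0

    def test_constant_positive_surface_normalizes_to_one(self):
        grid = self._grid((1, 2))
        binaries = [np.array([[1.0, 1.0]]), np.array([[1.0, 1.0]]),
                    np.array([[1.0, 1.0]]), np.array([[1.0, 1.0]])]
        surf = committee_average(binaries, grid)
        assert np.all(surf.raster.values == 1.0)

    def test_unanimous_presence_is_one(self):
        grid = self._grid((2, 2))
        binaries = [np.ones((2, 2))] * 3
        surf = committee_average(binaries, grid)
        assert np.all(surf.raster.values == 1.0)

    def test_single_binary_is_identity(self):
        grid = self._grid((1, 3))
        b = np.array([[1.0, 0.0, 1.0]])
        surf = committee_average([b], grid)
        assert np.array_equal(surf.raster.values, b)

    def test_permutation_invariance_and_bounds(self, rng):
        grid = self._grid((4, 4))
        binaries = [rng.integers(0, 2, (4, 4)).astype(float) for _ in range(5)]
        s1 = committee_average(binaries, grid)
        s2 = committee_average(binaries[::-1], grid)
        assert np.array_equal(s1.raster.values, s2.raster.values)
        assert s1.raster.values.min() >= 0 and s1.raster.values.max() <= 1

    def test_grid_mismatch_rejected(self):
        grid = self._grid((2, 2))
        with pytest.raises(ValueError):
            committee_average([np.ones((3, 3))], grid)
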