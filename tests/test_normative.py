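import numpy as np
import pytest

from icodiff.geometry import Parcellation, make_parcellation
from icodiff.normative import (
    abnormal_scores,
    classification_eval,
    roi_means,
    template_reference,
)


@pytest.fixture
def parc2(ico2):
    return make_parcellation(ico2, 34, seed=0)


class TestRoiMeans:
    def test_constant_map(self, parc2):
        assert np.allclose(roi_means(np.full(162, 2.5), parc2), 2.5)

    def test_hand_case(self):
        parc = Parcellation(labels=np.array([0, 0, 1]), n_rois=2)
        assert np.allclose(roi_means(np.array([1.0, 3.0, 5.0]), parc), [2.0, 5.0])

    def test_matches_loop_oracle(self, parc2, rng):
        x = rng.standard_normal(162)
        mine = roi_means(x, parc2)
        oracle = np.array([x[parc2.labels == r].mean() for r in range(34)])
        assert np.abs(mine - oracle).max() < 1e-12

    def test_empty_roi_gets_nan(self):
        parc = Parcellation(labels=np.array([0, 0, 2]), n_rois=3)
        out = roi_means(np.array([1.0, 2.0, 3.0]), parc)
        assert np.isnan(out[1]) and out[0] == 1.5

    def test_shape_mismatch(self, parc2):
        with pytest.raises(ValueError):
            roi_means(np.zeros(100), parc2)


class TestAbnormalScores:
    def test_hand_computed_z(self):
        # reference ROI means {1,2,3}, subject 4 -> (4-2)/sd([1,2,3], N-1) = 2
        parc = Parcellation(labels=np.zeros(4, dtype=int), n_rois=1)
        samples = np.array([[1.0] * 4, [2.0] * 4, [3.0] * 4])
        table = abnormal_scores(np.full(4, 4.0), samples, parc)
        assert table.z[0] == pytest.approx(2.0)

    def test_subject_equal_to_sample_mean_scores_zero(self, parc2, rng):
        samples = rng.standard_normal((10, 162))
        table = abnormal_scores(samples.mean(axis=0), samples, parc2)
        assert np.abs(table.z).max() < 1e-10

    def test_location_scale_invariance(self, parc2, rng):
        subject = rng.standard_normal(162)
        samples = rng.standard_normal((10, 162))
        z0 = abnormal_scores(subject, samples, parc2).z
        z1 = abnormal_scores(3.0 * subject - 2.0, 3.0 * samples - 2.0, parc2).z
        assert np.allclose(z0, z1, atol=1e-10)

    def test_local_shift_moves_only_that_roi(self, parc2, rng):
        subject = rng.standard_normal(162)
        samples = rng.standard_normal((10, 162))
        z0 = abnormal_scores(subject, samples, parc2).z
        roi = 5
        shifted = subject.copy()
        shifted[parc2.labels == roi] += 0.7
        z1 = abnormal_scores(shifted, samples, parc2).z
        moved = np.flatnonzero(~np.isclose(z0, z1, atol=1e-12))
        assert list(moved) == [roi]
        sd = roi_means(samples, parc2)[:, roi].std(ddof=1)
        assert z1[roi] - z0[roi] == pytest.approx(0.7 / sd)

    def test_degenerate_roi_sentinel(self):
        parc = Parcellation(labels=np.zeros(3, dtype=int), n_rois=1)
        samples = np.ones((5, 3))
        table = abnormal_scores(np.full(3, 2.0), samples, parc)
        assert table.degenerate_rois == [0]
        assert np.isposinf(table.z[0])

    def test_requires_two_samples(self, parc2):
        with pytest.raises(ValueError):
            abnormal_scores(np.zeros(162), np.zeros((1, 162)), parc2)

    def test_reference_distribution_calibration(self, parc2, rng):
        # subjects drawn from the reference distribution itself: z ~ mean 0,
        # variance mildly inflated by the N=10 estimate of the spread
        zs = []
        for _ in range(300):
            samples = rng.standard_normal((10, 162))
            subject = rng.standard_normal(162)
            zs.append(abnormal_scores(subject, samples, parc2).z)
        zs = np.concatenate(zs)
        assert abs(zs.mean()) < 0.2
        assert 0.6 < zs.var() < 1.8


class TestTemplateReference:
    def test_sort_by_distance_oracle(self):
        idx = template_reference(np.array([60.0, 61.0, 70.0, 80.0]), 62.0, k=2)
        assert list(idx) == [1, 0]

    def test_exact_age_match_included(self):
        ages = np.array([50.0, 63.0, 71.0, 88.0])
        assert 2 in template_reference(ages, 71.0, k=3)

    def test_k_equal_cohort_returns_all(self):
        ages = np.arange(5, dtype=float)
        assert sorted(template_reference(ages, 2.0, k=5)) == [0, 1, 2, 3, 4]

    def test_tie_breaks_toward_smaller_index(self):
        idx = template_reference(np.array([64.0, 66.0, 64.0]), 65.0, k=2)
        assert list(idx) == [0, 1]

    def test_insufficient_cohort(self):
        with pytest.raises(ValueError):
            template_reference(np.array([60.0]), 61.0, k=2)


class TestClassification:
    def _separable(self, rng, n=40, d=34, shift=5.0):
        X = rng.standard_normal((n, d))
        y = np.array(["CN"] * (n // 2) + ["AD"] * (n // 2))
        X[n // 2 :, :3] -= shift
        return X, y

    def test_separable_scores_classify_well(self, rng):
        X, y = self._separable(rng)
        report = classification_eval(X, y, folds=10, seed=0)
        assert report["accuracy"] >= 0.95

    def test_permuted_labels_are_at_chance(self, rng):
        X, _ = self._separable(rng, n=100, shift=0.0)
        y = np.array(["A"] * 50 + ["B"] * 50)
        report = classification_eval(X, rng.permutation(y), folds=10, seed=1)
        assert abs(report["accuracy"] - 0.5) < 0.2  # binomial noise band

    def test_deterministic_given_seed(self, rng):
        X, y = self._separable(rng)
        a = classification_eval(X, y, folds=5, seed=3)
        b = classification_eval(X, y, folds=5, seed=3)
        assert a == b

    def test_single_class_raises(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValueError):
            classification_eval(X, np.array(["CN"] * 10), folds=2)
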