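"""Transition-probability estimation, model fitting and the gk-NN blend."""

import numpy as np
import pandas as pd
import pytest

from bamboomap.geostat import (
    ConditionalProbabilityModel,
    EmpiricalTransitionCurve,
    GkNNConfig,
    empirical_transitions,
    fit_all_transitions,
    fit_transition_model,
    gknn_classify,
    lag_bins,
)
from bamboomap.knn import NeighborSet, find_neighbors, knn_classify
from bamboomap.samples import FIELD, SampleSet

from conftest import random_sample_set


def point_set(points):
    """points: list of (class_label, row, col)."""
    df = pd.DataFrame({
        "segment_id": np.arange(1, len(points) + 1),
        "class_label": [p[0] for p in points],
        "provenance": FIELD,
        "row": [float(p[1]) for p in points],
        "col": [float(p[2]) for p in points],
        "f0": 0.0,
    })
    return SampleSet(df)


class TestEmpiricalTransitions:
    def test_two_same_class_samples_give_unit_probability(self):
        s = point_set([("a", 0, 0), ("a", 0, 10)])
        curves = empirical_transitions(s, bin_width=5.0)
        cu = curves[("a", "a")]
        b = np.searchsorted(np.arange(0, cu.bin_centers[-1] + 5, 5.0),
                            10.0, side="right") - 1
        assert cu.probabilities[b] == 1.0
        assert cu.pair_counts[b] == 2  # both ordered pairs

    def test_checkerboard_has_zero_same_class_probability_at_unit_lag(self):
        pts = [("a" if (i + j) % 2 == 0 else "b", i, j)
               for i in range(6) for j in range(6)]
        # bin width 0.25 so bin [1.0, 1.25) holds exactly the unit-lag
        # pairs (diagonal same-class pairs sit at sqrt(2) ~ 1.41)
        curves = empirical_transitions(point_set(pts), bin_width=0.25)
        for c in ("a", "b"):
            cu = curves[(c, c)]
            assert cu.pair_counts[4] > 0
            assert cu.probabilities[4] == 0.0

    def test_matches_pair_enumeration_oracle_exactly(self):
        s = random_sample_set(100, 3, 1, seed=21)
        width = 5.0
        curves = empirical_transitions(s, bin_width=width)
        labels = s.labels()
        cent = s.centroids()
        classes = s.classes
        n_bins = len(next(iter(curves.values())).bin_centers)
        counts = {(m, mp): np.zeros(n_bins) for m in classes for mp in classes}
        for i in range(100):
            for j in range(100):
                if i == j:
                    continue
                h = np.linalg.norm(cent[i] - cent[j])
                b = min(int(h // width), n_bins - 1)
                counts[(labels[i], labels[j])][b] += 1
        for m in classes:
            row_tot = sum(counts[(m, mp)] for mp in classes)
            for mp in classes:
                cu = curves[(m, mp)]
                np.testing.assert_array_equal(cu.pair_counts, row_tot)
                expected = np.divide(counts[(m, mp)], row_tot,
                                     out=np.full(n_bins, np.nan),
                                     where=row_tot > 0)
                got = cu.probabilities
                mask = row_tot > 0
                np.testing.assert_array_equal(got[mask], expected[mask])
                assert np.isnan(got[~mask]).all()

    def test_per_bin_row_normalization(self):
        s = random_sample_set(40, 4, 1, seed=22)
        curves = empirical_transitions(s, bin_width=10.0)
        classes = s.classes
        any_curve = curves[(classes[0], classes[0])]
        for m in classes:
            tot = np.zeros_like(any_curve.probabilities)
            counts = curves[(m, classes[0])].pair_counts
            for mp in classes:
                p = curves[(m, mp)].probabilities
                tot = tot + np.where(np.isnan(p), 0.0, p)
            np.testing.assert_allclose(tot[counts > 0], 1.0, atol=1e-9)


class TestFitTransitionModel:
    @pytest.mark.parametrize("family", ["spherical", "exponential",
                                        "gaussian"])
    def test_noise_free_parameter_recovery(self, family):
        h = np.arange(2.5, 200, 5.0)
        true = ConditionalProbabilityModel("a", "a", family, 0.9, 0.2, 70.0)
        curve = EmpiricalTransitionCurve("a", "a", h, 5.0, true(h),
                                         np.full(len(h), 50.0))
        m = fit_transition_model(curve, family=family)
        assert abs(m.p0 - 0.9) < 1e-6
        assert abs(m.sill - 0.2) < 1e-6
        assert abs(m.range_ - 70.0) < 1e-6

    def test_auto_family_picks_generating_family(self):
        h = np.arange(2.5, 200, 5.0)
        true = ConditionalProbabilityModel("a", "a", "spherical",
                                           0.85, 0.15, 60.0)
        curve = EmpiricalTransitionCurve("a", "a", h, 5.0, true(h),
                                         np.full(len(h), 50.0))
        m = fit_transition_model(curve, family="auto")
        assert m.family == "spherical"
        assert abs(m.range_ - 60.0) < 1e-4

    def test_flat_curve_flagged_unidentifiable(self):
        h = np.arange(2.5, 100, 5.0)
        curve = EmpiricalTransitionCurve("a", "a", h, 5.0,
                                         np.full(len(h), 0.3),
                                         np.full(len(h), 10.0))
        m = fit_transition_model(curve)
        assert m.p0 == pytest.approx(0.3, abs=1e-6)
        assert m.sill == pytest.approx(0.3, abs=1e-6)
        assert "range_unidentifiable" in m.flags

    def test_first_bin_peak_excluded_from_fit(self):
        h = np.arange(2.5, 150, 5.0)
        true = ConditionalProbabilityModel("a", "a", "exponential",
                                           0.8, 0.2, 50.0)
        p = true(h)
        p[0] = 1.0  # within-segment peak, must be ignored
        curve = EmpiricalTransitionCurve("a", "a", h, 5.0, p,
                                         np.full(len(h), 50.0))
        m = fit_transition_model(curve, family="exponential")
        assert abs(m.p0 - 0.8) < 1e-6

    def test_too_few_bins_rejected(self):
        h = np.array([2.5, 7.5, 12.5])
        curve = EmpiricalTransitionCurve("a", "a", h, 5.0,
                                         np.array([0.5, 0.4, 0.3]),
                                         np.array([5.0, 5.0, 5.0]))
        with pytest.raises(ValueError):
            fit_transition_model(curve)  # first bin dropped -> only 2 left

    def test_model_evaluation_clipped(self):
        m = ConditionalProbabilityModel("a", "a", "spherical", 0.9, 0.1, 50.0)
        assert m(-5.0) == m(0.0)
        assert 0.0 <= m(1e9) <= 1.0
        with pytest.raises(ValueError):
            ConditionalProbabilityModel("a", "a", "spherical", 1.2, 0.1, 50.0)


def hand_models(classes, p_same=0.8, p_cross=0.1, a=40.0):
    models = {}
    for m in classes:
        for mp in classes:
            p0 = p_same if m == mp else p_cross
            sill = 1.0 / len(classes)
            models[(m, mp)] = ConditionalProbabilityModel(
                m, mp, "exponential", p0, sill, a)
    return models


class TestGknnClassify:
    def _neighbors(self, n_query=20, seed=30, k=5):
        train = random_sample_set(40, 3, 3, seed=seed)
        query = random_sample_set(n_query, 3, 3, seed=seed + 1)
        q = query.df.set_index("segment_id")[["row", "col"] +
                                             query.feature_names]
        return find_neighbors(train, q, k=k,
                              omega_scheme="inverse_distance"), train

    def test_sg_zero_reduces_to_plain_knn(self):
        nb, train = self._neighbors(n_query=25)
        plain = knn_classify(nb)
        blended = gknn_classify(nb, hand_models(train.classes),
                                GkNNConfig(sg=0.0, k=5))
        np.testing.assert_array_equal(plain.predicted, blended.predicted)
        np.testing.assert_allclose(plain.proba, blended.proba, atol=1e-12)

    def test_sg_one_single_neighbor_returns_model_probabilities(self):
        """K=1, Sg=1, M=2: p(m) = p_{m,c1}(h) / sum_m' p_{m',c1}(h)."""
        h = 12.0
        models = {
            ("a", "a"): ConditionalProbabilityModel("a", "a", "exponential",
                                                    0.8, 0.8, 1.0),
            ("b", "a"): ConditionalProbabilityModel("b", "a", "exponential",
                                                    0.2, 0.2, 1.0),
        }
        nb = NeighborSet(
            query_ids=np.array([1]),
            neighbor_index=np.array([[0]]),
            classes=np.array([["a"]]),
            distances=np.array([[0.5]]),
            lags=np.array([[h]]),
            weights=np.array([[1.0]]),
            train_classes=np.array(["a", "b"]),
        )
        res = gknn_classify(nb, models, GkNNConfig(sg=1.0, k=1),
                            class_names=["a", "b"])
        np.testing.assert_allclose(res.proba[0], [0.8, 0.2], atol=1e-12)

    def test_matches_hand_evaluated_blend(self):
        """3 training points, 2 classes, K=3, Sg=0.5: matches a manual
        spreadsheet-style evaluation of the blended score."""
        sg = 0.5
        models = hand_models(["a", "b"], p_same=0.9, p_cross=0.05, a=30.0)
        classes_k = np.array([["a", "b", "a"]])
        lags_k = np.array([[5.0, 11.0, 40.0]])
        weights_k = np.array([[2.0, 1.0, 0.5]])
        nb = NeighborSet(
            query_ids=np.array([7]),
            neighbor_index=np.array([[0, 1, 2]]),
            classes=classes_k,
            distances=np.array([[0.1, 0.2, 0.3]]),
            lags=lags_k,
            weights=weights_k,
            train_classes=np.array(["a", "b", "a"]),
        )
        res = gknn_classify(nb, models, GkNNConfig(sg=sg, k=3),
                            class_names=["a", "b"])
        scores = {}
        for m in ("a", "b"):
            total = 0.0
            for j in range(3):
                ck = classes_k[0, j]
                spatial = models[(m, ck)](lags_k[0, j])
                indicator = 1.0 if ck == m else 0.0
                total += weights_k[0, j] * (sg * spatial +
                                            (1 - sg) * indicator)
            scores[m] = total
        tot = scores["a"] + scores["b"]
        np.testing.assert_allclose(res.proba[0],
                                   [scores["a"] / tot, scores["b"] / tot],
                                   atol=1e-12)

    def test_probabilities_sum_to_one(self):
        nb, train = self._neighbors(n_query=30, seed=44)
        res = gknn_classify(nb, hand_models(train.classes),
                            GkNNConfig(sg=0.7, k=5))
        np.testing.assert_allclose(res.proba.sum(axis=1), 1.0, atol=1e-9)

    def test_probabilities_continuous_in_sg(self):
        nb, train = self._neighbors(n_query=10, seed=50)
        models = hand_models(train.classes)
        grid = np.linspace(0.0, 1.0, 101)
        prev = None
        for sg in grid:
            proba = gknn_classify(nb, models, GkNNConfig(sg=float(sg), k=5)
                                  ).proba
            if prev is not None:
                assert np.abs(proba - prev).max() < 0.05
            prev = proba

    def test_missing_model_rejected(self):
        nb, train = self._neighbors()
        models = hand_models(train.classes)
        del models[("class_0", "class_1")]
        with pytest.raises(KeyError):
            gknn_classify(nb, models, GkNNConfig(sg=0.5, k=5))


class TestFitAllTransitions:
    def test_sparse_pairs_fall_back_to_constant_model(self):
        # every pair within two lag bins: after the first-bin exclusion
        # no class row has the three usable bins a fit needs
        s = point_set([("a", 0, 0), ("a", 0, 8), ("b", 0, 4),
                       ("b", 0, 6), ("b", 0, 2)])
        models = fit_all_transitions(s, bin_width=5.0)
        assert set(models) == {(m, mp) for m in ("a", "b")
                               for mp in ("a", "b")}
        assert any("sparse" in m.flags for m in models.values())

    def test_lag_bins_cover_max_lag(self):
        edges = lag_bins(47.0, 5.0)
        assert edges[0] == 0.0
        assert edges[-1] >= 47.0
        assert np.allclose(np.diff(edges), 5.0)
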