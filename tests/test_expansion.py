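"""mu +/- t*sigma training expansion against exhaustive oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bamboomap.expansion import (
    ClassSpectralModel,
    candidate_matches,
    expand_training,
    fit_spectral_model,
    overlap_report,
    spectral_ranges,
)
from bamboomap.samples import EXPANDED, FIELD, SampleSet


def sample_set(records, bands=("b1", "b2")):
    rows = []
    for i, (label, feats) in enumerate(records):
        row = {"segment_id": i + 1, "class_label": label,
               "provenance": FIELD, "row": 0.0, "col": float(i)}
        row.update(dict(zip(bands, feats)))
        rows.append(row)
    return SampleSet(pd.DataFrame(rows))


def model_from(mu, sigma, t, bands=("b1", "b2")):
    classes = list(mu)
    return ClassSpectralModel(
        mu=pd.DataFrame({b: {c: mu[c][i] for c in classes}
                         for i, b in enumerate(bands)}),
        sigma=pd.DataFrame({b: {c: sigma[c][i] for c in classes}
                            for i, b in enumerate(bands)}),
        t=pd.Series(t),
    )


class TestFitSpectralModel:
    def test_single_sample_per_class_gives_zero_sigma(self):
        s = sample_set([("a", (10.0, 20.0)), ("b", (30.0, 40.0))])
        m = fit_spectral_model(s, ["b1", "b2"], {"a": 1.0, "b": 1.0})
        assert m.mu.loc["a", "b1"] == 10.0
        assert (m.sigma.to_numpy() == 0).all()

    def test_two_samples_population_std(self):
        s = sample_set([("a", (100.0, 0.0)), ("a", (102.0, 0.0)),
                        ("b", (0.0, 0.0))])
        m = fit_spectral_model(s, ["b1"], {"a": 1.0, "b": 1.0})
        assert m.mu.loc["a", "b1"] == pytest.approx(101.0)
        assert m.sigma.loc["a", "b1"] == pytest.approx(1.0)

    def test_matches_moment_oracle(self, rng):
        feats = rng.normal(size=(12, 2)) * 10 + 100
        s = sample_set([("a" if i < 7 else "b", tuple(feats[i]))
                        for i in range(12)])
        m = fit_spectral_model(s, ["b1", "b2"], {"a": 0.5, "b": 0.5})
        np.testing.assert_allclose(m.mu.loc["a"].to_numpy(),
                                   feats[:7].mean(axis=0))
        np.testing.assert_allclose(m.sigma.loc["a"].to_numpy(),
                                   feats[:7].std(axis=0, ddof=0))

    def test_missing_t_rejected(self):
        s = sample_set([("a", (1.0, 2.0))])
        with pytest.raises(KeyError):
            fit_spectral_model(s, ["b1"], {})


class TestSpectralRanges:
    def test_zero_t_degenerates_to_mu(self):
        m = model_from({"a": (5.0, 7.0)}, {"a": (2.0, 3.0)}, {"a": 0.0})
        r = spectral_ranges(m)
        assert r.loc["a", ("b1", "lo")] == r.loc["a", ("b1", "hi")] == 5.0

    def test_reproduces_published_bamboo_nir2_interval(self):
        """mu 138.15 with t*sigma 5.55 gives the published (132.6, 143.7)."""
        m = model_from({"bamboo": (138.15,)}, {"bamboo": (22.2,)},
                       {"bamboo": 0.25}, bands=("nir2",))
        r = spectral_ranges(m)
        assert r.loc["bamboo", ("nir2", "lo")] == pytest.approx(132.6)
        assert r.loc["bamboo", ("nir2", "hi")] == pytest.approx(143.7)

    @given(mu=st.floats(-1e3, 1e3), sigma=st.floats(0, 1e2),
           t=st.floats(0, 10))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_endpoints_match_arithmetic(self, mu, sigma, t):
        m = model_from({"a": (mu, 0.0)}, {"a": (sigma, 0.0)}, {"a": t})
        r = spectral_ranges(m)
        assert r.loc["a", ("b1", "lo")] == pytest.approx(mu - t * sigma)
        assert r.loc["a", ("b1", "hi")] == pytest.approx(mu + t * sigma)
        assert r.loc["a", ("b1", "hi")] - r.loc["a", ("b1", "lo")] == \
            pytest.approx(2 * t * sigma, abs=1e-6)


class TestOverlapReport:
    def test_disjoint_intervals_zero_overlap(self):
        m = model_from({"a": (0.0, 0.0), "b": (10.0, 10.0)},
                       {"a": (1.0, 1.0), "b": (1.0, 1.0)},
                       {"a": 1.0, "b": 1.0})
        assert (overlap_report(m).to_numpy() == 0).all()

    def test_nested_intervals_overlap_equals_inner_width(self):
        m = model_from({"a": (5.0, 5.0), "b": (5.0, 5.0)},
                       {"a": (10.0, 10.0), "b": (1.0, 1.0)},
                       {"a": 1.0, "b": 1.0})
        assert (overlap_report(m).to_numpy() == 2.0).all()

    def test_matches_interval_intersection_oracle(self, rng):
        mu = {c: tuple(rng.uniform(0, 100, 2)) for c in "abc"}
        sig = {c: tuple(rng.uniform(0, 20, 2)) for c in "abc"}
        t = {c: float(rng.uniform(0, 2)) for c in "abc"}
        m = model_from(mu, sig, t)
        rep = overlap_report(m)
        for (ca, cb) in rep.index:
            for bi, band in enumerate(("b1", "b2")):
                lo_a, hi_a = (mu[ca][bi] - t[ca] * sig[ca][bi],
                              mu[ca][bi] + t[ca] * sig[ca][bi])
                lo_b, hi_b = (mu[cb][bi] - t[cb] * sig[cb][bi],
                              mu[cb][bi] + t[cb] * sig[cb][bi])
                expected = max(0.0, min(hi_a, hi_b) - max(lo_a, lo_b))
                assert rep.loc[(ca, cb), band] == pytest.approx(expected)


def toy_table(rng, n=20, bands=("b1", "b2")):
    df = pd.DataFrame(rng.uniform(0, 100, size=(n, len(bands))),
                      columns=list(bands),
                      index=pd.RangeIndex(1, n + 1, name="segment_id"))
    df.insert(0, "row", rng.uniform(0, 50, n))
    df.insert(1, "col", rng.uniform(0, 50, n))
    return df


class TestExpandTraining:
    def field(self, table, bands=("b1", "b2")):
        df = table.iloc[:2].reset_index()
        df.insert(1, "class_label", ["a", "b"])
        df.insert(2, "provenance", FIELD)
        return SampleSet(df)

    def test_matches_interval_membership_oracle(self, rng):
        table = toy_table(rng)
        m = model_from({"a": (30.0, 40.0), "b": (70.0, 60.0)},
                       {"a": (20.0, 25.0), "b": (15.0, 30.0)},
                       {"a": 1.0, "b": 0.8})
        field = self.field(table)
        out = expand_training(table, m, field)
        ranges = spectral_ranges(m)
        got = dict(zip(out.df["segment_id"], out.df["class_label"]))
        field_ids = set(field.df["segment_id"])
        for sid in table.index:
            inside = []
            for c in ("a", "b"):
                ok = all(ranges.loc[c, (b, "lo")] <= table.loc[sid, b]
                         <= ranges.loc[c, (b, "hi")] for b in ("b1", "b2"))
                if ok:
                    inside.append(c)
            if sid in field_ids:
                assert sid in got
            elif len(inside) == 1:
                assert got.get(sid) == inside[0]
            else:
                assert sid not in got

    def test_segment_outside_all_intervals_unlabelled(self, rng):
        table = toy_table(rng, n=5)
        table.loc[:, ["b1", "b2"]] = 1000.0
        m = model_from({"a": (0.0, 0.0), "b": (50.0, 50.0)},
                       {"a": (1.0, 1.0), "b": (1.0, 1.0)},
                       {"a": 1.0, "b": 1.0})
        field = self.field(table)
        out = expand_training(table, m, field)
        assert set(out.df["segment_id"]) == set(field.df["segment_id"])

    def test_field_samples_survive_unchanged(self, rng):
        table = toy_table(rng)
        m = model_from({"a": (50.0, 50.0), "b": (50.0, 50.0)},
                       {"a": (50.0, 50.0), "b": (50.0, 50.0)},
                       {"a": 2.0, "b": 2.0})
        field = self.field(table)
        out = expand_training(table, m, field)
        merged = out.df.set_index("segment_id")
        for _, rec in field.df.iterrows():
            assert merged.loc[rec["segment_id"], "class_label"] == \
                rec["class_label"]
            assert merged.loc[rec["segment_id"], "provenance"] == FIELD

    def test_infinite_t_makes_everything_ambiguous(self, rng):
        table = toy_table(rng)
        m = model_from({"a": (30.0, 40.0), "b": (70.0, 60.0)},
                       {"a": (20.0, 25.0), "b": (15.0, 30.0)},
                       {"a": np.inf, "b": np.inf})
        field = self.field(table)
        out = expand_training(table, m, field)
        assert len(out) == len(field)

    def test_candidate_sets_monotone_in_t_before_ambiguity_drop(self, rng):
        table = toy_table(rng)
        base = dict(mu={"a": (30.0, 40.0), "b": (70.0, 60.0)},
                    sigma={"a": (20.0, 25.0), "b": (15.0, 30.0)})
        small = model_from(**base, t={"a": 0.5, "b": 0.5})
        large = model_from(**base, t={"a": 1.5, "b": 1.5})
        m_small = candidate_matches(table, small)
        m_large = candidate_matches(table, large)
        assert (m_large.to_numpy() >= m_small.to_numpy()).all()

    def test_nearest_assignment_mode_labels_ambiguous_segments(self, rng):
        table = toy_table(rng, n=6)
        table.loc[:, ["b1", "b2"]] = 50.0
        m = model_from({"a": (49.0, 50.0), "b": (52.0, 50.0)},
                       {"a": (10.0, 10.0), "b": (10.0, 10.0)},
                       {"a": 1.0, "b": 1.0})
        field = self.field(table)
        out = expand_training(table, m, field, ambiguous="nearest")
        expanded = out.df[out.df["provenance"] == EXPANDED]
        assert (expanded["class_label"] == "a").all()  # closer centroid
        assert len(expanded) == 4
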