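"""FTOE, interval medians, baseline normalization, deltas, block averages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spafnirs import (
    attach_ftoe,
    block_average,
    compute_deltas,
    compute_ftoe,
    interval_medians,
    normalize_to_interval2,
    preprocess_session,
)
from spafnirs.derived import SIGNALS
from spafnirs.preprocess import PreprocessedSession


def make_pre(sto2_ac=None, sto2_pfc=None, spo2=None, pr=None, n=825, sid="p"):
    """PreprocessedSession straight from arrays (skips filtering)."""
    full = lambda v: np.full(n, float(v))
    sto2_ac = full(70) if sto2_ac is None else np.asarray(sto2_ac, float)
    sto2_pfc = sto2_ac.copy() if sto2_pfc is None else np.asarray(sto2_pfc, float)
    spo2 = full(97) if spo2 is None else np.asarray(spo2, float)
    pr = full(150) if pr is None else np.asarray(pr, float)
    return PreprocessedSession(
        subject_id=sid, fs=0.25, time=np.arange(n) * 4.0,
        sto2_ac=sto2_ac, sto2_pfc=sto2_pfc, spo2=spo2, pr=pr,
        artifact_mask=np.zeros(n, dtype=bool),
    )


def steps(values_by_interval, seg):
    """Piecewise-constant series from {interval: value}."""
    x = np.zeros(825)
    for k, idx in seg.items():
        x[idx] = values_by_interval.get(k, values_by_interval.get("default", 70.0))
    return x


class TestFtoe:
    @pytest.mark.parametrize(
        "spo2,sto2,expected",
        [(96.0, 72.0, 0.25), (88.0, 88.0, 0.0), (np.nan, 70.0, np.nan),
         (0.0, 70.0, np.nan), (97.0, np.nan, np.nan)],
    )
    def test_pointwise_cases(self, spo2, sto2, expected):
        out = compute_ftoe(np.array([spo2]), np.array([sto2]))
        if np.isnan(expected):
            assert np.isnan(out[0])
        else:
            assert out[0] == pytest.approx(expected)

    def test_matches_elementwise_oracle_on_grid(self):
        spo2, sto2 = np.meshgrid(np.arange(80.0, 101.0), np.arange(40.0, 101.0, 5))
        out = compute_ftoe(spo2.ravel(), sto2.ravel())
        oracle = np.array([(a - b) / a for a, b in zip(spo2.ravel(), sto2.ravel())])
        np.testing.assert_array_equal(out, oracle)

    def test_ftoe_decreasing_in_sto2_at_fixed_spo2(self):
        sto2 = np.linspace(40, 90, 50)
        f = compute_ftoe(np.full(50, 97.0), sto2)
        assert np.all(np.diff(f) < 0)


class TestIntervalMedians:
    def test_piecewise_constant_recovered(self, protocol):
        from spafnirs import segment

        seg = segment(protocol, 0.25, 825)
        pre = make_pre(sto2_ac=steps({2: 70.0, 3: 73.2, "default": 70.0}, seg))
        summ = interval_medians(pre, protocol)
        assert summ.median("sto2_ac", 2) == pytest.approx(70.0)
        assert summ.median("sto2_ac", 3) == pytest.approx(73.2)

    def test_fully_masked_interval_missing(self, protocol):
        from spafnirs import segment

        seg = segment(protocol, 0.25, 825)
        x = np.full(825, 70.0)
        x[seg[3]] = np.nan
        summ = interval_medians(make_pre(sto2_ac=x), protocol)
        assert np.isnan(summ.median("sto2_ac", 3))
        assert summ.valid_fraction.loc["sto2_ac", 3] == 0.0

    def test_matches_sort_based_median_oracle(self, protocol, rng):
        from spafnirs import segment

        seg = segment(protocol, 0.25, 825)
        x = rng.uniform(50, 90, 825)
        summ = interval_medians(make_pre(sto2_ac=x), protocol)
        for k, idx in seg.items():
            vals = np.sort(x[idx])
            n = len(vals)
            oracle = (
                vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
            )
            assert summ.median("sto2_ac", k) == pytest.approx(oracle)


class TestNormalization:
    def test_constant_becomes_zero(self, protocol):
        norm = normalize_to_interval2(make_pre(), protocol=protocol)
        np.testing.assert_allclose(norm["sto2_ac"], 0.0, atol=1e-12)

    @given(shift=st.floats(-20, 20))
    @settings(max_examples=20, deadline=None)
    def test_translation_equivariance(self, shift):
        rng = np.random.default_rng(3)
        x = np.clip(rng.normal(70, 3, 825), 0, 100)
        a = normalize_to_interval2(make_pre(sto2_ac=x))["sto2_ac"]
        b = normalize_to_interval2(make_pre(sto2_ac=np.clip(x + shift, None, None)))[
            "sto2_ac"
        ]
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_interval2_median_zero_after_normalization(self, protocol, rng):
        from spafnirs import segment

        seg = segment(protocol, 0.25, 825)
        for _ in range(5):
            x = rng.uniform(40, 90, 825)
            norm = normalize_to_interval2(make_pre(sto2_ac=x), protocol=protocol)
            assert np.nanmedian(norm["sto2_ac"][seg[2]]) == pytest.approx(0.0, abs=1e-12)

    def test_divide_mode(self, protocol):
        norm = normalize_to_interval2(make_pre(), protocol=protocol, mode="divide")
        np.testing.assert_allclose(norm["sto2_ac"], 1.0, atol=1e-12)


class TestDeltas:
    @pytest.mark.parametrize("v3,expected", [(73.2, 3.2), (68.8, -1.2), (70.0, 0.0)])
    def test_interval_median_difference(self, protocol, v3, expected):
        from spafnirs import segment

        seg = segment(protocol, 0.25, 825)
        pre = make_pre(sto2_ac=steps({3: v3, "default": 70.0}, seg))
        d = compute_deltas(interval_medians(pre, protocol))
        assert d["sto2_ac"] == pytest.approx(expected)

    def test_missing_median_gives_missing_delta(self, protocol):
        from spafnirs import segment

        seg = segment(protocol, 0.25, 825)
        x = np.full(825, 70.0)
        x[seg[3]] = np.nan
        d = compute_deltas(interval_medians(make_pre(sto2_ac=x), protocol))
        assert np.isnan(d["sto2_ac"])

    def test_sign_anticorrelation_with_ftoe(self, protocol):
        """A pure StO2 rise at constant SpO2 must lower FTOE."""
        from spafnirs import segment

        seg = segment(protocol, 0.25, 825)
        pre = make_pre(sto2_ac=steps({3: 73.2, "default": 70.0}, seg))
        d = compute_deltas(interval_medians(pre, protocol))
        assert d["sto2_ac"] > 0
        assert d["spo2"] == pytest.approx(0.0)
        assert d["ftoe_ac"] < 0


class TestBlockAverage:
    def _normalized(self, arrays):
        return {
            f"s{i}": {sig: np.asarray(a, float) for sig in SIGNALS}
            for i, a in enumerate(arrays)
        }

    def test_identical_sessions_collapse(self):
        x = np.sin(np.linspace(0, 3, 825))
        norm = self._normalized([x, x])
        out = block_average(norm, {"s0": 1, "s1": 1})
        df = out.curves[(1, "sto2_ac")]
        np.testing.assert_allclose(df["median"], x, atol=1e-12)
        np.testing.assert_allclose(df["p25"], df["p75"], atol=1e-12)

    def test_percentile_order(self, rng):
        norm = self._normalized([rng.normal(0, 1, 825) for _ in range(7)])
        out = block_average(norm, {f"s{i}": 1 for i in range(7)})
        df = out.curves[(1, "sto2_ac")]
        assert (df["p25"] <= df["median"] + 1e-12).all()
        assert (df["median"] <= df["p75"] + 1e-12).all()

    def test_three_constants_match_percentile_oracle(self):
        norm = self._normalized([np.full(825, v) for v in (1.0, 2.0, 3.0)])
        out = block_average(norm, {"s0": 1, "s1": 1, "s2": 1})
        df = out.curves[(1, "sto2_ac")]
        np.testing.assert_allclose(df["median"], 2.0)
        # linear interpolation between order statistics
        np.testing.assert_allclose(df["p25"], np.percentile([1, 2, 3], 25))
        np.testing.assert_allclose(df["p75"], np.percentile([1, 2, 3], 75))

    def test_empty_subgroup_warns(self):
        norm = self._normalized([np.zeros(10)])
        with pytest.warns(UserWarning, match="empty"):
            out = block_average(norm, {"s0": 1})
        assert out.n_subjects[2] == 0


class TestEndToEndDerived:
    def test_block_average_flat_over_baseline_interval(self, protocol, small_cohort):
        from spafnirs import assign_subgroups, segment

        sessions, metas, truth = small_cohort
        pres = [preprocess_session(s) for s in sessions[:6]]
        for p in pres:
            attach_ftoe(p)
        seg = segment(protocol, 0.25, len(pres[0].time))
        norm = {p.subject_id: normalize_to_interval2(p) for p in pres}
        assigns, _ = assign_subgroups(pres)
        out = block_average(norm, {a.subject_id: a.subgroup for a in assigns if a.subgroup})
        for (g, sig), df in out.curves.items():
            med2 = np.nanmedian(df["median"].to_numpy()[seg[2]])
            assert abs(med2) < 0.15  # curves referenced to first touch
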