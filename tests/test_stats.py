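"""Agreement and group-comparison statistics checks."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import respiradar as rr
from respiradar.pipeline import InstantRateSeries
from respiradar.stats import (
    PairedRates,
    dunn_posthoc,
    significance_stars,
    split_by_schedule,
)


def make_series(t0, t1, bpm_fn, grid_rate=10.0, kind="Q"):
    """Minimal InstantRateSeries for stats-level tests."""
    grid = np.arange(t0, t1 + 1e-9, 1.0 / grid_rate)
    bpm = np.asarray([bpm_fn(t) for t in grid], dtype=float)
    freq = bpm / 60.0
    q = np.ones_like(bpm)
    return InstantRateSeries(
        event_times=grid,
        freq=freq,
        quality=q,
        grid_times=grid,
        freq_interp=freq,
        quality_interp=q,
        bpm=bpm,
        kind=kind,
    )


def make_pairs(radar, reference):
    radar = np.asarray(radar, dtype=float)
    reference = np.asarray(reference, dtype=float)
    return PairedRates(
        grid_times=np.arange(len(radar), dtype=float),
        radar_bpm=radar,
        reference_bpm=reference,
    )


class TestPairSeries:
    def test_identical_series_give_zero_differences(self):
        s = make_series(0, 60, lambda t: 60 + 0.1 * t)
        pairs = rr.pair_series(s, s, grid_rate=1.0)
        assert np.allclose(pairs.radar_bpm, pairs.reference_bpm)

    def test_overlap_arithmetic(self):
        a = make_series(0, 100, lambda t: 60.0)
        b = make_series(50, 150, lambda t: 60.0)
        pairs = rr.pair_series(a, b, grid_rate=1.0)
        assert len(pairs) == 51
        assert pairs.grid_times[0] == 50.0 and pairs.grid_times[-1] == 100.0

    def test_no_overlap_rejected(self):
        a = make_series(0, 10, lambda t: 60.0)
        b = make_series(20, 30, lambda t: 60.0)
        with pytest.raises(ValueError, match="no overlap"):
            rr.pair_series(a, b)

    def test_simulated_radar_vs_reference_pairing(self, noisy_config):
        sc = rr.RespirationScenario(segments=((30.0, 80.0), (30.0, 60.0)), seed=9)
        iq, ref = rr.simulate_recording(sc, noisy_config, seed=9)
        radar = rr.analyze_recording(iq)
        reference = rr.analyze_channel(
            rr.ChannelSignal(times=ref.times, values=ref.displacement, kind="R")
        )
        pairs = rr.pair_series(radar, reference, grid_rate=1.0)
        assert np.mean(np.abs(pairs.radar_bpm - pairs.reference_bpm)) < 1.0


class TestBlandAltman:
    def test_identical_series(self):
        mean_d, lo, hi = rr.bland_altman(make_pairs([60, 62, 64], [60, 62, 64]))
        assert (mean_d, lo, hi) == (0.0, 0.0, 0.0)

    def test_hand_computed_limits(self):
        # differences [-1, 1]: mean 0, sd (n-1) = sqrt(2), LoA = +/-1.96 sqrt(2)
        mean_d, lo, hi = rr.bland_altman(make_pairs([61, 59], [60, 60]))
        assert mean_d == pytest.approx(0.0)
        assert hi == pytest.approx(1.96 * np.sqrt(2), abs=1e-9)
        assert lo == pytest.approx(-1.96 * np.sqrt(2), abs=1e-9)

    @given(st.integers(0, 10_000))
    def test_antisymmetric_under_swap(self, seed):
        rng = np.random.default_rng(seed)
        pairs = make_pairs(rng.normal(70, 5, 20), rng.normal(70, 5, 20))
        m1, lo1, hi1 = rr.bland_altman(pairs, sign="reference_minus_radar")
        m2, lo2, hi2 = rr.bland_altman(pairs, sign="radar_minus_reference")
        assert m2 == pytest.approx(-m1) and lo2 == pytest.approx(-hi1) and hi2 == pytest.approx(-lo1)


class TestErrorMetrics:
    def test_identical_series(self):
        rmse, mape, r = rr.error_metrics(make_pairs([60, 62, 64], [60, 62, 64]))
        assert rmse == 0.0 and mape == 0.0 and r == pytest.approx(1.0)

    def test_hand_computed_values(self):
        rmse, mape, _ = rr.error_metrics(make_pairs([50, 60], [55, 66]))
        assert rmse == pytest.approx(np.sqrt((25 + 36) / 2))
        assert mape == pytest.approx(10.0)

    def test_rmse_at_least_mean_difference(self):
        rng = np.random.default_rng(1)
        pairs = make_pairs(rng.normal(70, 5, 50), rng.normal(72, 5, 50))
        mean_d, _, _ = rr.bland_altman(pairs)
        rmse, _, _ = rr.error_metrics(pairs)
        assert rmse >= abs(mean_d)

    @given(st.floats(0.1, 10.0), st.floats(-20.0, 20.0))
    def test_pearson_invariant_to_affine_rescaling(self, scale, shift):
        rng = np.random.default_rng(0)
        radar = rng.normal(70, 5, 30)
        reference = radar + rng.normal(0, 2, 30)
        _, _, r1 = rr.error_metrics(make_pairs(radar, reference))
        _, _, r2 = rr.error_metrics(make_pairs(radar * scale + shift, reference))
        assert r2 == pytest.approx(r1, abs=1e-9)

    def test_zero_denominator_names_timestamps(self):
        pairs = make_pairs([60, 0, 62], [60, 1, 62])
        with pytest.raises(ValueError, match="t = 1.000"):
            rr.error_metrics(pairs, mape_denominator="radar")


class TestKruskalPosthoc:
    def test_identical_groups_not_significant(self):
        g = np.array([60.0, 70.0, 80.0, 90.0])
        res = rr.kruskal_posthoc({"a": g, "b": g.copy()})
        assert res.kw_p > 0.9
        assert res.posthoc.loc["a", "b"] > 0.5

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(42)
        res = rr.kruskal_posthoc(
            {"deep": rng.normal(55, 2, 100), "light": rng.normal(90, 2, 100)}
        )
        assert res.kw_p < 1e-3
        assert res.posthoc.loc["deep", "light"] < 1e-3

    def test_posthoc_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        groups = {k: rng.normal(70 + i, 3, 30) for i, k in enumerate("abcd")}
        mat = dunn_posthoc(groups)
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 1.0)
        assert ((mat.values >= 0) & (mat.values <= 1)).all()

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            rr.kruskal_posthoc({"a": np.array([1.0, 2.0]), "b": np.array([1.0])})

    def test_stars_thresholds(self):
        assert significance_stars(0.5) == "ns"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"


class TestSplitBySchedule:
    def test_samples_assigned_to_levels(self):
        s = make_series(0, 100, lambda t: 60.0 if t < 50 else 90.0)
        groups = split_by_schedule(s, [(50.0, "lo"), (50.0, "hi")], sample_rate=1.0)
        assert np.median(groups["lo"]) == pytest.approx(60.0, abs=1.0)
        assert np.median(groups["hi"]) == pytest.approx(90.0, abs=1.0)

    def test_repeated_labels_pooled(self):
        s = make_series(0, 30, lambda t: 60.0)
        groups = split_by_schedule(s, [(10.0, "a"), (10.0, "b"), (10.0, "a")], sample_rate=1.0)
        assert len(groups["a"]) > len(groups["b"])
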