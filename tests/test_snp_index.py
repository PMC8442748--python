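import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsamap.mendel import CrossModel
from bsamap.snp_index import (
    OrientationError,
    extract_regions,
    fit_track,
    percentile_threshold,
    snp_index,
    snp_index_table,
    theoretical_delta,
    top_peak_chrom,
)
from _oracles import brute_force_runs


def table_from_depths(rows):
    """Rows of (pos, (s_ref, s_alt), (f_ref, f_alt)); ALT is the sterile allele."""
    return pd.DataFrame(
        [
            {
                "chrom": "c1",
                "pos": pos,
                "gt_parent_sterile": "1/1",
                "gt_parent_fertile": "0/0",
                "ad_ref_bulk_sterile": sr,
                "ad_alt_bulk_sterile": sa,
                "ad_ref_bulk_fertile": fr,
                "ad_alt_bulk_fertile": fa,
            }
            for pos, (sr, sa), (fr, fa) in rows
        ]
    )


class TestSnpIndex:
    def test_fixed_sterile_pool(self):
        assert snp_index(0, 34) == 1.0

    def test_fertile_pool_third(self):
        assert snp_index(20, 10) == pytest.approx(1 / 3)

    def test_zero_depth_is_missing(self):
        assert math.isnan(snp_index(0, 0))

    def test_orientation_flips_when_ref_is_sterile_allele(self):
        assert snp_index(10, 30, alt_is_sterile_allele=False) == pytest.approx(0.25)

    def test_equal_indices_give_zero_delta(self):
        t = snp_index_table(table_from_depths([(100, (10, 30), (5, 15))]))
        assert t["delta"].iloc[0] == pytest.approx(0.0)

    def test_identical_parents_raise_orientation_error(self):
        t = table_from_depths([(100, (10, 30), (5, 15))])
        t["gt_parent_fertile"] = "1/1"
        with pytest.raises(OrientationError):
            snp_index_table(t)

    def test_bounds_and_antisymmetry(self):
        rng = np.random.default_rng(3)
        rows = [
            (i * 10, tuple(rng.integers(0, 40, 2)), tuple(rng.integers(1, 40, 2)))
            for i in range(1, 60)
        ]
        t = snp_index_table(table_from_depths(rows))
        ok = t["delta"].notna()
        assert t.loc[ok, "index_sterile"].between(0, 1).all()
        assert t.loc[ok, "delta"].between(-1, 1).all()
        swapped = table_from_depths(
            [(pos, f_depths, s_depths) for pos, s_depths, f_depths in rows]
        )
        t2 = snp_index_table(swapped)
        np.testing.assert_allclose(t2["delta"], -t["delta"])


class TestTheoreticalDelta:
    def test_f2_recessive_is_two_thirds(self):
        assert round(theoretical_delta(CrossModel()), 3) == 0.667

    def test_unsupported_design_propagates(self):
        with pytest.raises(NotImplementedError):
            theoretical_delta(CrossModel(dominance="dominant"))


class TestFitTrack:
    def test_constant_values_fit_to_constant(self):
        pos = np.arange(1, 51) * 1000
        track = fit_track(pos, np.full(50, 0.42), window_bp=10_000, step_bp=2_000, min_sites=1)
        ok = ~np.isnan(track.fitted)
        assert ok.any()
        np.testing.assert_allclose(track.fitted[ok], 0.42)

    def test_single_site_window(self):
        track = fit_track([500], [0.7], window_bp=1000, step_bp=100, min_sites=1)
        assert track.fitted[0] == pytest.approx(0.7)

    def test_window_mean_of_five_sites(self):
        track = fit_track(
            [100, 110, 120, 130, 140], [0.1, 0.2, 0.3, 0.4, 0.5],
            window_bp=1000, step_bp=1000, min_sites=5,
        )
        assert track.fitted[0] == pytest.approx(0.3)

    def test_min_sites_flags_missing(self):
        track = fit_track([100, 50_000], [0.1, 0.9], window_bp=1000, step_bp=1000, min_sites=2)
        assert np.isnan(track.fitted).all()

    def test_invalid_window_raises(self):
        with pytest.raises(ValueError):
            fit_track([1], [0.1], window_bp=0)
        with pytest.raises(ValueError):
            fit_track([1], [0.1], step_bp=-5)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40), st.integers(0, 10**6))
    def test_fitted_within_hull_of_raw(self, values, seed):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(np.arange(1, 10**6), size=len(values), replace=False))
        track = fit_track(pos, np.array(values), window_bp=100_000, step_bp=20_000, min_sites=1)
        ok = ~np.isnan(track.fitted)
        if ok.any():
            assert track.fitted[ok].min() >= min(values) - 1e-12
            assert track.fitted[ok].max() <= max(values) + 1e-12


class TestPercentileThreshold:
    def test_constant_values(self):
        assert percentile_threshold(np.full(10, 0.3), 99) == pytest.approx(0.3)

    def test_median_of_eleven(self):
        assert percentile_threshold(np.linspace(0, 1, 11), 50) == pytest.approx(0.5)

    def test_monotone_in_q(self):
        rng = np.random.default_rng(1)
        values = rng.random(200)
        qs = [50, 75, 90, 95, 99]
        thresholds = [percentile_threshold(values, q) for q in qs]
        assert thresholds == sorted(thresholds)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            percentile_threshold(np.array([np.nan]))


def synthetic_track(fitted, step=100, window=100):
    """A track whose windows are disjoint, one site per window center."""
    centers = np.arange(1, len(fitted) + 1) * step
    return fit_track(centers, np.array(fitted), chrom="cX",
                     window_bp=window, step_bp=step, min_sites=1)


class TestExtractRegions:
    def test_single_run_with_peak(self):
        track = synthetic_track([0.1, 0.7, 0.8, 0.2])
        regions = extract_regions(track, 0.56)
        assert len(regions) == 1
        r = regions[0]
        assert r.peak_value == pytest.approx(0.8)
        assert r.start == 200 and r.end == 300
        assert r.n_sites == 2

    def test_nothing_above_threshold(self):
        track = synthetic_track([0.1, 0.2])
        assert extract_regions(track, 0.56) == []

    def test_threshold_is_strict(self):
        track = synthetic_track([0.56, 0.56])
        assert extract_regions(track, 0.56) == []

    def test_matches_exhaustive_interval_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = rng.integers(1, 51)
            fitted = rng.random(n)
            fitted[rng.random(n) < 0.2] = np.nan  # missing windows break runs
            track = synthetic_track(list(fitted))
            threshold = float(rng.random())
            above = np.zeros(n, dtype=bool)
            ok = ~np.isnan(fitted)
            above[ok] = fitted[ok] > threshold
            expected = brute_force_runs(above)
            regions = extract_regions(track, threshold)
            got = [(r.start // 100 - 1, r.end // 100 - 1) for r in regions]
            assert got == expected


class TestTopPeak:
    def test_top_peak_chromosome(self):
        tracks = {
            "a": synthetic_track([0.2, 0.4]),
            "b": synthetic_track([0.9, 0.1]),
        }
        tracks["b"].chrom = "b"
        assert top_peak_chrom(tracks) == "b"
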