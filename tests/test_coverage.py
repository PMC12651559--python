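import numpy as np
import pandas as pd
import pytest

from replireset.coverage import (
    bin_coverage,
    detect_degradation_plateau,
    normalize_track,
    orientation_index,
    origin_terminus_ratio,
    read_bedgraph,
    replicore_asymmetry,
    smooth_and_trim,
    track_from_binned,
    write_bedgraph,
)
from replireset.genome import GenomeMap


def brute_force_bins(intervals, length, bin_width):
    """Per-base accumulation oracle for length-weighted binning."""
    per_base = np.zeros(length)
    for _, row in intervals.iterrows():
        per_base[int(row["start"]) : int(row["end"])] += row["value"]
    n = int(np.ceil(length / bin_width))
    return np.array(
        [per_base[i * bin_width : (i + 1) * bin_width].sum() for i in range(n)]
    )


class TestBinning:
    def test_uniform_coverage_conserved(self, toy_genome):
        iv = pd.DataFrame({"start": [0], "end": [10_000], "value": [1.0]})
        track = bin_coverage(iv, toy_genome, bin_width=500)
        assert np.all(track.values == 500.0)
        assert track.values.sum() == pytest.approx(10_000.0)

    def test_matches_per_base_oracle(self, toy_genome, rng):
        starts = rng.integers(0, 9_500, 20)
        lengths = rng.integers(1, 900, 20)
        iv = pd.DataFrame(
            {
                "start": starts,
                "end": np.minimum(starts + lengths, 10_000),
                "value": rng.uniform(0.5, 3.0, 20),
            }
        )
        track = bin_coverage(iv, toy_genome, bin_width=500)
        np.testing.assert_allclose(
            track.values, brute_force_bins(iv, 10_000, 500), rtol=1e-9
        )

    def test_partial_overlap_is_length_weighted(self, toy_genome):
        iv = pd.DataFrame({"start": [450], "end": [1_050], "value": [2.0]})
        track = bin_coverage(iv, toy_genome, bin_width=500)
        np.testing.assert_allclose(track.values[:3], [100.0, 1_000.0, 100.0])

    def test_masked_bins_zeroed_and_flagged(self):
        g = GenomeMap(length=10_000, oric=6_000, terminus_window=(800, 1_200),
                      masked_intervals=[(2_000, 3_000)])
        iv = pd.DataFrame({"start": [0], "end": [10_000], "value": [1.0]})
        track = bin_coverage(iv, g, bin_width=500)
        assert np.all(track.values[4:6] == 0.0)
        assert np.all(track.mask[4:6])

    def test_short_last_bin_warns(self):
        g = GenomeMap(length=10_100, oric=6_000, terminus_window=(800, 1_200))
        iv = pd.DataFrame({"start": [0], "end": [10_100], "value": [1.0]})
        with pytest.warns(UserWarning, match="last bin"):
            track = bin_coverage(iv, g, bin_width=500)
        assert track.values[-1] == pytest.approx(100.0)

    def test_bedgraph_round_trip(self, toy_genome, tmp_path, rng):
        vals = rng.uniform(1, 5, 20)
        track = track_from_binned(toy_genome, vals, bin_width=500)
        path = tmp_path / "t.bedgraph"
        write_bedgraph(track, path)
        df = read_bedgraph(path)
        np.testing.assert_allclose(df["value"], vals, rtol=1e-5)
        assert df["start"].iloc[0] == 0 and df["end"].iloc[-1] == 10_000


class TestNormalization:
    def test_cpm_total_is_one_million(self, toy_genome, rng):
        track = track_from_binned(toy_genome, rng.uniform(1, 9, 20), 500)
        out = normalize_track(track, "cpm")
        assert out.values.sum() == pytest.approx(1e6)

    def test_cpm_idempotent(self, toy_genome, rng):
        track = track_from_binned(toy_genome, rng.uniform(1, 9, 20), 500)
        once = normalize_track(track, "cpm")
        twice = normalize_track(once, "cpm")
        np.testing.assert_allclose(twice.values, once.values)

    def test_uniform_terminus_corrected_is_one(self, toy_genome):
        track = track_from_binned(toy_genome, np.full(20, 7.0), 500)
        out = normalize_track(track, "cpm+terminus")
        np.testing.assert_allclose(out.values, 1.0)

    def test_zero_signal_rejected(self, toy_genome):
        track = track_from_binned(toy_genome, np.zeros(20), 500)
        with pytest.raises(ValueError):
            normalize_track(track, "cpm")


class TestSmoothAndTrim:
    def test_constant_track_unchanged(self, toy_genome):
        track = track_from_binned(toy_genome, np.full(100, 5.0), 100)
        out = smooth_and_trim(track, span=0.05)
        np.testing.assert_allclose(out.values, 5.0)

    def test_spike_removed(self, toy_genome):
        vals = np.full(100, 5.0)
        vals[40] = 500.0
        track = track_from_binned(toy_genome, vals, 100)
        out = smooth_and_trim(track, span=0.05, trim_k=5.0)
        np.testing.assert_allclose(out.values, 5.0, rtol=1e-6)

    def test_replicates_averaged(self, toy_genome):
        t1 = track_from_binned(toy_genome, np.full(100, 4.0), 100)
        t2 = track_from_binned(toy_genome, np.full(100, 6.0), 100)
        out = smooth_and_trim([t1, t2], span=0.05)
        np.testing.assert_allclose(out.values, 5.0)

    def test_sine_track_matches_rolling_regression_oracle(self, toy_genome):
        n = 100
        x = np.arange(n)
        vals = 10 + 3 * np.sin(2 * np.pi * x / n)
        track = track_from_binned(toy_genome, vals, 100)
        span = 0.1
        out = smooth_and_trim(track, span=span)
        # independent oracle: explicit per-bin tricube-weighted linear fit
        half = max(2, int(round(span * n / 2)))
        oracle = np.empty(n)
        for i in range(n):
            offs = np.arange(-half, half + 1)
            w = (1 - (np.abs(offs) / (half + 1)) ** 3) ** 3
            ys = vals[(i + offs) % n]
            W = np.diag(w)
            X = np.column_stack([np.ones_like(offs), offs]).astype(float)
            beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ ys)
            oracle[i] = beta[0]
        np.testing.assert_allclose(out.values, oracle, rtol=0.01)

    def test_all_trimmed_rejected(self, toy_genome):
        track = track_from_binned(toy_genome, np.full(20, 1.0), 500)
        track.mask[:] = True
        with pytest.raises(ValueError):
            smooth_and_trim(track, span=0.1)


class TestAsymmetry:
    def test_symmetric_track_unity(self, toy_genome):
        track = track_from_binned(toy_genome, np.full(100, 3.0), 100)
        assert replicore_asymmetry(track, 4_500) == pytest.approx(1.0)

    def test_reciprocal_identity(self, toy_genome, rng):
        vals = rng.uniform(1, 4, 100)
        track = track_from_binned(toy_genome, vals, 100)
        locus = 4_550
        mirror = toy_genome.mirror_locus(locus)
        a = replicore_asymmetry(track, locus)
        b = replicore_asymmetry(track, mirror)
        assert a * b == pytest.approx(1.0)


def _pyramid(genome, n_bins, height, rng, noise=0.02):
    """Monotone origin-peaked profile (exponential marker-frequency shape)."""
    centres = np.arange(n_bins) * (genome.length // n_bins) + genome.length // (2 * n_bins)
    rel = np.array([genome.origin_distance(int(c)) for c in centres]) / (
        genome.length / 2
    )
    vals = height ** (1 - rel)
    return vals * rng.normal(1.0, noise, n_bins)


class TestPlateauDetector:
    def test_monotone_pyramids_give_no_plateau(self, toy_genome, rng):
        for _ in range(20):
            vals = _pyramid(toy_genome, 1_000, height=rng.uniform(2, 8), rng=rng)
            track = track_from_binned(toy_genome, vals, 10)
            plateaus = detect_degradation_plateau(track, min_length=50)
            assert len(plateaus) == 0

    def test_constructed_plateau_found_with_boundaries(self, toy_genome, rng):
        n = 1_000
        vals = _pyramid(toy_genome, n, height=4.0, rng=rng, noise=0.005)
        # carve a flat, below-trend region between two loci equidistant
        # from oriC (bin 600): bins 450..750 across the origin
        lo, hi = 450, 750
        level = vals[[lo - 1, hi + 1]].mean() * 0.7
        vals[lo : hi + 1] = level * rng.normal(1.0, 0.003, hi + 1 - lo)
        track = track_from_binned(toy_genome, vals, 10)
        plateaus = detect_degradation_plateau(track, min_length=50)
        assert len(plateaus) == 1
        assert abs(plateaus.loc[0, "start"] - lo * 10) <= 20
        assert abs(plateaus.loc[0, "end"] - (hi + 1) * 10) <= 20
        assert plateaus.loc[0, "level"] == pytest.approx(level, rel=0.02)

    def test_flat_track_has_no_plateau(self, toy_genome, rng):
        vals = np.full(1_000, 3.0) * rng.normal(1, 0.01, 1_000)
        track = track_from_binned(toy_genome, vals, 10)
        assert len(detect_degradation_plateau(track, min_length=50)) == 0


class TestOrientation:
    def test_pure_away_signal(self, toy_genome):
        n = 100
        fwd = np.zeros(n)
        rev = np.zeros(n)
        fwd[70:90] = 10.0  # right replichore (bins 60..100 wrap ori at 6000)
        track = track_from_binned(toy_genome, fwd + rev, 100, fwd=fwd, rev=rev)
        oi, away = orientation_index(track)
        assert away == pytest.approx(1.0)
        assert np.nanmax(oi) == 1.0

    def test_balanced_track_half(self, toy_genome, rng):
        sig = rng.uniform(1, 3, 100)
        track = track_from_binned(toy_genome, 2 * sig, 100, fwd=sig, rev=sig.copy())
        oi, away = orientation_index(track)
        np.testing.assert_allclose(oi[np.isfinite(oi)], 0.0, atol=1e-12)
        assert away == pytest.approx(0.5)

    def test_oi_bounded(self, toy_genome, rng):
        fwd = rng.uniform(0, 5, 100)
        rev = rng.uniform(0, 5, 100)
        track = track_from_binned(toy_genome, fwd + rev, 100, fwd=fwd, rev=rev)
        oi, away = orientation_index(track)
        finite = oi[np.isfinite(oi)]
        assert np.all(finite >= -1) and np.all(finite <= 1)
        assert 0.0 <= away <= 1.0

    def test_unstranded_rejected(self, toy_genome):
        track = track_from_binned(toy_genome, np.ones(100), 100)
        with pytest.raises(ValueError):
            orientation_index(track)


class TestOriginTerminusRatio:
    def test_flat_track_unity(self, toy_genome):
        track = track_from_binned(toy_genome, np.full(100, 2.0), 100)
        assert origin_terminus_ratio(track, window=1_000) == pytest.approx(1.0)

    def test_zero_terminus_rejected(self, toy_genome):
        vals = np.full(100, 2.0)
        vals[8:12] = 0.0
        track = track_from_binned(toy_genome, vals, 100)
        with pytest.raises(ValueError):
            origin_terminus_ratio(track, window=1_000)


class TestCircularity:
    def test_rotation_invariance(self, rng):
        """Rotating the coordinate frame leaves summary statistics unchanged."""
        length, bw = 10_000, 100
        vals = rng.uniform(1, 5, length // bw)
        fwd = rng.uniform(0, 3, length // bw)
        rev = rng.uniform(0, 3, length // bw)
        shift_bins = 37
        shift = shift_bins * bw
        g0 = GenomeMap(length=length, oric=6_000, terminus_window=(800, 1_200))
        g1 = GenomeMap(
            length=length,
            oric=(6_000 + shift) % length,
            terminus_window=((800 + shift) % length, (1_200 + shift) % length),
        )
        t0 = track_from_binned(g0, vals, bw, fwd=fwd, rev=rev)
        t1 = track_from_binned(
            g1, np.roll(vals, shift_bins), bw,
            fwd=np.roll(fwd, shift_bins), rev=np.roll(rev, shift_bins),
        )
        assert origin_terminus_ratio(t0, 1_000) == pytest.approx(
            origin_terminus_ratio(t1, 1_000)
        )
        assert orientation_index(t0)[1] == pytest.approx(orientation_index(t1)[1])
        assert replicore_asymmetry(t0, 4_500) == pytest.approx(
            replicore_asymmetry(t1, (4_500 + shift) % length)
        )
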