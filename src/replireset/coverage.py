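"""Circular-genome coverage analytics.

Supports the two sequencing readouts of replication state: replication
run-out depth profiles (marker-frequency "pyramids", terminus-normalised
copy number, degradation plateaus, replichore asymmetry) and stranded
DNA-end maps (orientation index, fraction of end signal facing away from
the origin).

Tracks are fixed-width bins tiling the circle exactly once; coordinates are
0-based half-open and all operations respect circular wrap-around.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .genome import GenomeMap

__all__ = [
    "CoverageTrack",
    "bin_coverage",
    "read_bedgraph",
    "write_bedgraph",
    "normalize_track",
    "smooth_and_trim",
    "replicore_asymmetry",
    "detect_degradation_plateau",
    "orientation_index",
    "origin_terminus_ratio",
]

DEFAULT_BIN_WIDTH = 1000


def n_bins_for(genome: GenomeMap, bin_width: int) -> int:
    return int(np.ceil(genome.length / bin_width))


@dataclass
class CoverageTrack:
    """Binned coverage over a circular genome, optionally stranded.

    ``values`` holds the combined (or only) signal; stranded tracks carry
    ``fwd`` and ``rev`` with ``values`` their sum.  ``units`` is one of
    "raw", "cpm" or "cpm+terminus".
    """

    genome: GenomeMap
    bin_width: int
    values: np.ndarray
    fwd: np.ndarray | None = None
    rev: np.ndarray | None = None
    units: str = "raw"
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = n_bins_for(self.genome, self.bin_width)
        if len(self.values) != n:
            raise ValueError(f"expected {n} bins, got {len(self.values)}")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)

    @property
    def stranded(self) -> bool:
        return self.fwd is not None and self.rev is not None

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_width

    @property
    def bin_ends(self) -> np.ndarray:
        return np.minimum(self.bin_starts + self.bin_width, self.genome.length)

    def bin_of(self, pos: int) -> int:
        return int(self.genome.wrap(pos) // self.bin_width)

    @property
    def normalized(self) -> bool:
        return self.units != "raw"

    def copy(self) -> "CoverageTrack":
        return replace(
            self,
            values=self.values.copy(),
            fwd=None if self.fwd is None else self.fwd.copy(),
            rev=None if self.rev is None else self.rev.copy(),
            mask=self.mask.copy(),
        )


# ---------------------------------------------------------------------------
# Binning and IO


def read_bedgraph(path) -> pd.DataFrame:
    """Read a 4-column bedGraph (chrom, start, end, value; 0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        comment="#",
    )
    return df


def write_bedgraph(track: CoverageTrack, path, strand: str | None = None,
                   chrom: str = "chr") -> None:
    """Write one strand (or the combined signal) as bedGraph."""
    if strand == "fwd":
        vals = track.fwd
    elif strand == "rev":
        vals = track.rev
    else:
        vals = track.values
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": track.bin_starts,
            "end": track.bin_ends,
            "value": vals,
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def _accumulate(intervals: pd.DataFrame, genome: GenomeMap, bin_width: int) -> np.ndarray:
    """Length-weighted accumulation of interval signal into bins."""
    n = n_bins_for(genome, bin_width)
    out = np.zeros(n)
    starts = intervals["start"].to_numpy()
    ends = intervals["end"].to_numpy()
    values = intervals["value"].to_numpy(dtype=float)
    if np.any(starts < 0) or np.any(ends > genome.length) or np.any(ends < starts):
        raise ValueError("interval coordinates outside genome or inverted")
    for s, e, v in zip(starts, ends, values):
        if e == s:
            continue
        b0 = int(s // bin_width)
        b1 = int((e - 1) // bin_width)
        if b0 == b1:
            out[b0] += v * (e - s)
            continue
        out[b0] += v * ((b0 + 1) * bin_width - s)
        if b1 > b0 + 1:
            out[b0 + 1 : b1] += v * bin_width
        out[b1] += v * (e - b1 * bin_width)
    return out


def bin_coverage(
    intervals,
    genome: GenomeMap,
    bin_width: int = DEFAULT_BIN_WIDTH,
    stranded: bool = False,
) -> CoverageTrack:
    """Bin interval signal into fixed-width bins on the circular genome.

    ``intervals`` is a bedGraph path or DataFrame with columns start, end,
    value and, when ``stranded``, a ``strand`` column with "+"/"-".  Signal
    is length-weighted: an interval contributes value x overlap-bp to each
    bin, so the binned total conserves the input total.  Bins overlapping
    masked genome intervals are zeroed and flagged in ``track.mask``.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if not isinstance(intervals, pd.DataFrame):
        intervals = read_bedgraph(intervals)
    if genome.length % bin_width:
        warnings.warn(
            "bin width does not divide the genome length; last bin shortened",
            UserWarning,
            stacklevel=2,
        )
    if stranded:
        if "strand" not in intervals.columns:
            raise ValueError("stranded binning requires a 'strand' column")
        fwd = _accumulate(intervals[intervals["strand"] == "+"], genome, bin_width)
        rev = _accumulate(intervals[intervals["strand"] == "-"], genome, bin_width)
        track = CoverageTrack(genome, bin_width, fwd + rev, fwd=fwd, rev=rev)
    else:
        track = CoverageTrack(genome, bin_width, _accumulate(intervals, genome, bin_width))
    _apply_mask(track)
    return track


def track_from_binned(
    genome: GenomeMap,
    values,
    bin_width: int = DEFAULT_BIN_WIDTH,
    fwd=None,
    rev=None,
    units: str = "raw",
) -> CoverageTrack:
    """Wrap already-binned per-bin values (e.g. simulator output) as a track."""
    track = CoverageTrack(
        genome,
        bin_width,
        np.asarray(values, dtype=float),
        fwd=None if fwd is None else np.asarray(fwd, dtype=float),
        rev=None if rev is None else np.asarray(rev, dtype=float),
        units=units,
    )
    _apply_mask(track)
    return track


def _apply_mask(track: CoverageTrack) -> None:
    genome = track.genome
    if not genome.masked_intervals:
        return
    centres = track.bin_starts + (track.bin_ends - track.bin_starts) // 2
    mask = np.array([genome.is_masked(int(c)) for c in centres])
    track.mask |= mask
    track.values[mask] = 0.0
    for arr in (track.fwd, track.rev):
        if arr is not None:
            arr[mask] = 0.0


# ---------------------------------------------------------------------------
# Normalisation


def _window_bins(track: CoverageTrack, window: tuple[int, int]) -> np.ndarray:
    start, end = window
    b0 = track.bin_of(start)
    b1 = track.bin_of((end - 1) % track.genome.length)
    if b1 >= b0:
        bins = np.arange(b0, b1 + 1)
    else:  # window wraps the coordinate origin
        bins = np.r_[np.arange(b0, track.n_bins), np.arange(0, b1 + 1)]
    return bins


def normalize_track(track: CoverageTrack, mode: str = "cpm") -> CoverageTrack:
    """Counts-per-million normalisation, optionally terminus-corrected.

    ``mode="cpm"`` rescales so the unmasked total is 1e6; it is idempotent.
    ``mode="cpm+terminus"`` additionally divides by the mean CPM over the
    genome's terminus window, so terminus copy number sits at ~1 and every
    other bin reads as copy number relative to the terminus.
    """
    if mode not in ("cpm", "cpm+terminus"):
        raise ValueError(f"unknown normalisation mode {mode!r}")
    out = track.copy()
    total = out.values[~out.mask].sum()
    if total <= 0:
        raise ValueError("track has no signal to normalise")
    scale = 1e6 / total
    out.values *= scale
    for arr in (out.fwd, out.rev):
        if arr is not None:
            arr *= scale
    out.units = "cpm"
    if mode == "cpm+terminus":
        bins = _window_bins(out, out.genome.terminus_window)
        usable = bins[~out.mask[bins]]
        if len(usable) == 0:
            raise ValueError("terminus window fully masked; cannot terminus-correct")
        ter = out.values[usable].mean()
        if ter <= 0:
            raise ValueError("terminus window has zero depth")
        out.values /= ter
        for arr in (out.fwd, out.rev):
            if arr is not None:
                arr /= ter
        out.units = "cpm+terminus"
    return out


# ---------------------------------------------------------------------------
# Averaging, trimming, smoothing


def _circular_loess(values: np.ndarray, span: float) -> np.ndarray:
    """Locally weighted degree-1 regression with tricube weights, circular."""
    n = len(values)
    half = max(2, int(round(span * n / 2)))
    pad = half
    ext = np.r_[values[-pad:], values, values[:pad]]
    x = np.arange(-half, half + 1, dtype=float)
    w = (1 - (np.abs(x) / (half + 1)) ** 3) ** 3
    # Weighted linear fit evaluated at the window centre reduces to a
    # convolution because the design is identical for every bin.
    s_w = w.sum()
    s_wx = (w * x).sum()  # zero by symmetry, kept for clarity
    s_wxx = (w * x * x).sum()
    denom = s_w * s_wxx - s_wx**2
    # beta0 at centre: (s_wxx * sum(w y) - s_wx * sum(w x y)) / denom
    wy = np.convolve(ext, w[::-1], mode="same")
    wxy = np.convolve(ext, (w * x)[::-1], mode="same")
    smoothed = (s_wxx * wy - s_wx * wxy) / denom
    return smoothed[pad : pad + n]


def smooth_and_trim(
    tracks,
    span: float = 0.02,
    trim_k: float = 5.0,
    trim_window: int = 11,
) -> CoverageTrack:
    """Average replicate tracks, trim outlier bins, loess-smooth circularly.

    Replicates are averaged per bin; bins deviating more than ``trim_k``
    robust SDs (1.4826 x rolling MAD) from a rolling median are removed and
    imputed from their neighbours; the result is smoothed with a circular
    tricube-weighted local linear regression over ``span`` x genome
    (``span=None`` averages and trims without smoothing).
    """
    if isinstance(tracks, CoverageTrack):
        tracks = [tracks]
    if not tracks:
        raise ValueError("no tracks supplied")
    if span is not None and not (0 < span <= 0.5):
        raise ValueError("span must be in (0, 0.5]")
    if trim_k <= 0:
        raise ValueError("trim_k must be positive")
    first = tracks[0]
    vals = np.mean([t.values for t in tracks], axis=0)
    mask = np.any([t.mask for t in tracks], axis=0)

    med = ndimage.median_filter(vals, size=trim_window, mode="wrap")
    mad = ndimage.median_filter(np.abs(vals - med), size=trim_window, mode="wrap")
    robust_sd = 1.4826 * mad
    outlier = np.abs(vals - med) > trim_k * np.maximum(robust_sd, 1e-12)
    good = ~outlier & ~mask
    if not np.any(good):
        raise ValueError("all bins trimmed; nothing left to smooth")
    if np.any(outlier):
        n = len(vals)
        idx_good = np.flatnonzero(good)
        idx_bad = np.flatnonzero(outlier & ~mask)
        # circular interpolation: extend the good support by one period
        xp = np.r_[idx_good, idx_good + n]
        fp = np.r_[vals[idx_good], vals[idx_good]]
        vals = vals.copy()
        vals[idx_bad] = np.interp(idx_bad + n, xp, fp)

    out = first.copy()
    out.values = _circular_loess(vals, span) if span is not None else vals
    out.fwd = out.rev = None
    out.mask = mask
    return out


# ---------------------------------------------------------------------------
# Profile summaries


def replicore_asymmetry(track: CoverageTrack, locus: int) -> float:
    """Depth at a locus over depth at the oriC-equidistant mirror locus."""
    genome = track.genome
    if genome.circular_distance(locus, genome.oric) == 0:
        raise ValueError("locus coincides with oriC; asymmetry undefined")
    b = track.bin_of(locus)
    bm = track.bin_of(genome.mirror_locus(locus))
    if track.mask[b] or track.mask[bm]:
        warnings.warn("locus or mirror bin masked; asymmetry undefined", UserWarning,
                      stacklevel=2)
        return float("nan")
    denom = track.values[bm]
    if denom == 0:
        return float("nan")
    return float(track.values[b] / denom)


def detect_degradation_plateau(
    track: CoverageTrack,
    min_length: int = 50,
    flatness_tol: float = 0.05,
    range_tol: float = 0.05,
    flank_bins: int | None = None,
    depth_margin: float = 0.02,
) -> pd.DataFrame:
    """Find flat, below-trend runs — the signature of nascent-arm degradation.

    A plateau is a maximal circular run of at least ``min_length`` bins in
    which (i) the per-bin slope magnitude never exceeds ``flatness_tol``
    times the genome-median depth, (ii) the level range across the run
    stays within ``range_tol`` of the median depth, and (iii) the mean
    level lies below the linear trend of the flanking bins extrapolated to
    the run centre by more than ``depth_margin`` times the median depth.
    Returns a DataFrame with columns start, end (bp, the run's circular
    interval) and level.
    """
    vals = track.values
    n = len(vals)
    scale = max(np.median(vals[~track.mask]), 1e-12)
    # circular per-bin slope
    slope = (np.roll(vals, -1) - vals) / scale
    flat = np.abs(slope) <= flatness_tol
    # bridge isolated single-bin noise breaches (a genuine boundary step is
    # much larger than the flatness tolerance)
    breach = ~flat & (np.abs(slope) <= 2 * flatness_tol)
    isolated = breach & np.roll(flat, 1) & np.roll(flat, -1)
    flat |= isolated

    if flank_bins is None:
        flank_bins = max(10, min_length // 2)

    # find circular runs of flat bins on a doubled array
    flat2 = np.r_[flat, flat]
    runs = []
    i = 0
    while i < n:  # run starts only scanned in first period
        if not flat2[i]:
            i += 1
            continue
        if i == 0 and flat[n - 1]:
            # continuation of a run that wraps the coordinate origin;
            # it is reported from its true (wrapped) start instead
            while i < n and flat2[i]:
                i += 1
            continue
        j = i
        while j < i + n and flat2[j]:
            j += 1
        runs.append((i, min(j, i + n)))
        i = j + 1
    out = []
    for i, j in runs:
        # flat slopes i..j-1 mean the level run covers value bins i..j
        length = j - i + 1
        if length < min_length:
            continue
        idx = np.arange(i, j + 1) % n
        level = float(vals[idx].mean())
        if np.ptp(vals[idx]) > range_tol * scale:
            continue
        centre = (i + j) / 2.0
        # each flank's own linear trend extrapolated to the run centre;
        # their mean is the expected level had no material been degraded
        extrapolated = []
        for xs in (np.arange(i - flank_bins, i), np.arange(j + 1, j + 1 + flank_bins)):
            ys = vals[xs % n]
            coef = np.polyfit(xs - centre, ys, 1)
            extrapolated.append(coef[1])
        trend_at_centre = float(np.mean(extrapolated))
        if trend_at_centre - level > depth_margin * scale:
            end_bin = (j % n) + 1
            out.append(
                {
                    "start": int((i % n) * track.bin_width),
                    "end": int(min(end_bin * track.bin_width, track.genome.length))
                    if end_bin <= n
                    else track.genome.length,
                    "level": level,
                }
            )
    return pd.DataFrame(out, columns=["start", "end", "level"])


def orientation_index(track: CoverageTrack, smooth_span: float | None = None):
    """Per-bin strand orientation index and the origin-facing summary.

    oi = (R - L) / (R + L) per bin where R/L are forward ("right-facing")
    and reverse ("left-facing") end signal.  ``away_fraction`` is the
    genome-wide fraction of end signal oriented away from oriC: forward
    strand on the right replichore, reverse strand on the left replichore.
    Returns ``(oi, away_fraction)`` with oi NaN where R + L = 0.
    """
    if not track.stranded:
        raise ValueError("orientation index requires a stranded track")
    fwd, rev = track.fwd, track.rev
    total = fwd + rev
    usable = ~track.mask
    if total[usable].sum() <= 0:
        raise ValueError("track has no end signal")
    with np.errstate(divide="ignore", invalid="ignore"):
        oi = np.where(total > 0, (fwd - rev) / np.where(total > 0, total, 1.0), np.nan)
    if smooth_span is not None:
        filled = np.where(np.isnan(oi), 0.0, oi)
        oi = _circular_loess(filled, smooth_span)

    centres = track.bin_starts + (track.bin_ends - track.bin_starts) // 2
    right = np.array([track.genome.replichore(int(c)) == "right" for c in centres])
    away = np.where(right, fwd, rev)
    away_fraction = float(away[usable].sum() / total[usable].sum())
    return oi, away_fraction


def plot_profile(track: CoverageTrack, ax=None, loci: bool = True):
    """Depth profile around the circle with oriC/terminus/named loci marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    x = (track.bin_starts + track.bin_ends) / 2 / 1e6
    ax.plot(x, track.values, lw=0.8)
    genome = track.genome
    ax.axvline(genome.oric / 1e6, color="tab:green", ls="--", lw=0.8, label="oriC")
    ax.axvline(genome.terminus / 1e6, color="tab:orange", ls="--", lw=0.8,
               label="terminus")
    if loci:
        for name, pos in genome.loci.items():
            ax.axvline(pos / 1e6, color="grey", ls=":", lw=0.8)
            ax.text(pos / 1e6, ax.get_ylim()[1], name, fontsize=7, ha="center")
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel(f"depth ({track.units})")
    ax.legend(frameon=False, fontsize=8)
    return ax


def origin_terminus_ratio(
    track: CoverageTrack, window: int = 100_000
) -> float:
    """Mean depth around oriC over mean depth in the terminus window."""
    genome = track.genome
    ori_bins = _window_bins(
        track, (genome.wrap(genome.oric - window // 2), genome.wrap(genome.oric + window // 2))
    )
    ter_bins = _window_bins(track, genome.terminus_window)
    ori_bins = ori_bins[~track.mask[ori_bins]]
    ter_bins = ter_bins[~track.mask[ter_bins]]
    if len(ori_bins) == 0 or len(ter_bins) == 0:
        raise ValueError("origin or terminus window fully masked")
    ter = track.values[ter_bins].mean()
    if ter <= 0:
        raise ValueError("terminus depth is zero; ratio undefined")
    return float(track.values[ori_bins].mean() / ter)
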