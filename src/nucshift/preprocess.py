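"""Normalization of probe-level intensities and fragment midpoints into occupancy tracks.

Tiling-array intensities arrive as a :class:`ProbeMatrix` (one column per
hybridization, probes on a uniform bp grid). The chain applied here mirrors
standard tiling-array practice for MNase nucleosome maps:

1. quantile normalization across arrays,
2. running-median smoothing over neighboring probes (30 nt bandwidth),
3. linear rescaling of every array to a common data range,
4. log2 ratio of each sample over a genomic-DNA control,
5. removal of slow baseline drift with a running median (5 kb window).

Sequencing mode converges on the same :class:`OccupancyTrack` container by
binning paired-end fragment midpoints onto the probe grid (each midpoint is
an estimate of a nucleosome center).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ProbeMatrix",
    "OccupancyTrack",
    "quantile_normalize",
    "median_smooth",
    "rescale_common_range",
    "detrend_baseline",
    "log_ratio",
    "midpoint_track",
    "preprocess_occupancy",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ProbeMatrix:
    """Probe-level intensities on a uniform genomic grid.

    positions are 1-based bp with a constant step; ``data`` holds one named
    column of linear-scale intensities per sample.
    """

    chrom: str
    positions: np.ndarray
    data: pd.DataFrame
    strand: str = "."

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if len(self.positions) != len(self.data):
            raise ValueError("positions and data length mismatch")
        if len(self.positions) > 1:
            steps = np.diff(self.positions)
            if steps.min() <= 0 or steps.min() != steps.max():
                raise ValueError("positions must be strictly increasing on a uniform grid")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("non-finite intensity values")

    @property
    def step(self) -> int:
        return int(self.positions[1] - self.positions[0]) if len(self.positions) > 1 else 1

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class OccupancyTrack:
    """Per-position log2 occupancy ratio (sample over control) on one chromosome."""

    chrom: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions/values shape mismatch")

    @property
    def step(self) -> int:
        return int(self.positions[1] - self.positions[0]) if len(self.positions) > 1 else 1


# ---------------------------------------------------------------------------
# array normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ProbeMatrix) -> ProbeMatrix:
    """Force every sample column onto the common (rank-mean) distribution.

    After the call, the sorted values of every column are identical: the
    per-rank mean over columns. Within-column rank order is preserved, and
    ties receive the average of the reference values at the tied ranks.
    """
    df = matrix.data
    if df.shape[1] < 2:
        warnings.warn("quantile_normalize with a single sample is the identity")
        return matrix
    values = df.to_numpy(dtype=float)
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return replace(matrix, data=pd.DataFrame(out, columns=df.columns, index=df.index))


def _rolling_median(values: np.ndarray, half_probes: int) -> np.ndarray:
    window = 2 * half_probes + 1
    s = pd.Series(values)
    return s.rolling(window, center=True, min_periods=1).median().to_numpy()


def median_smooth(track: OccupancyTrack, bandwidth: int = 30) -> OccupancyTrack:
    """Median filter over probes within ±bandwidth bp; edges use truncated windows."""
    if len(track.positions) == 0:
        return track
    step = track.step
    if bandwidth < step:
        raise ValueError("bandwidth must be at least the grid step")
    half = int(bandwidth // step)
    return OccupancyTrack(track.chrom, track.positions, _rolling_median(track.values, half))


def median_smooth_matrix(matrix: ProbeMatrix, bandwidth: int = 30) -> ProbeMatrix:
    """Column-wise :func:`median_smooth` on a probe matrix."""
    half = int(bandwidth // matrix.step)
    out = {c: _rolling_median(matrix.data[c].to_numpy(dtype=float), half) for c in matrix.data}
    return replace(matrix, data=pd.DataFrame(out, index=matrix.data.index))


def rescale_common_range(matrix: ProbeMatrix, lo_pct: float = 1.0, hi_pct: float = 99.0) -> ProbeMatrix:
    """Affinely map each sample so its 1st/99th percentiles match the cross-sample mean.

    The map is monotone, so within-sample order is preserved exactly. A sample
    with zero spread between the two percentiles is left untouched (warning).
    """
    df = matrix.data
    if df.shape[1] < 2:
        warnings.warn("rescale_common_range with a single sample is the identity")
        return matrix
    values = df.to_numpy(dtype=float)
    lo = np.percentile(values, lo_pct, axis=0)
    hi = np.percentile(values, hi_pct, axis=0)
    target_lo, target_hi = lo.mean(), hi.mean()
    out = values.copy()
    for j in range(values.shape[1]):
        spread = hi[j] - lo[j]
        if spread <= 0:
            warnings.warn(f"sample {df.columns[j]!r} has zero spread; left unscaled")
            continue
        out[:, j] = (values[:, j] - lo[j]) / spread * (target_hi - target_lo) + target_lo
    return replace(matrix, data=pd.DataFrame(out, columns=df.columns, index=df.index))


def detrend_baseline(track: OccupancyTrack, window: int = 5000) -> OccupancyTrack:
    """Subtract a running median over ``window`` bp to remove slow baseline drift."""
    if len(track.positions) == 0:
        return track
    step = track.step
    if window < 10 * step:
        raise ValueError("detrend window must be at least 10x the grid step")
    half = int(window // (2 * step))
    baseline = _rolling_median(track.values, half)
    return OccupancyTrack(track.chrom, track.positions, track.values - baseline)


def log_ratio(sample: OccupancyTrack | np.ndarray, control: OccupancyTrack | np.ndarray,
              chrom: str | None = None, positions: np.ndarray | None = None) -> OccupancyTrack:
    """log2(sample/control) per position; control values must be positive."""
    if isinstance(sample, OccupancyTrack):
        chrom, positions = sample.chrom, sample.positions
        sample_values = sample.values
    else:
        sample_values = np.asarray(sample, dtype=float)
    control_values = control.values if isinstance(control, OccupancyTrack) else np.asarray(control, dtype=float)
    bad = np.flatnonzero(control_values <= 0)
    if bad.size:
        pos = positions[bad[0]] if positions is not None else bad[0]
        raise ValueError(f"nonpositive control value at position {pos}")
    return OccupancyTrack(chrom or "", positions, np.log2(sample_values / control_values))


# ---------------------------------------------------------------------------
# sequencing mode
# ---------------------------------------------------------------------------

def midpoint_track(pairs: pd.DataFrame, chrom_length: int, step: int = 4,
                   chrom: str = "") -> tuple[OccupancyTrack, int]:
    """Bin paired-end fragment midpoints onto the probe grid.

    ``pairs`` needs ``start``/``end`` columns (1-based closed). The fragment
    midpoint estimates the nucleosome center; counts are assigned to the
    nearest grid position. Returns the count track and the number of malformed
    pairs (end < start) that were skipped; total count is otherwise preserved.
    """
    positions = np.arange(1, chrom_length + 1, step, dtype=np.int64)
    counts = np.zeros(len(positions))
    if len(pairs) == 0:
        return OccupancyTrack(chrom, positions, counts), 0
    start = pairs["start"].to_numpy(dtype=np.int64)
    end = pairs["end"].to_numpy(dtype=np.int64)
    ok = end >= start
    n_skipped = int((~ok).sum())
    mid = np.rint((start[ok] + end[ok]) / 2.0)
    idx = np.clip(np.rint((mid - 1) / step).astype(np.int64), 0, len(positions) - 1)
    np.add.at(counts, idx, 1.0)
    return OccupancyTrack(chrom, positions, counts), n_skipped


# ---------------------------------------------------------------------------
# the full array-mode chain
# ---------------------------------------------------------------------------

def preprocess_occupancy(matrix: ProbeMatrix, sample_cols: list[str], control_col: str,
                         smooth_bandwidth: int = 30, baseline_window: int = 5000,
                         ) -> dict[str, OccupancyTrack]:
    """Run the full array chain and return one detrended log2-ratio track per sample.

    The MNase sample columns are quantile-normalized together; the genomic-DNA
    control is smoothed but kept out of the normalization (its marginal
    distribution differs from nucleosomal samples by design) and serves as the
    ratio denominator.
    """
    samples = replace(matrix, data=matrix.data[sample_cols])
    if len(sample_cols) > 1:
        samples = quantile_normalize(samples)
    samples = median_smooth_matrix(samples, smooth_bandwidth)
    if len(sample_cols) > 1:
        samples = rescale_common_range(samples)
    half = int(smooth_bandwidth // matrix.step)
    control = _rolling_median(matrix.data[control_col].to_numpy(dtype=float), half)
    tracks: dict[str, OccupancyTrack] = {}
    for name in sample_cols:
        ratio = log_ratio(samples.data[name].to_numpy(dtype=float), control,
                          chrom=matrix.chrom, positions=matrix.positions)
        tracks[name] = detrend_baseline(ratio, baseline_window)
    return tracks
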