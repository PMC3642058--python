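"""Nucleosome center calling from occupancy tracks.

The occupancy signal is convolved with a discretized Gaussian (bandwidth
50 nt, mean 0, sd 25) and nucleosome centers are assigned sequentially to the
highest remaining local maxima of the Gaussian score until no candidate is
left more than 100 nt away from every already-called position. The 10% of
calls with the lowest score are flagged as excluded, and retained calls inside
genes are numbered +1, +2, ... by strand-aware distance downstream of the TSS.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .preprocess import OccupancyTrack
from .synthio import Gene

__all__ = [
    "GaussianKernel",
    "NucleosomeCall",
    "GenicCall",
    "gaussian_score",
    "call_positions",
    "filter_low_scores",
    "assign_genic",
]


@dataclass(frozen=True)
class GaussianKernel:
    """Discretized normal smoothing kernel, truncated at ±half_support bp."""

    sd: float = 25.0
    mean: float = 0.0
    half_support: int = 50

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.half_support < self.sd:
            raise ValueError("half_support must be at least the sd")

    def weights(self, step: int) -> tuple[np.ndarray, np.ndarray]:
        """(offsets in bp, unit-sum weights) sampled on the grid step."""
        k = int(self.half_support // step)
        offsets = step * np.arange(-k, k + 1, dtype=float)
        w = norm.pdf(offsets, loc=self.mean, scale=self.sd)
        return offsets, w / w.sum()


@dataclass
class NucleosomeCall:
    chrom: str
    center: int
    score: float
    retained: bool = True


@dataclass
class GenicCall:
    gene_id: str
    index: int          # +1 = first call downstream of the TSS
    call: NucleosomeCall


def gaussian_score(track: OccupancyTrack, kernel: GaussianKernel = GaussianKernel()) -> OccupancyTrack:
    """Convolve the track with the kernel; truncated edge windows are renormalized."""
    step = track.step
    if step > kernel.half_support:
        raise ValueError("grid step exceeds the kernel half-support")
    _, w = kernel.weights(step)
    values = np.asarray(track.values, dtype=float)
    num = np.convolve(values, w, mode="same")
    den = np.convolve(np.ones_like(values), w, mode="same")
    return OccupancyTrack(track.chrom, track.positions, num / den)


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus contribute their leftmost point.

    Track endpoints never qualify (a monotone track has no local maximum).
    """
    n = len(values)
    if n < 3:
        return np.empty(0, dtype=np.int64)
    change = np.flatnonzero(np.diff(values) != 0)
    run_starts = np.r_[0, change + 1]
    run_vals = values[run_starts]
    if len(run_starts) < 3:
        return np.empty(0, dtype=np.int64)
    interior = np.arange(1, len(run_starts) - 1)
    is_max = (run_vals[interior] > run_vals[interior - 1]) & (run_vals[interior] > run_vals[interior + 1])
    return run_starts[interior[is_max]]


def call_positions(score: OccupancyTrack, min_separation: int = 100) -> list[NucleosomeCall]:
    """Greedy sequential assignment of centers to the highest local maxima.

    Candidates are the local maxima of the score; the highest remaining one is
    accepted if it lies more than ``min_separation`` bp from every call made so
    far. Equal scores are broken toward the leftmost coordinate.
    """
    values = np.asarray(score.values, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("scores must be finite")
    cand = _local_maxima(values)
    if cand.size == 0:
        return []
    pos = score.positions[cand]
    sc = values[cand]
    order = np.lexsort((pos, -sc))
    accepted_pos: list[int] = []
    calls: list[NucleosomeCall] = []
    for i in order:
        p = int(pos[i])
        j = bisect.bisect_left(accepted_pos, p)
        if j > 0 and p - accepted_pos[j - 1] <= min_separation:
            continue
        if j < len(accepted_pos) and accepted_pos[j] - p <= min_separation:
            continue
        accepted_pos.insert(j, p)
        calls.append(NucleosomeCall(score.chrom, p, float(sc[i])))
    calls.sort(key=lambda c: c.center)
    return calls


def filter_low_scores(calls: list[NucleosomeCall], fraction: float = 0.10) -> list[NucleosomeCall]:
    """Flag the floor(fraction*N) lowest-score calls as not retained.

    The exclusion is global across the provided analysis set (all chromosomes
    pooled). Score ties at the cutoff are resolved by excluding the leftmost
    first so the excluded count is exact.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    n_excl = math.floor(fraction * len(calls))
    scores = np.array([c.score for c in calls])
    pos = np.array([c.center for c in calls])
    order = np.lexsort((pos, scores))
    excluded = set(order[:n_excl].tolist())
    return [NucleosomeCall(c.chrom, c.center, c.score, retained=i not in excluded)
            for i, c in enumerate(calls)]


def assign_genic(calls: list[NucleosomeCall], genes: list[Gene],
                 past_tes: int = 100) -> dict[str, list[GenicCall]]:
    """Number retained calls +1, +2, ... by strand-aware distance from each TSS.

    A call is genic for a gene if its center is strictly downstream of the TSS
    (on the gene's strand) and no further than ``past_tes`` bp beyond the TES.
    Genes overlapping on opposite strands may share a call. Genes with no
    downstream call map to an empty list.
    """
    by_chrom: dict[str, list[NucleosomeCall]] = {}
    for c in calls:
        if c.retained:
            by_chrom.setdefault(c.chrom, []).append(c)
    for chrom_calls in by_chrom.values():
        chrom_calls.sort(key=lambda c: c.center)
    out: dict[str, list[GenicCall]] = {}
    for gene in genes:
        chrom_calls = by_chrom.get(gene.chrom, [])
        d = gene.direction
        picked = []
        for c in chrom_calls:
            dist = (c.center - gene.tss) * d
            if dist <= 0:
                continue
            if (c.center - gene.tes) * d > past_tes:
                continue
            picked.append((dist, c))
        picked.sort(key=lambda t: t[0])
        out[gene.gene_id] = [GenicCall(gene.gene_id, k, c) for k, (_, c) in enumerate(picked, start=1)]
    return out
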