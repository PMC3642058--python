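"""Nucleosome shift statistics against a wild-type panel.

A shift is the signed change of a matched nucleosome's center position
between a condition and its WT reference, with positive values pointing away
from the TSS. Each WT call is matched to the nearest condition call within a
100-bp window; a nucleosome is significantly shifted when it moved by at least
10 bp in the same direction in every replicate and a two-sample t-test of the
replicate center positions against the positions observed across the panel of
independently grown WT conditions gives p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .nuccall import GenicCall, NucleosomeCall

__all__ = [
    "ShiftRecord",
    "PositionSummary",
    "match_positions",
    "match_shift",
    "significance",
    "build_shift_records",
    "position_summary",
    "flag_condition",
    "neighbor_profiles",
    "smoothed_profile",
]


@dataclass
class ShiftRecord:
    gene_id: str
    genic_index: int
    chrom: str
    wt_pos: int
    strand: str
    replicate_deltas: list[float]              # signed bp, + = away from TSS
    replicate_positions: list[float]           # matched genomic center positions
    wt_panel_positions: list[float]
    delta: float = float("nan")                # mean over replicates
    p_value: float = float("nan")
    significant: bool = False
    testable: bool = True

    def __post_init__(self) -> None:
        if self.replicate_deltas:
            self.delta = float(np.mean(self.replicate_deltas))


@dataclass
class PositionSummary:
    genic_index: int
    median: float
    q1: float
    q3: float
    n: int


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def match_positions(ref: np.ndarray, query: np.ndarray, window: int = 100,
                    strand: str = "+") -> list[int | None]:
    """Nearest query position within ±window for each reference position.

    Equidistant candidates resolve toward the TSS (lower coordinate on '+',
    higher on '-'), which is conservative against inflating away-shifts.
    Returns the matched query position or None per reference position.
    """
    query = np.sort(np.asarray(query, dtype=np.int64))
    out: list[int | None] = []
    for p in np.asarray(ref, dtype=np.int64):
        j = np.searchsorted(query, p)
        cands = []
        if j > 0:
            cands.append(int(query[j - 1]))
        if j < len(query):
            cands.append(int(query[j]))
        best = None
        for q in cands:
            if abs(q - p) > window:
                continue
            if best is None or abs(q - p) < abs(best - p):
                best = q
            elif abs(q - p) == abs(best - p):
                best = min(best, q) if strand == "+" else max(best, q)
        out.append(best)
    return out


def match_shift(wt_calls: list[NucleosomeCall], cond_calls: list[NucleosomeCall],
                window: int = 100, strand: str = "+") -> list[float | None]:
    """Per-WT-call signed delta (positive away from the TSS) or None if unmatched."""
    wt_pos = np.array([c.center for c in wt_calls], dtype=np.int64)
    cond_pos = np.array([c.center for c in cond_calls], dtype=np.int64)
    d = 1 if strand == "+" else -1
    matched = match_positions(wt_pos, cond_pos, window, strand)
    return [None if m is None else float((m - p) * d) for p, m in zip(wt_pos, matched)]


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------

def _pooled_t_p(x: np.ndarray, y: np.ndarray, floor_sd_y: float = 1.0) -> float:
    """Two-sample pooled-variance Student t-test p-value.

    The pooled test keeps its power when the treatment has only two
    replicates (the panel's 30 degrees of freedom carry the variance
    estimate); the panel sd is floored to guard degenerate zero-variance
    panels.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    vx = float(np.var(x, ddof=1)) if nx > 1 else 0.0
    vy = max(float(np.var(y, ddof=1)), floor_sd_y ** 2)
    df = nx + ny - 2
    pooled = ((nx - 1) * vx + (ny - 1) * vy) / df
    se = np.sqrt(pooled * (1.0 / nx + 1.0 / ny))
    if se == 0:
        return 1.0
    t = (x.mean() - y.mean()) / se
    return float(2.0 * stats.t.sf(abs(t), df))


def significance(record: ShiftRecord, min_shift: float = 10.0, alpha: float = 0.05) -> ShiftRecord:
    """Apply the replicate-direction rule and the panel t-test to one record.

    Significant iff every replicate delta has |delta| >= min_shift, all
    replicate deltas share a sign, and the pooled t-test of replicate center
    positions against the WT panel positions gives p < alpha. Records with
    fewer than 2 replicates or fewer than 3 panel positions are untestable.
    """
    deltas = np.asarray(record.replicate_deltas, dtype=float)
    if len(deltas) < 2 or len(record.wt_panel_positions) < 3:
        record.testable = False
        record.significant = False
        return record
    record.p_value = _pooled_t_p(np.asarray(record.replicate_positions, dtype=float),
                                 np.asarray(record.wt_panel_positions, dtype=float))
    same_sign = np.all(deltas > 0) or np.all(deltas < 0)
    big_enough = bool(np.all(np.abs(deltas) >= min_shift))
    record.significant = bool(same_sign and big_enough and record.p_value < alpha)
    return record


def build_shift_records(wt_genic: dict[str, list[GenicCall]],
                        cond_genic_reps: list[dict[str, list[GenicCall]]],
                        panel_genic: list[dict[str, list[GenicCall]]],
                        genes_by_id: dict, window: int = 100,
                        min_shift: float = 10.0, alpha: float = 0.05) -> list[ShiftRecord]:
    """Assemble per-(gene, genic index) ShiftRecords from called nucleosomes.

    Replicate and panel calls are matched to the WT reference call position
    within the window; records missing a match in any replicate are dropped
    (the nucleosome is absent rather than shifted), matching-window semantics
    are strand-aware throughout.
    """
    records: list[ShiftRecord] = []
    for gene_id, wt_calls in wt_genic.items():
        gene = genes_by_id[gene_id]
        strand, d = gene.strand, gene.direction
        for gc in wt_calls:
            wt_pos = gc.call.center
            rep_deltas, rep_positions = [], []
            complete = True
            for rep in cond_genic_reps:
                positions = np.array([g.call.center for g in rep.get(gene_id, [])])
                m = match_positions(np.array([wt_pos]), positions, window, strand)[0]
                if m is None:
                    complete = False
                    break
                rep_positions.append(float(m))
                rep_deltas.append(float((m - wt_pos) * d))
            if not complete:
                continue
            panel_positions = []
            for panel in panel_genic:
                positions = np.array([g.call.center for g in panel.get(gene_id, [])])
                m = match_positions(np.array([wt_pos]), positions, window, strand)[0]
                if m is not None:
                    panel_positions.append(float(m))
            rec = ShiftRecord(gene_id, gc.index, gene.chrom, wt_pos, strand,
                              rep_deltas, rep_positions, panel_positions)
            records.append(significance(rec, min_shift, alpha))
    return records


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def position_summary(records: list[ShiftRecord], max_index: int = 8) -> list[PositionSummary]:
    """Median and quartiles of the mean shift per genic index (indices 1..max_index)."""
    by_index: dict[int, list[float]] = {}
    for r in records:
        if 1 <= r.genic_index <= max_index and np.isfinite(r.delta):
            by_index.setdefault(r.genic_index, []).append(r.delta)
    out = []
    for idx in sorted(by_index):
        v = np.asarray(by_index[idx])
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        out.append(PositionSummary(idx, float(med), float(q1), float(q3), len(v)))
    return out


def flag_condition(summaries: list[PositionSummary], threshold: float = 4.0) -> bool:
    """Condition shows a genic shift pattern iff any index has |median| >= threshold bp."""
    return any(abs(s.median) >= threshold for s in summaries)


def neighbor_profiles(records: list[ShiftRecord], focal_index: int,
                      max_index: int = 8) -> pd.DataFrame:
    """Mean shift ± 95% CI at every genic index, with genes grouped by the
    significance status of their focal-index nucleosome (positive/negative/none).
    """
    group_of: dict[str, str] = {r.gene_id: "none" for r in records}
    for r in records:
        if r.genic_index == focal_index and r.significant:
            group_of[r.gene_id] = "positive" if r.delta > 0 else "negative"
    rows = []
    for group in ("positive", "negative", "none"):
        by_index: dict[int, list[float]] = {}
        for r in records:
            if group_of.get(r.gene_id) == group and 1 <= r.genic_index <= max_index:
                by_index.setdefault(r.genic_index, []).append(r.delta)
        for idx in sorted(by_index):
            v = np.asarray(by_index[idx])
            mean = float(v.mean())
            if len(v) >= 2:
                half = 1.96 * v.std(ddof=1) / np.sqrt(len(v))
                lo, hi = mean - half, mean + half
            else:
                lo = hi = float("nan")
            rows.append((group, idx, mean, lo, hi, len(v)))
    return pd.DataFrame(rows, columns=["group", "index", "mean", "ci_lo", "ci_hi", "n"])


def smoothed_profile(offsets: np.ndarray, values: np.ndarray,
                     bandwidth: int = 25) -> pd.DataFrame:
    """Mean curve with normal-approximation 95% CI over values within ±bandwidth
    of each populated offset; offsets with an empty window leave a gap."""
    offsets = np.asarray(offsets)
    values = np.asarray(values, dtype=float)
    if offsets.size and offsets.max() - offsets.min() < bandwidth:
        raise ValueError("offsets must span at least the bandwidth")
    order = np.argsort(offsets, kind="mergesort")
    offsets, values = offsets[order], values[order]
    grid = np.arange(offsets.min() - bandwidth, offsets.max() + bandwidth + 1) if offsets.size else np.empty(0)
    rows = []
    for o in grid:
        lo = np.searchsorted(offsets, o - bandwidth, side="left")
        hi = np.searchsorted(offsets, o + bandwidth, side="right")
        window = values[lo:hi]
        if window.size == 0:
            continue
        mean = float(window.mean())
        if window.size >= 2:
            half = 1.96 * window.std(ddof=1) / np.sqrt(window.size)
            ci_lo, ci_hi = mean - half, mean + half
        else:
            ci_lo = ci_hi = float("nan")
        rows.append((int(o), mean, ci_lo, ci_hi, int(window.size)))
    return pd.DataFrame(rows, columns=["offset", "mean", "ci_lo", "ci_hi", "n"])
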