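"""Strand-specific detection of differentially transcribed regions (transfrags).

Per-probe statistics pool expression intensities from all probes within a
30-bp bandwidth across replicates and compare treatment to control with a
two-sided Wilcoxon rank-sum test. Transfrags are maximal runs of probes
passing a fold-change >= 2 and p <= 0.05 threshold in the same direction
(maximum 48-nt gap between passing probes) that span at least 80 nt and 10
probes. Neighboring transfrags are merged when four criteria hold (<= 250-bp
gap, same strand, same direction, consistent sign of all intervening probes),
transfrags covered > 20% by same-strand annotation are removed, and the rest
are classified by orientation relative to genes within 3 kb of their 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import mannwhitneyu

from .synthio import ExpressionSet, Gene

__all__ = [
    "Transfrag",
    "rank_sum_p",
    "probe_stats",
    "detect",
    "merge",
    "filter_annotated",
    "classify",
    "classify_all",
    "union_regions",
]

ORIENTATION_CLASSES = ("tandem-sense", "tandem-antisense", "diverging",
                       "converging", "intragenic-antisense", "unclassified")


@dataclass
class Transfrag:
    """A strand-specific differentially transcribed interval (1-based closed)."""

    chrom: str
    strand: str
    start: int
    end: int
    direction: str                  # "up" | "down"
    n_probes: int
    mean_log2_fc: float
    orientation_class: str = "unclassified"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and self.end >= start


# ---------------------------------------------------------------------------
# per-probe statistics
# ---------------------------------------------------------------------------

def rank_sum_p(treatment: np.ndarray, control: np.ndarray, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum p-value for one probe window.

    With ``method='auto'`` the exact null distribution of U is used for small
    windows (so complete-separation windows reproduce the exact enumeration
    value 2/C(n+m, n)); larger windows use the tie-corrected normal
    approximation. Fewer than 3 values in either group returns p = 1.
    """
    t = np.asarray(treatment, dtype=float)
    c = np.asarray(control, dtype=float)
    if len(t) < 3 or len(c) < 3:
        return 1.0
    if method == "auto":
        method = "exact" if max(len(t), len(c)) <= 40 else "asymptotic"
    p = mannwhitneyu(t, c, alternative="two-sided", method=method).pvalue
    return float(min(p, 1.0))


def probe_stats(treatment: np.ndarray, control: np.ndarray, positions: np.ndarray,
                chrom: str, strand: str, bandwidth: int = 30) -> pd.DataFrame:
    """Windowed fold change and rank-sum p-value per probe.

    ``treatment``/``control`` are (n_replicates, n_probes) intensity arrays on
    the shared grid. For each probe, values from all probes within ±bandwidth
    across replicates are pooled in each channel; log2_fc = log2 of the ratio
    of pooled means and p is the two-sided rank-sum p of the pooled windows.
    """
    t = np.atleast_2d(np.asarray(treatment, dtype=float))
    c = np.atleast_2d(np.asarray(control, dtype=float))
    positions = np.asarray(positions, dtype=np.int64)
    n = t.shape[1]
    step = int(positions[1] - positions[0]) if n > 1 else 1
    k = int(bandwidth // step)
    width = 2 * k + 1

    ones = np.ones(min(width, n))
    count = np.convolve(np.ones(n), ones, mode="same")
    sum_t = np.convolve(t.sum(axis=0), ones, mode="same")
    sum_c = np.convolve(c.sum(axis=0), ones, mode="same")
    mean_t = sum_t / (count * t.shape[0])
    mean_c = sum_c / (count * c.shape[0])
    log2_fc = np.log2(mean_t / mean_c)

    p = np.ones(n)
    if n >= width:
        tw = sliding_window_view(t, width, axis=1)         # (reps, n-width+1, width)
        cw = sliding_window_view(c, width, axis=1)
        tw = np.moveaxis(tw, 0, 1).reshape(n - width + 1, -1)
        cw = np.moveaxis(cw, 0, 1).reshape(n - width + 1, -1)
        method = "exact" if tw.shape[1] <= 40 and cw.shape[1] <= 40 else "asymptotic"
        if tw.shape[1] >= 3 and cw.shape[1] >= 3:
            p[k:n - k] = np.minimum(
                mannwhitneyu(tw, cw, alternative="two-sided", method=method, axis=1).pvalue, 1.0)
        for i in list(range(k)) + list(range(n - k, n)):
            lo, hi = max(0, i - k), min(n, i + k + 1)
            p[i] = rank_sum_p(t[:, lo:hi].ravel(), c[:, lo:hi].ravel())
    else:
        for i in range(n):
            lo, hi = max(0, i - k), min(n, i + k + 1)
            p[i] = rank_sum_p(t[:, lo:hi].ravel(), c[:, lo:hi].ravel())

    return pd.DataFrame({"chrom": chrom, "pos": positions, "strand": strand,
                         "log2_fc": log2_fc, "p": p})


def probe_stats_expression(es: ExpressionSet, bandwidth: int = 30) -> pd.DataFrame:
    """Convenience wrapper computing :func:`probe_stats` for an ExpressionSet."""
    return probe_stats(es.treatment.to_numpy(dtype=float).T,
                       es.control.to_numpy(dtype=float).T,
                       es.positions, es.chrom, es.strand, bandwidth)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def detect(stats: pd.DataFrame, fc_thresh: float = 2.0, p_thresh: float = 0.05,
           min_len: int = 80, min_probes: int = 10, max_gap: int = 48) -> list[Transfrag]:
    """Maximal same-direction runs of passing probes, subject to span/count/gap rules.

    A probe passes when |log2_fc| >= log2(fc_thresh) and p <= p_thresh.
    Consecutive passing probes more than ``max_gap`` bp apart, or with opposite
    fold-change signs, break the run. Runs are emitted iff they span at least
    ``min_len`` bp (first to last passing probe, closed) AND contain at least
    ``min_probes`` passing probes.
    """
    lfc_thresh = np.log2(fc_thresh)
    out: list[Transfrag] = []
    for (chrom, strand), grp in stats.groupby(["chrom", "strand"], sort=False):
        grp = grp.sort_values("pos", kind="mergesort")
        pos = grp["pos"].to_numpy(np.int64)
        fc = grp["log2_fc"].to_numpy(float)
        p = grp["p"].to_numpy(float)
        passing = np.flatnonzero((np.abs(fc) >= lfc_thresh) & (p <= p_thresh))
        if passing.size == 0:
            continue
        run: list[int] = []

        def flush(run: list[int]) -> None:
            if not run:
                return
            start, end = int(pos[run[0]]), int(pos[run[-1]])
            if end - start + 1 >= min_len and len(run) >= min_probes:
                mean_fc = float(fc[run].mean())
                out.append(Transfrag(chrom, strand, start, end,
                                     "up" if mean_fc > 0 else "down", len(run), mean_fc))

        for i in passing:
            if run and (pos[i] - pos[run[-1]] > max_gap or np.sign(fc[i]) != np.sign(fc[run[-1]])):
                flush(run)
                run = []
            run.append(int(i))
        flush(run)
    out.sort(key=lambda t: (t.chrom, t.strand, t.start))
    return out


def merge(transfrags: list[Transfrag], stats: pd.DataFrame, max_gap: int = 250) -> list[Transfrag]:
    """Merge neighboring transfrags when all four criteria hold.

    i) gap <= max_gap bp; ii) same strand; iii) same direction of change;
    iv) every intervening probe's log2 fold change has the direction's sign.
    Applied left to right until no further merge is possible (a single sweep
    reaches the fixed point because merging only extends regions rightward).
    """
    probe_index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for (chrom, strand), grp in stats.groupby(["chrom", "strand"], sort=False):
        grp = grp.sort_values("pos", kind="mergesort")
        probe_index[(chrom, strand)] = (grp["pos"].to_numpy(np.int64),
                                        grp["log2_fc"].to_numpy(float))
    out: list[Transfrag] = []
    key = lambda t: (t.chrom, t.strand)
    groups: dict[tuple[str, str], list[Transfrag]] = {}
    for t in transfrags:
        groups.setdefault(key(t), []).append(t)
    for (chrom, strand), group in groups.items():
        group = sorted(group, key=lambda t: t.start)
        pos, fc = probe_index.get((chrom, strand), (np.empty(0, np.int64), np.empty(0)))
        cur = group[0]
        for nxt in group[1:]:
            gap = nxt.start - cur.end - 1
            sign = 1.0 if cur.direction == "up" else -1.0
            lo = np.searchsorted(pos, cur.end, side="right")
            hi = np.searchsorted(pos, nxt.start, side="left")
            consistent = bool(np.all(np.sign(fc[lo:hi]) == sign)) if hi > lo else True
            if gap <= max_gap and nxt.direction == cur.direction and consistent:
                n = cur.n_probes + nxt.n_probes
                mean_fc = (cur.mean_log2_fc * cur.n_probes + nxt.mean_log2_fc * nxt.n_probes) / n
                cur = replace(cur, end=nxt.end, n_probes=n, mean_log2_fc=mean_fc)
            else:
                out.append(cur)
                cur = nxt
        out.append(cur)
    out.sort(key=lambda t: (t.chrom, t.strand, t.start))
    return out


# ---------------------------------------------------------------------------
# annotation filtering and orientation
# ---------------------------------------------------------------------------

def _union_overlap(start: int, end: int, intervals: list[tuple[int, int]]) -> int:
    """Total bp of [start, end] covered by the union of the intervals."""
    if not intervals:
        return 0
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    total = 0
    for s, e in merged:
        lo, hi = max(s, start), min(e, end)
        if hi >= lo:
            total += hi - lo + 1
    return total


def filter_annotated(transfrags: list[Transfrag], genes: list[Gene],
                     max_overlap_frac: float = 0.20) -> list[Transfrag]:
    """Drop transfrags whose same-strand annotated overlap exceeds the fraction.

    Overlap is the union over all same-strand features; removal requires the
    covered fraction to be strictly greater than ``max_overlap_frac``.
    """
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for g in genes:
        by_key.setdefault((g.chrom, g.strand), []).append((g.start, g.end))
    kept = []
    for t in transfrags:
        overlap = _union_overlap(t.start, t.end, by_key.get((t.chrom, t.strand), []))
        if overlap <= max_overlap_frac * t.length:
            kept.append(t)
    return kept


def classify(tf: Transfrag, genes: list[Gene], flank: int = 3000) -> str:
    """Orientation of a transfrag relative to overlapping/neighboring genes.

    Priority: (1) intragenic-antisense when the transfrag overlaps an
    opposite-strand gene; otherwise the nearest gene whose body or boundary
    lies within ``flank`` bp of the transfrag's 5' end decides:
    (2) diverging — opposite strand, its TSS at or upstream of the 5' end in
    the transfrag's orientation (the two transcribe outward from a shared
    region); (3) converging — opposite strand, wholly ahead of the 5' end,
    transcribing toward the transfrag; (4) tandem-sense — same strand, the 5'
    end downstream of the gene's TES; (5) tandem-antisense — opposite strand,
    the 5' end downstream of the gene's TES; otherwise unclassified.
    """
    same_chrom = [g for g in genes if g.chrom == tf.chrom]
    for g in same_chrom:
        if g.strand != tf.strand and tf.overlaps(g.start, g.end):
            return "intragenic-antisense"
    T = tf.five_prime
    d = 1 if tf.strand == "+" else -1

    def dist(g: Gene) -> int:
        if g.start <= T <= g.end:
            return 0
        return min(abs(T - g.start), abs(T - g.end))

    nearby = [g for g in same_chrom if dist(g) <= flank]
    if not nearby:
        return "unclassified"
    g = min(nearby, key=lambda g: (dist(g), g.start))
    e, Gs, Ge = g.direction, g.tss, g.tes
    if e == -d and (T - Gs) * d >= 0:
        return "diverging"
    if e == -d and (Gs - T) * d > 0 and (Ge - T) * d > 0:
        return "converging"
    if e == d and (T - Ge) * e > 0:
        return "tandem-sense"
    if e == -d and (T - Ge) * e > 0:
        return "tandem-antisense"
    return "unclassified"


def classify_all(transfrags: list[Transfrag], genes: list[Gene], flank: int = 3000) -> list[Transfrag]:
    return [replace(t, orientation_class=classify(t, genes, flank)) for t in transfrags]


# ---------------------------------------------------------------------------
# cross-condition union
# ---------------------------------------------------------------------------

def union_regions(condition_sets: dict[str, list[Transfrag]]) -> pd.DataFrame:
    """Collapse same-strand overlapping transfrags across conditions into a
    non-redundant union set; per condition, the mean log2 fold change of its
    member transfrags is reported for each union region (NaN when absent)."""
    conditions = list(condition_sets)
    items: dict[tuple[str, str], list[tuple[int, int, str, float]]] = {}
    for cond, tfs in condition_sets.items():
        for t in tfs:
            items.setdefault((t.chrom, t.strand), []).append((t.start, t.end, cond, t.mean_log2_fc))
    rows = []
    for (chrom, strand), group in sorted(items.items()):
        group.sort()
        cluster: list[tuple[int, int, str, float]] = []
        cluster_end = None

        def flush() -> None:
            if not cluster:
                return
            start = min(s for s, *_ in cluster)
            end = max(e for _, e, *_ in cluster)
            row = {"chrom": chrom, "strand": strand, "start": start, "end": end}
            for cond in conditions:
                fcs = [fc for s, e, c, fc in cluster if c == cond]
                row[f"mean_fc_{cond}"] = float(np.mean(fcs)) if fcs else float("nan")
            rows.append(row)

        for s, e, cond, fc in group:
            if cluster_end is not None and s <= cluster_end:
                cluster.append((s, e, cond, fc))
                cluster_end = max(cluster_end, e)
            else:
                flush()
                cluster = [(s, e, cond, fc)]
                cluster_end = e
        flush()
    return pd.DataFrame(rows)
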