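"""Combined occupancy + expression signatures.

Promoter NDRs are the 200 bp directly upstream of each curated TSS. Two
signatures combine transfrag calls with the change in log2 nucleosome
occupancy between a condition and its WT reference:

* TCR (Tup1/Cyc8-repressed-like): an up-regulated transfrag (>= 2-fold,
  p <= 0.05, >= 80 nt — guaranteed by the transfrag rules) coupled with at
  least a 1.5-fold occupancy decrease in the 200 bp upstream of its 5' end.
* PAT (promoter-associated transcript): a transfrag whose 5' end originates
  inside a gene's NDR window; PATs are tabulated by the orientation of the
  promoter they arise from (diverging vs tandem gene configuration).

TSS-anchored occupancy averaging and NDR-occupancy/expression ranking support
the compendium-style overviews.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .preprocess import OccupancyTrack
from .synthio import Gene
from .transfrag import Transfrag

__all__ = [
    "NdrWindow",
    "SignatureHit",
    "ndr_window",
    "ndr_occupancy_change",
    "detect_tcr",
    "detect_pat",
    "tss_profile",
    "rank_by_ndr",
]


@dataclass
class NdrWindow:
    gene_id: str
    chrom: str
    start: int
    end: int
    mean_docc: float = float("nan")
    truncated: bool = False


@dataclass
class SignatureHit:
    kind: str                     # "TCR" | "PAT"
    transfrag: Transfrag
    anchor: str                   # gene id (PAT) or locus id (TCR)
    upstream_docc: float
    category: str                 # TCR: subtelomeric|antisense|intergenic; PAT: diverging|tandem|unknown


def ndr_window(gene: Gene, width: int = 200) -> tuple[int, int]:
    """The ``width``-bp window directly upstream of the TSS (strand-aware,
    1-based closed, abutting but not including the TSS)."""
    if gene.strand == "+":
        return gene.tss - width, gene.tss - 1
    return gene.tss + 1, gene.tss + width


def _window_mean(track: OccupancyTrack, start: int, end: int) -> tuple[float, bool]:
    mask = (track.positions >= start) & (track.positions <= end)
    truncated = start < track.positions[0] or end > track.positions[-1]
    if not mask.any():
        return float("nan"), True
    return float(track.values[mask].mean()), truncated


def ndr_occupancy_change(gene: Gene, docc: dict[str, OccupancyTrack],
                         width: int = 200) -> NdrWindow:
    """Mean change in log2 occupancy over the gene's NDR window.

    Windows truncated by a chromosome end are averaged over the covered
    positions and flagged.
    """
    start, end = ndr_window(gene, width)
    track = docc[gene.chrom]
    mean, truncated = _window_mean(track, start, end)
    return NdrWindow(gene.gene_id, gene.chrom, start, end, mean, truncated)


def _upstream_window(chrom_pos: int, strand: str, width: int) -> tuple[int, int]:
    if strand == "+":
        return chrom_pos - width, chrom_pos - 1
    return chrom_pos + 1, chrom_pos + width


def detect_tcr(transfrags: list[Transfrag], docc: dict[str, OccupancyTrack],
               chrom_lengths: dict[str, int], occ_fold: float = 1.5,
               ndr_width: int = 200, subtelomeric_dist: int = 25_000) -> list[SignatureHit]:
    """Up-regulated transfrags with an upstream nucleosome-occupancy decrease.

    A hit requires direction "up" and a mean change in log2 occupancy over the
    ``ndr_width`` bp upstream of the transfrag's 5' end of at most
    -log2(occ_fold). Hits are categorized subtelomeric (5' end within
    ``subtelomeric_dist`` of a chromosome end), antisense (intragenic-antisense
    orientation) or intergenic.
    """
    threshold = -np.log2(occ_fold)
    hits: list[SignatureHit] = []
    for i, tf in enumerate(transfrags):
        if tf.direction != "up":
            continue
        start, end = _upstream_window(tf.five_prime, tf.strand, ndr_width)
        mean, _ = _window_mean(docc[tf.chrom], start, end)
        if not np.isfinite(mean) or mean > threshold:
            continue
        clen = chrom_lengths[tf.chrom]
        if min(tf.five_prime - 1, clen - tf.five_prime) <= subtelomeric_dist:
            category = "subtelomeric"
        elif tf.orientation_class == "intragenic-antisense":
            category = "antisense"
        else:
            category = "intergenic"
        hits.append(SignatureHit("TCR", tf, f"TCR{i + 1:03d}", mean, category))
    return hits


def promoter_configuration(gene: Gene, genes: list[Gene]) -> str:
    """Orientation of the two genes flanking a promoter NDR.

    The neighbor is the nearest gene on the far side of the NDR (upstream of
    the anchor's TSS). Opposite-strand neighbors share the intergenic region
    with the anchor's promoter facing it: diverging. Same-strand neighbors put
    the promoter downstream of the neighbor's TES: tandem.
    """
    d = gene.direction
    best = None
    for g in genes:
        if g.gene_id == gene.gene_id or g.chrom != gene.chrom:
            continue
        # gene body strictly on the upstream side of the anchor TSS
        if d == 1 and g.end < gene.tss:
            gap = gene.tss - g.end
        elif d == -1 and g.start > gene.tss:
            gap = g.start - gene.tss
        else:
            continue
        if best is None or gap < best[0]:
            best = (gap, g)
    if best is None:
        return "unknown"
    return "diverging" if best[1].strand != gene.strand else "tandem"


def detect_pat(transfrags: list[Transfrag], genes: list[Gene],
               ndr_width: int = 200) -> tuple[list[SignatureHit], dict]:
    """Transfrags originating inside a promoter NDR, with configuration counts.

    Anchoring ties (a 5' end inside two genes' NDR windows) resolve to the
    gene with the nearer TSS. The summary reports PAT counts and fractions at
    diverging vs tandem promoter configurations.
    """
    hits: list[SignatureHit] = []
    for tf in transfrags:
        anchors = []
        for g in genes:
            if g.chrom != tf.chrom:
                continue
            start, end = ndr_window(g, ndr_width)
            if start <= tf.five_prime <= end:
                anchors.append(g)
        if not anchors:
            continue
        anchor = min(anchors, key=lambda g: abs(g.tss - tf.five_prime))
        config = promoter_configuration(anchor, genes)
        hits.append(SignatureHit("PAT", tf, anchor.gene_id, float("nan"), config))
    n_div = sum(1 for h in hits if h.category == "diverging")
    n_tan = sum(1 for h in hits if h.category == "tandem")
    denom = n_div + n_tan
    summary = {
        "n_pats": len(hits),
        "n_diverging": n_div,
        "n_tandem": n_tan,
        "diverging_fraction": n_div / denom if denom else float("nan"),
        "tandem_fraction": n_tan / denom if denom else float("nan"),
    }
    return hits, summary


def tss_profile(tracks: dict[str, OccupancyTrack], genes: list[Gene],
                lo: int = -500, hi: int = 2000) -> pd.DataFrame:
    """Mean occupancy per bp offset relative to the TSS, strand-aware.

    Genes on the '-' strand contribute coordinate-reflected offsets; genes
    near chromosome ends contribute only the offsets their track covers.
    """
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for gene in genes:
        track = tracks.get(gene.chrom)
        if track is None:
            continue
        d = gene.direction
        offsets = (track.positions - gene.tss) * d
        mask = (offsets >= lo) & (offsets <= hi)
        for o, v in zip(offsets[mask], track.values[mask]):
            sums[int(o)] = sums.get(int(o), 0.0) + float(v)
            counts[int(o)] = counts.get(int(o), 0) + 1
    rows = [(o, sums[o] / counts[o], counts[o]) for o in sorted(sums)]
    return pd.DataFrame(rows, columns=["offset", "mean", "n"])


def rank_by_ndr(ndr_docc: dict[str, float], expression_change: dict[str, float],
                ) -> tuple[pd.DataFrame, float, int]:
    """Rank genes by mean NDR occupancy change, pairing the expression change.

    Returns the table sorted by mean_docc ascending (ties broken by gene id),
    the Spearman rank correlation between the two measures (NaN when
    undefined, e.g. a constant ranking), and the count of genes excluded for a
    missing expression value.
    """
    rows = []
    n_missing = 0
    for gene_id in sorted(ndr_docc):
        if gene_id not in expression_change:
            n_missing += 1
            continue
        rows.append((gene_id, ndr_docc[gene_id], expression_change[gene_id]))
    df = pd.DataFrame(rows, columns=["gene_id", "mean_docc", "expression_change"])
    df = df.sort_values(["mean_docc", "gene_id"], kind="mergesort").reset_index(drop=True)
    if len(df) >= 2 and df["mean_docc"].nunique() > 1 and df["expression_change"].nunique() > 1:
        rho = float(spearmanr(df["mean_docc"], df["expression_change"]).statistic)
    else:
        rho = float("nan")
    return df, rho, n_missing
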