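"""Pipeline configuration, wiring and shared I/O.

``PipelineConfig`` collects every tunable threshold with its standard default
(see docs/methods.md for units and rationale) and round-trips losslessly
through YAML. ``run_pipeline`` executes preprocess -> nucleosome calling ->
shift statistics -> transfrag segmentation -> signature scanning on the files
written by :func:`nucshift.synthio.write_scenario` (or files of the same
layout exported from real data), writing TSV/BED/JSON results plus a manifest
with a config hash and a checksum of every input and output file. Reruns on
identical inputs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nuccall, preprocess, shiftstats, signatures, transfrag
from .nuccall import GaussianKernel
from .synthio import read_gff3, read_probe_table, write_bed6

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("nucshift")


@dataclass
class PipelineConfig:
    """All pipeline thresholds (units: bp unless noted)."""

    kernel_sd: float = 25.0
    kernel_half_support: int = 50
    min_separation: int = 100
    score_exclusion: float = 0.10       # fraction of lowest-score calls dropped
    match_window: int = 100
    min_shift: float = 10.0
    alpha: float = 0.05                 # probability
    median_flag: float = 4.0
    probe_bandwidth: int = 30
    fc_thresh: float = 2.0              # fold
    p_thresh: float = 0.05              # probability
    min_len: int = 80
    min_probes: int = 10
    max_gap: int = 48
    merge_gap: int = 250
    overlap_frac: float = 0.20          # fraction
    flank: int = 3000
    ndr_width: int = 200
    occ_fold: float = 1.5               # fold
    smoothing: int = 25
    smooth_bandwidth: int = 30
    baseline_window: int = 5000
    subtelomeric_dist: int = 25_000
    seed: int = 0

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = yaml.safe_load(text) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def kernel(self) -> GaussianKernel:
        return GaussianKernel(sd=self.kernel_sd, half_support=self.kernel_half_support)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _calls_frame(calls: list[nuccall.NucleosomeCall]) -> pd.DataFrame:
    return pd.DataFrame([(c.chrom, c.center, c.score, c.retained) for c in calls],
                        columns=["chrom", "center", "score", "retained"])


def _call_track(track: preprocess.OccupancyTrack, config: PipelineConfig) -> list[nuccall.NucleosomeCall]:
    score = nuccall.gaussian_score(track, config.kernel)
    return nuccall.call_positions(score, config.min_separation)


def run_pipeline(config: PipelineConfig, indir: str | Path, outdir: str | Path) -> dict:
    """Run the full analysis on a scenario directory; returns the results bundle.

    Expects per-chromosome ``occupancy_<chrom>.tsv`` probe tables with
    ``wt_*``/``cond_*``/``panel_*``/``gdna`` columns, stranded
    ``expression_<chrom>_<plus|minus>.tsv`` tables with ``treat*``/``ctrl*``
    columns, ``genes.gff3`` and ``chrom_sizes.tsv``.
    """
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = read_gff3(indir / "genes.gff3")
    genes_by_id = {g.gene_id: g for g in genes}
    chrom_lengths = {}
    for line in (indir / "chrom_sizes.tsv").read_text().splitlines():
        chrom, clen = line.split("\t")
        chrom_lengths[chrom] = int(clen)
    inputs = sorted(indir.glob("*.tsv")) + sorted(indir.glob("*.gff3")) + sorted(indir.glob("*.json"))

    # --- preprocess: per-chromosome occupancy tracks ----------------------
    wt_tracks: dict[str, dict[str, preprocess.OccupancyTrack]] = {}
    cond_tracks: dict[str, dict[str, preprocess.OccupancyTrack]] = {}
    panel_tracks: dict[str, dict[str, preprocess.OccupancyTrack]] = {}
    docc: dict[str, preprocess.OccupancyTrack] = {}
    for chrom in chrom_lengths:
        matrix = read_probe_table(indir / f"occupancy_{chrom}.tsv")
        # normalize within each condition group (mutant vs its parallel WT
        # control): cross-group quantile mapping would compress
        # condition-specific occupancy changes toward the panel distribution
        groups = {
            "wt": [c for c in matrix.samples if c.startswith("wt_")],
            "cond": [c for c in matrix.samples if c.startswith("cond_")],
        }
        for c in matrix.samples:
            if c.startswith("panel_"):
                groups[c] = [c]
        tracks: dict[str, preprocess.OccupancyTrack] = {}
        for cols in groups.values():
            if cols:
                tracks.update(preprocess.preprocess_occupancy(
                    matrix, cols, "gdna", config.smooth_bandwidth, config.baseline_window))
        wt_tracks[chrom] = {c: tracks[c] for c in tracks if c.startswith("wt_")}
        cond_tracks[chrom] = {c: tracks[c] for c in tracks if c.startswith("cond_")}
        panel_tracks[chrom] = {c: tracks[c] for c in tracks if c.startswith("panel_")}
        wt_mean = np.mean([t.values for t in wt_tracks[chrom].values()], axis=0)
        cond_mean = np.mean([t.values for t in cond_tracks[chrom].values()], axis=0)
        docc[chrom] = preprocess.OccupancyTrack(chrom, matrix.positions, cond_mean - wt_mean)
    log.info("preprocess: %d chromosomes", len(chrom_lengths))

    # --- nucleosome calls -------------------------------------------------
    def call_group(tracks_by_chrom: dict[str, dict[str, preprocess.OccupancyTrack]],
                   combine: bool) -> dict[str, list[nuccall.NucleosomeCall]]:
        """Calls per sample name ('' = replicate-mean track), 10% filter pooled
        across chromosomes per sample."""
        per_sample: dict[str, list[nuccall.NucleosomeCall]] = {}
        for chrom, tracks in tracks_by_chrom.items():
            if combine:
                mean_values = np.mean([t.values for t in tracks.values()], axis=0)
                track = preprocess.OccupancyTrack(chrom, next(iter(tracks.values())).positions, mean_values)
                per_sample.setdefault("", []).extend(_call_track(track, config))
            else:
                for name, track in tracks.items():
                    per_sample.setdefault(name, []).extend(_call_track(track, config))
        return {name: nuccall.filter_low_scores(calls, config.score_exclusion)
                for name, calls in per_sample.items()}

    wt_calls = call_group(wt_tracks, combine=True)[""]
    cond_calls = call_group(cond_tracks, combine=False)
    panel_calls = call_group(panel_tracks, combine=False)
    wt_genic = nuccall.assign_genic(wt_calls, genes)
    cond_genic = [nuccall.assign_genic(c, genes) for c in cond_calls.values()]
    panel_genic = [nuccall.assign_genic(c, genes) for c in panel_calls.values()]
    log.info("nuccall: %d WT calls (%d retained)", len(wt_calls),
             sum(c.retained for c in wt_calls))

    # --- shifts -----------------------------------------------------------
    records = shiftstats.build_shift_records(wt_genic, cond_genic, panel_genic,
                                             genes_by_id, config.match_window,
                                             config.min_shift, config.alpha)
    summaries = shiftstats.position_summary(records)
    flagged = shiftstats.flag_condition(summaries, config.median_flag)
    log.info("shiftstats: %d records, %d significant", len(records),
             sum(r.significant for r in records))

    # --- transfrags -------------------------------------------------------
    stats_frames = []
    for path in sorted(indir.glob("expression_*.tsv")):
        matrix = read_probe_table(path)
        treat = matrix.data[[c for c in matrix.samples if c.startswith("treat")]]
        ctrl = matrix.data[[c for c in matrix.samples if c.startswith("ctrl")]]
        stats_frames.append(transfrag.probe_stats(
            treat.to_numpy(float).T, ctrl.to_numpy(float).T, matrix.positions,
            matrix.chrom, matrix.strand, config.probe_bandwidth))
    stats = pd.concat(stats_frames, ignore_index=True) if stats_frames else pd.DataFrame(
        columns=["chrom", "pos", "strand", "log2_fc", "p"])
    raw = transfrag.detect(stats, config.fc_thresh, config.p_thresh,
                           config.min_len, config.min_probes, config.max_gap)
    merged = transfrag.merge(raw, stats, config.merge_gap)
    retained = transfrag.filter_annotated(merged, genes, config.overlap_frac)
    classified = transfrag.classify_all(retained, genes, config.flank)
    log.info("transfrag: %d raw -> %d merged -> %d retained", len(raw), len(merged), len(classified))

    # --- signatures -------------------------------------------------------
    ndr = {g.gene_id: signatures.ndr_occupancy_change(g, docc, config.ndr_width) for g in genes}
    tcr = signatures.detect_tcr(classified, docc, chrom_lengths, config.occ_fold,
                                config.ndr_width, config.subtelomeric_dist)
    pat, pat_summary = signatures.detect_pat(classified, genes, config.ndr_width)
    log.info("signatures: %d TCR hits, %d PAT hits", len(tcr), len(pat))

    # --- outputs ----------------------------------------------------------
    written: list[Path] = []

    def emit_frame(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)

    emit_frame(_calls_frame(wt_calls), "wt_calls.tsv")
    genic_rows = [(gc.gene_id, gc.index, gc.call.chrom, gc.call.center, gc.call.score)
                  for calls in wt_genic.values() for gc in calls]
    emit_frame(pd.DataFrame(genic_rows, columns=["gene_id", "index", "chrom", "center", "score"]),
               "wt_genic_calls.tsv")
    bed_path = outdir / "wt_calls.bed"
    max_score = max((c.score for c in wt_calls), default=1.0) or 1.0
    write_bed6([(c.chrom, c.center, c.center, f"nuc{i}",
                 round(1000 * max(c.score, 0.0) / max(max_score, 1e-12)), ".")
                for i, c in enumerate(wt_calls) if c.retained], bed_path)
    written.append(bed_path)
    emit_frame(pd.DataFrame(
        [(r.gene_id, r.genic_index, r.chrom, r.wt_pos, r.delta,
          ";".join(f"{d:g}" for d in r.replicate_deltas), r.p_value, r.significant, r.testable)
         for r in records],
        columns=["gene_id", "index", "chrom", "wt_pos", "delta", "replicate_deltas",
                 "p_value", "significant", "testable"]), "shifts.tsv")
    emit_frame(pd.DataFrame([(s.genic_index, s.median, s.q1, s.q3, s.n) for s in summaries],
                            columns=["index", "median", "q1", "q3", "n"]), "position_summary.tsv")
    emit_frame(pd.DataFrame(
        [(t.chrom, t.strand, t.start, t.end, t.direction, t.n_probes, t.mean_log2_fc,
          t.orientation_class) for t in classified],
        columns=["chrom", "strand", "start", "end", "direction", "n_probes",
                 "mean_log2_fc", "orientation_class"]), "transfrags.tsv")
    emit_frame(pd.DataFrame(
        [(h.kind, h.anchor, h.transfrag.chrom, h.transfrag.strand, h.transfrag.start,
          h.transfrag.end, h.upstream_docc, h.category) for h in tcr + pat],
        columns=["kind", "anchor", "chrom", "strand", "start", "end",
                 "upstream_docc", "category"]), "signature_hits.tsv")
    emit_frame(pd.DataFrame(
        [(w.gene_id, w.chrom, w.start, w.end, w.mean_docc, w.truncated) for w in ndr.values()],
        columns=["gene_id", "chrom", "start", "end", "mean_docc", "truncated"]), "ndr_windows.tsv")

    summary = {
        "condition_flagged": bool(flagged),
        "n_wt_calls": len(wt_calls),
        "n_shift_records": len(records),
        "n_significant_shifts": int(sum(r.significant for r in records)),
        "n_transfrags": len(classified),
        "n_tcr": len(tcr),
        "n_pat": len(pat),
        "pat_summary": pat_summary,
    }
    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    written.append(summary_path)

    manifest = {
        "config": dataclasses.asdict(config),
        "config_sha256": config.digest(),
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": {p.name: _sha256(p) for p in written},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return {"wt_calls": wt_calls, "wt_genic": wt_genic, "records": records,
            "summaries": summaries, "flagged": flagged, "transfrags": classified,
            "tcr": tcr, "pat": pat, "pat_summary": pat_summary, "ndr": ndr,
            "docc": docc, "summary": summary, "manifest": manifest}
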