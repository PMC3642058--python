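"""Synthetic yeast-like chromatin scenarios with known ground truth.

Budding-yeast genes carry a nucleosome-depleted region (NDR) directly upstream
of the TSS followed by a regularly phased array of ~147-bp nucleosome cores
separated by ~18-bp linkers. The generator reproduces that geometry on a 4-bp
probe grid (the tiling-array design), together with stranded expression
baselines and paired-end fragment midpoints, so that every downstream stage —
normalization, peak calling, shift statistics, transfrag segmentation and
signature scanning — can be tested against planted truth:

* nucleosome shifts (per gene, per genic index, signed bp away from the TSS),
* interval-wise occupancy scaling (e.g. NDR deepening),
* cryptic sense/antisense transcripts with a chosen fold change,
* global histone depletion.

Occupancy arrays are emitted as linear probe intensities with lognormal noise
(additive Gaussian on the log2 scale) plus a flat genomic-DNA control column,
so the array normalization chain is exercised end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ProbeMatrix

__all__ = [
    "GenomeSpec",
    "PerturbationSpec",
    "SyntheticTruth",
    "Gene",
    "Genome",
    "ExpressionSet",
    "Scenario",
    "build_genome",
    "simulate_occupancy",
    "simulate_expression",
    "simulate_readpairs",
    "simulate_scenario",
    "write_scenario",
]


# ---------------------------------------------------------------------------
# specs and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Geometry of a synthetic genome.

    Defaults follow the yeast tiling-array setting: 147-bp cores, ~18-bp
    linkers (165-bp repeat), a 200-bp promoter NDR and 4-bp probe spacing.
    ``strands`` optionally fixes the per-gene strand pattern (cycled);
    otherwise strands are drawn at random.
    """

    n_chromosomes: int = 1
    chrom_length: int = 200_000
    n_genes: int = 80
    gene_length_mean: int = 1500
    intergenic_length_mean: int = 500
    ndr_width: int = 200
    core_width: int = 147
    linker_length: int = 18
    probe_spacing: int = 4
    seed: int = 0
    strands: tuple[str, ...] | None = None

    def validate(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "n_genes", "gene_length_mean",
                     "intergenic_length_mean", "ndr_width", "core_width",
                     "linker_length", "probe_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.chrom_length % self.probe_spacing != 0:
            raise ValueError("probe_spacing must divide chrom_length")
        if self.gene_length_mean < self.core_width:
            raise ValueError(
                f"gene_length_mean={self.gene_length_mean} is too short for a single "
                f"{self.core_width}-bp nucleosome core")
        if self.strands is not None and any(s not in "+-" for s in self.strands):
            raise ValueError("strands must contain only '+' and '-'")


@dataclass
class PerturbationSpec:
    """Planted deviations from the wild-type genome, with ground truth attached.

    shift_map: gene id -> {genic index -> signed bp}, positive = away from TSS.
    occupancy_scale_map: (chrom, start, end, factor) intervals; the linear
    occupancy signal inside the interval is multiplied by the factor.
    cryptic_transcripts: (chrom, start, end, strand, fold) intervals whose
    treatment-channel expression is multiplied by ``fold``.
    """

    shift_map: dict[str, dict[int, int]] = field(default_factory=dict)
    occupancy_scale_map: list[tuple[str, int, int, float]] = field(default_factory=list)
    cryptic_transcripts: list[tuple[str, int, int, str, float]] = field(default_factory=list)
    global_histone_depletion: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.global_histone_depletion <= 1.0:
            raise ValueError("global_histone_depletion must be in [0, 1]")
        for chrom, start, end, factor in self.occupancy_scale_map:
            if factor <= 0:
                raise ValueError(f"occupancy scale factor must be positive on {chrom}:{start}-{end}")
        for chrom, start, end, strand, fold in self.cryptic_transcripts:
            if fold <= 0:
                raise ValueError(f"cryptic transcript fold must be positive on {chrom}:{start}-{end}")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a scenario, for recovery tests."""

    true_centers: dict[str, list[int]] = field(default_factory=dict)
    true_transfrags: list[tuple[str, int, int, str, float]] = field(default_factory=list)
    true_signature_loci: list[tuple[str, int, int, str]] = field(default_factory=list)


@dataclass
class Gene:
    """One annotated gene. Coordinates 1-based closed; for '-' genes TSS > TES."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def direction(self) -> int:
        return 1 if self.strand == "+" else -1


@dataclass
class Genome:
    spec: GenomeSpec
    chrom_lengths: dict[str, int]
    genes: list[Gene]
    truth: SyntheticTruth

    def genes_on(self, chrom: str) -> list[Gene]:
        return [g for g in self.genes if g.chrom == chrom]

    def positions(self, chrom: str) -> np.ndarray:
        return np.arange(1, self.chrom_lengths[chrom] + 1, self.spec.probe_spacing,
                         dtype=np.int64)

    @property
    def gene_by_id(self) -> dict[str, Gene]:
        return {g.gene_id: g for g in self.genes}


@dataclass
class ExpressionSet:
    """Stranded expression probe data for one chromosome and strand."""

    chrom: str
    strand: str
    positions: np.ndarray
    treatment: pd.DataFrame
    control: pd.DataFrame


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def build_genome(spec: GenomeSpec) -> Genome:
    """Place non-overlapping genes with promoter NDRs and phased nucleosome arrays.

    The +1 nucleosome center sits ceil(core_width/2) bp downstream of the TSS;
    consecutive centers are core_width + linker_length apart and are placed
    while the full core still fits inside the gene body. The NDR (ndr_width bp
    directly upstream of the TSS, strand-aware) contains no true centers.
    Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    repeat = spec.core_width + spec.linker_length
    half_core = spec.core_width // 2
    plus1_offset = (spec.core_width + 1) // 2
    min_gap = spec.ndr_width + 60

    genes: list[Gene] = []
    centers: dict[str, list[int]] = {}
    chrom_lengths = {f"chr{i + 1}": spec.chrom_length for i in range(spec.n_chromosomes)}
    remaining = spec.n_genes
    gi = 0
    for chrom, clen in chrom_lengths.items():
        cursor = 1
        while remaining > 0:
            gap = max(min_gap, int(round(rng.normal(spec.intergenic_length_mean,
                                                    0.2 * spec.intergenic_length_mean))))
            glen = max(spec.core_width + 30,
                       int(round(rng.normal(spec.gene_length_mean, 0.15 * spec.gene_length_mean))))
            if spec.strands is not None:
                strand = spec.strands[gi % len(spec.strands)]
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            body_start = cursor + gap
            body_end = body_start + glen - 1
            # keep the NDR of '-' genes (downstream in coordinates) on-chromosome
            if body_end + (spec.ndr_width if strand == "-" else 0) > clen - min_gap:
                break
            gi += 1
            gene_id = f"gene{gi:04d}"
            if strand == "+":
                gene = Gene(gene_id, chrom, "+", body_start, body_end)
            else:
                gene = Gene(gene_id, chrom, "-", body_end, body_start)
            genes.append(gene)
            d = gene.direction
            c = gene.tss + d * plus1_offset
            gcenters: list[int] = []
            while gene.start + half_core <= c <= gene.end - half_core + (spec.core_width % 2):
                # core [c-half, c+half] must fit the gene body
                if c - half_core < gene.start or c + half_core > gene.end:
                    break
                gcenters.append(int(c))
                c += d * repeat
            centers[gene_id] = gcenters
            cursor = body_end
            remaining -= 1
        if remaining == 0:
            break
    if remaining > 0:
        raise ValueError(
            f"chrom_length={spec.chrom_length} x n_chromosomes={spec.n_chromosomes} cannot "
            f"host n_genes={spec.n_genes} at the requested gene/intergenic lengths")
    return Genome(spec, chrom_lengths, genes, SyntheticTruth(true_centers=centers))


def perturbed_centers(genome: Genome, perturbation: PerturbationSpec | None) -> dict[str, list[int]]:
    """True centers after applying the shift map; errors name the offending gene/index."""
    if perturbation is None:
        return {g: list(c) for g, c in genome.truth.true_centers.items()}
    out: dict[str, list[int]] = {}
    gene_by_id = genome.gene_by_id
    for gene_id, gcenters in genome.truth.true_centers.items():
        shifts = perturbation.shift_map.get(gene_id, {})
        gene = gene_by_id[gene_id]
        moved = []
        for k, c in enumerate(gcenters, start=1):
            s = shifts.get(k, 0)
            nc = c + gene.direction * s
            if s != 0:
                if not 1 <= nc <= genome.chrom_lengths[gene.chrom]:
                    raise ValueError(f"shift pushes gene {gene_id} nucleosome +{k} off chromosome")
                if not gene.start <= nc <= gene.end:
                    raise ValueError(f"shift leaves gene {gene_id} nucleosome +{k} outside the gene span")
            moved.append(int(nc))
        out[gene_id] = moved
    return out


# ---------------------------------------------------------------------------
# occupancy simulation
# ---------------------------------------------------------------------------

def expected_occupancy_linear(genome: Genome, perturbation: PerturbationSpec | None,
                              chrom: str, background: float = 0.1) -> np.ndarray:
    """Noise-free expected linear occupancy on the probe grid of one chromosome.

    Each nucleosome deposits a triangular kernel of half-width core_width/2
    (unit height at the center); the per-probe signal is background plus the
    depletion-scaled kernel sum, then interval scale factors apply
    position-wise.
    """
    spec = genome.spec
    positions = genome.positions(chrom)
    signal = np.zeros(len(positions))
    half = spec.core_width / 2.0
    step = spec.probe_spacing
    centers = perturbed_centers(genome, perturbation)
    for gene in genome.genes_on(chrom):
        for c in centers[gene.gene_id]:
            i0 = max(0, math.ceil((c - half - 1) / step))
            i1 = min(len(positions) - 1, math.floor((c + half - 1) / step))
            if i1 < i0:
                continue
            window = positions[i0:i1 + 1]
            signal[i0:i1 + 1] += np.maximum(0.0, 1.0 - np.abs(window - c) / half)
    depletion = perturbation.global_histone_depletion if perturbation else 0.0
    total = background + (1.0 - depletion) * signal
    if perturbation:
        for pchrom, start, end, factor in perturbation.occupancy_scale_map:
            if pchrom != chrom:
                continue
            mask = (positions >= start) & (positions <= end)
            total[mask] *= factor
    return total


def simulate_occupancy(genome: Genome, perturbation: PerturbationSpec | None = None, *,
                       noise_sd: float = 0.2, n_replicates: int = 2, seed: int = 0,
                       background: float = 0.1, sample_prefix: str = "rep",
                       control_name: str | None = "gdna") -> dict[str, ProbeMatrix]:
    """Linear probe intensities per replicate, plus an optional flat gDNA control.

    Noise is multiplicative lognormal: intensity = expected * 2**N(0, noise_sd),
    i.e. iid additive Gaussian on the log2 scale per probe and replicate.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if perturbation:
        perturbation.validate()
    rng = np.random.default_rng(seed)
    out: dict[str, ProbeMatrix] = {}
    for chrom in genome.chrom_lengths:
        positions = genome.positions(chrom)
        expected = expected_occupancy_linear(genome, perturbation, chrom, background)
        cols: dict[str, np.ndarray] = {}
        for r in range(1, n_replicates + 1):
            noise = rng.normal(0.0, noise_sd, len(positions)) if noise_sd > 0 else 0.0
            cols[f"{sample_prefix}{r}"] = expected * np.exp2(noise)
        if control_name:
            noise = rng.normal(0.0, noise_sd, len(positions)) if noise_sd > 0 else 0.0
            cols[control_name] = np.exp2(noise)
        out[chrom] = ProbeMatrix(chrom, positions, pd.DataFrame(cols))
    return out


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(genome: Genome, perturbation: PerturbationSpec | None = None, *,
                        noise_sd: float = 0.2, n_replicates: int = 2, seed: int = 0,
                        background: float = 50.0, gene_level: float = 400.0,
                        ) -> list[ExpressionSet]:
    """Stranded expression intensities for treatment and control channels.

    Annotated genes are expressed on their own strand in both channels;
    planted cryptic transcripts multiply the treatment channel by their fold
    change on their stated strand/interval only.
    """
    if perturbation:
        perturbation.validate()
        for chrom, start, end, strand, fold in perturbation.cryptic_transcripts:
            if chrom not in genome.chrom_lengths:
                raise ValueError(f"cryptic transcript on unknown chromosome {chrom!r}")
            if start < 1 or end > genome.chrom_lengths[chrom]:
                raise ValueError(f"cryptic transcript {chrom}:{start}-{end} outside the chromosome")
    rng = np.random.default_rng(seed)
    out: list[ExpressionSet] = []
    for chrom in genome.chrom_lengths:
        positions = genome.positions(chrom)
        for strand in ("+", "-"):
            base = np.full(len(positions), background)
            for gene in genome.genes_on(chrom):
                if gene.strand == strand:
                    mask = (positions >= gene.start) & (positions <= gene.end)
                    base[mask] += gene_level
            treat = base.copy()
            if perturbation:
                for pchrom, start, end, pstrand, fold in perturbation.cryptic_transcripts:
                    if pchrom == chrom and pstrand == strand:
                        mask = (positions >= start) & (positions <= end)
                        treat[mask] *= fold
            tcols, ccols = {}, {}
            for r in range(1, n_replicates + 1):
                tn = rng.normal(0.0, noise_sd, len(positions)) if noise_sd > 0 else 0.0
                cn = rng.normal(0.0, noise_sd, len(positions)) if noise_sd > 0 else 0.0
                tcols[f"treat{r}"] = treat * np.exp2(tn)
                ccols[f"ctrl{r}"] = base * np.exp2(cn)
            out.append(ExpressionSet(chrom, strand, positions,
                                     pd.DataFrame(tcols), pd.DataFrame(ccols)))
    return out


# ---------------------------------------------------------------------------
# paired-end fragments
# ---------------------------------------------------------------------------

def simulate_readpairs(genome: Genome, perturbation: PerturbationSpec | None = None, *,
                       depth: float = 50.0, jitter_sd: float = 10.0,
                       frag_length: int = 147, seed: int = 0) -> pd.DataFrame:
    """Paired-end fragments per true nucleosome; midpoint = center + discretized
    Gaussian jitter, fragment length = frag_length. Sorted by coordinate."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    centers = perturbed_centers(genome, perturbation)
    rows = []
    half = frag_length // 2
    for gene in genome.genes:
        clen = genome.chrom_lengths[gene.chrom]
        for c in centers[gene.gene_id]:
            n = rng.poisson(depth)
            if n == 0:
                continue
            jitter = (np.rint(rng.normal(0.0, jitter_sd, n)).astype(np.int64)
                      if jitter_sd > 0 else np.zeros(n, dtype=np.int64))
            mids = np.clip(c + jitter, 1 + half, clen - (frag_length - 1 - half))
            starts = mids - half
            ends = starts + frag_length - 1
            for s, e in zip(starts, ends):
                rows.append((gene.chrom, int(s), int(e)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# full scenarios
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """A complete mutant-vs-WT study: genome, occupancy for the condition, a WT
    reference, a panel of independent WT conditions, stranded expression, truth."""

    genome: Genome
    perturbation: PerturbationSpec
    occ_wt: dict[str, ProbeMatrix]
    occ_cond: dict[str, ProbeMatrix]
    occ_panel: list[dict[str, ProbeMatrix]]
    expression: list[ExpressionSet]
    truth: SyntheticTruth


def simulate_scenario(spec: GenomeSpec, perturbation: PerturbationSpec | None = None, *,
                      noise_sd: float = 0.2, n_replicates: int = 2, n_panel: int = 8,
                      seed: int = 0) -> Scenario:
    """Simulate a full study: WT reference, perturbed condition, WT panel, expression."""
    perturbation = perturbation or PerturbationSpec()
    genome = build_genome(spec)
    seeds = np.random.SeedSequence(seed).generate_state(3 + n_panel) % (2 ** 31)
    occ_wt = simulate_occupancy(genome, None, noise_sd=noise_sd,
                                n_replicates=n_replicates, seed=int(seeds[0]))
    occ_cond = simulate_occupancy(genome, perturbation, noise_sd=noise_sd,
                                  n_replicates=n_replicates, seed=int(seeds[1]))
    occ_panel = [simulate_occupancy(genome, None, noise_sd=noise_sd, n_replicates=1,
                                    seed=int(seeds[3 + i]), sample_prefix="panel")
                 for i in range(n_panel)]
    expression = simulate_expression(genome, perturbation, noise_sd=noise_sd,
                                     n_replicates=n_replicates, seed=int(seeds[2]))
    truth = SyntheticTruth(
        true_centers=perturbed_centers(genome, perturbation),
        true_transfrags=list(perturbation.cryptic_transcripts),
        true_signature_loci=[(c, s, e, st) for c, s, e, st, _ in perturbation.cryptic_transcripts],
    )
    return Scenario(genome, perturbation, occ_wt, occ_cond, occ_panel, expression, truth)


# ---------------------------------------------------------------------------
# file output (all coordinates converted at the boundary: BED family is
# 0-based half-open; TSV/GFF3 stay 1-based closed)
# ---------------------------------------------------------------------------

def write_probe_table(matrix: ProbeMatrix, path: str | Path) -> None:
    df = matrix.data.copy()
    df.insert(0, "strand", matrix.strand)
    df.insert(0, "pos", matrix.positions)
    df.insert(0, "chrom", matrix.chrom)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_probe_table(path: str | Path) -> ProbeMatrix:
    df = pd.read_csv(path, sep="\t")
    strand = str(df["strand"].iloc[0]) if len(df) else "."
    return ProbeMatrix(str(df["chrom"].iloc[0]), df["pos"].to_numpy(np.int64),
                       df.drop(columns=["chrom", "pos", "strand"]), strand)


def write_bedgraph(track, path: str | Path) -> None:
    step = track.step
    with open(path, "w") as fh:
        for pos, val in zip(track.positions, track.values):
            fh.write(f"{track.chrom}\t{pos - 1}\t{pos - 1 + step}\t{val:.6g}\n")


def write_bed6(intervals: list[tuple[str, int, int, str, float, str]], path: str | Path) -> None:
    """intervals: (chrom, start, end, name, score, strand), 1-based closed in."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\t{score:g}\t{strand}\n")


def write_bedpe(pairs: pd.DataFrame, path: str | Path) -> None:
    """Each fragment written as a read pair (two 36-nt mates at the fragment ends)."""
    read = 36
    with open(path, "w") as fh:
        for i, row in enumerate(pairs.itertuples(index=False)):
            s, e = int(row.start), int(row.end)
            fh.write(f"{row.chrom}\t{s - 1}\t{min(e, s - 1 + read)}\t"
                     f"{row.chrom}\t{max(s - 1, e - read)}\t{e}\tpair{i}\t0\t+\t-\n")


def read_bedpe(path: str | Path) -> pd.DataFrame:
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
            "name", "score", "strand1", "strand2"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    return pd.DataFrame({"chrom": df["chrom1"],
                         "start": df["start1"] + 1,
                         "end": df["end2"]})


def write_gff3(genes: list[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tnucshift\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")


def read_gff3(path: str | Path) -> list[Gene]:
    genes: list[Gene] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = line.rstrip("\n").split("\t")
            if ftype != "gene":
                continue
            gid = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv).get("ID", "")
            start, end = int(start), int(end)
            tss, tes = (start, end) if strand == "+" else (end, start)
            genes.append(Gene(gid, chrom, strand, tss, tes))
    return genes


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"true_centers": truth.true_centers,
                   "true_transfrags": truth.true_transfrags,
                   "true_signature_loci": truth.true_signature_loci}, fh, indent=1)


def write_scenario(scenario: Scenario, outdir: str | Path) -> list[Path]:
    """Write a scenario as plain-text files consumed by the pipeline runner."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path) -> Path:
        written.append(path)
        return path

    for chrom in scenario.genome.chrom_lengths:
        wt, cond = scenario.occ_wt[chrom], scenario.occ_cond[chrom]
        data = {f"wt_{c}": wt.data[c] for c in wt.data if c != "gdna"}
        data.update({f"cond_{c}": cond.data[c] for c in cond.data if c != "gdna"})
        for i, panel in enumerate(scenario.occ_panel, 1):
            data[f"panel_{i}"] = panel[chrom].data["panel1"]
        data["gdna"] = wt.data["gdna"]
        merged = ProbeMatrix(chrom, wt.positions, pd.DataFrame(data))
        write_probe_table(merged, emit(outdir / f"occupancy_{chrom}.tsv"))
    for es in scenario.expression:
        tag = "plus" if es.strand == "+" else "minus"
        df = pd.concat([es.treatment, es.control], axis=1)
        matrix = ProbeMatrix(es.chrom, es.positions, df, es.strand)
        write_probe_table(matrix, emit(outdir / f"expression_{es.chrom}_{tag}.tsv"))
    write_gff3(scenario.genome.genes, emit(outdir / "genes.gff3"))
    write_truth_json(scenario.truth, emit(outdir / "truth.json"))
    with open(emit(outdir / "chrom_sizes.tsv"), "w") as fh:
        for chrom, clen in scenario.genome.chrom_lengths.items():
            fh.write(f"{chrom}\t{clen}\n")
    return written
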