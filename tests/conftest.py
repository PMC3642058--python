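"""Shared fixtures and helpers: small synthetic genomes and the standard
preprocess -> call chain used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

import nucshift as ns


def mean_occupancy_track(matrix, sample_cols):
    """Preprocess MNase sample columns and return the replicate-mean log2 track."""
    tracks = ns.preprocess_occupancy(matrix, sample_cols, "gdna")
    values = np.mean([tracks[c].values for c in sample_cols], axis=0)
    return ns.OccupancyTrack(matrix.chrom, matrix.positions, values)


def call_chain(track, fraction=0.10):
    """Gaussian score -> sequential calling -> low-score exclusion at defaults."""
    score = ns.gaussian_score(track)
    return ns.filter_low_scores(ns.call_positions(score), fraction)


def genic_calls_for(genome, matrix, sample_cols):
    calls = call_chain(mean_occupancy_track(matrix, sample_cols))
    return ns.assign_genic(calls, genome.genes)


@pytest.fixture(scope="session")
def small_genome():
    """10 genes on one 60-kb chromosome, default yeast-like geometry."""
    return ns.build_genome(ns.GenomeSpec(chrom_length=60_000, n_genes=10, seed=1))


@pytest.fixture(scope="session")
def noisefree_occupancy(small_genome):
    return ns.simulate_occupancy(small_genome, None, noise_sd=0.0,
                                 n_replicates=1, seed=2)["chr1"]
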