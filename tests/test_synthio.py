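"""Generator geometry, determinism and planted-perturbation semantics."""

import numpy as np
import pandas as pd
import pytest

import nucshift as ns
from nucshift.synthio import expected_occupancy_linear, perturbed_centers


class TestBuildGenome:
    def test_consecutive_centers_repeat_length_apart(self, small_genome):
        for centers in small_genome.truth.true_centers.values():
            if len(centers) > 1:
                assert set(np.abs(np.diff(centers))) == {165}  # 147 + 18

    def test_nucleosome_count_matches_arithmetic(self):
        # a 3000-bp gene hosts floor((3000-147)/165)+1 = 18 whole cores
        spec = ns.GenomeSpec(chrom_length=40_000, n_genes=1, gene_length_mean=3000, seed=0)
        genome = ns.build_genome(spec)
        gene = genome.genes[0]
        centers = genome.truth.true_centers[gene.gene_id]
        if gene.length == 3000:
            assert len(centers) == 18
        else:  # length is drawn around the mean; fall back to the formula
            assert len(centers) == (gene.length - 147) // 165 + 1

    def test_same_seed_identical_genomes(self):
        spec = ns.GenomeSpec(chrom_length=50_000, n_genes=8, seed=11)
        a, b = ns.build_genome(spec), ns.build_genome(spec)
        assert a.genes == b.genes
        assert a.truth.true_centers == b.truth.true_centers

    def test_ndr_contains_no_centers_and_truth_inside_genome(self, small_genome):
        for gene in small_genome.genes:
            lo, hi = ns.ndr_window(gene)
            for c in small_genome.truth.true_centers[gene.gene_id]:
                assert not lo <= c <= hi
                assert gene.start <= c <= gene.end
                assert 1 <= c <= small_genome.chrom_lengths[gene.chrom]

    def test_plus_one_center_half_core_downstream_of_tss(self, small_genome):
        for gene in small_genome.genes:
            centers = small_genome.truth.true_centers[gene.gene_id]
            assert centers[0] == gene.tss + gene.direction * 74

    def test_infeasible_geometry_names_parameter(self):
        with pytest.raises(ValueError, match="gene_length_mean"):
            ns.build_genome(ns.GenomeSpec(gene_length_mean=100))
        with pytest.raises(ValueError, match="probe_spacing"):
            ns.build_genome(ns.GenomeSpec(chrom_length=100_001))
        with pytest.raises(ValueError, match="n_genes"):
            ns.build_genome(ns.GenomeSpec(chrom_length=20_000, n_genes=500))


class TestSimulateOccupancy:
    def test_noisefree_argmax_at_true_centers(self, small_genome, noisefree_occupancy):
        values = noisefree_occupancy.data["rep1"].to_numpy()
        positions = noisefree_occupancy.positions
        for centers in small_genome.truth.true_centers.values():
            for c in centers:
                mask = np.abs(positions - c) <= 60
                peak = positions[mask][np.argmax(values[mask])]
                assert abs(peak - c) <= 2  # within half a probe step

    def test_shift_moves_noisefree_argmax(self, small_genome):
        gene = small_genome.genes[0]
        pert = ns.PerturbationSpec(shift_map={gene.gene_id: {1: 16}})
        occ = ns.simulate_occupancy(small_genome, pert, noise_sd=0.0, n_replicates=1, seed=0)["chr1"]
        base = ns.simulate_occupancy(small_genome, None, noise_sd=0.0, n_replicates=1, seed=0)["chr1"]
        c = small_genome.truth.true_centers[gene.gene_id][0]
        mask = np.abs(occ.positions - c) <= 80
        before = occ.positions[mask][np.argmax(base.data["rep1"].to_numpy()[mask])]
        after = occ.positions[mask][np.argmax(occ.data["rep1"].to_numpy()[mask])]
        assert after - before == 16 * gene.direction

    def test_scale_factor_half_drops_one_log2_unit(self, small_genome):
        gene = small_genome.genes[0]
        interval = (gene.start, gene.start + 400)
        pert = ns.PerturbationSpec(occupancy_scale_map=[("chr1", *interval, 0.5)])
        base = expected_occupancy_linear(small_genome, None, "chr1")
        scaled = expected_occupancy_linear(small_genome, pert, "chr1")
        positions = small_genome.positions("chr1")
        mask = (positions >= interval[0]) & (positions <= interval[1])
        diff = np.log2(scaled[mask]) - np.log2(base[mask])
        assert np.allclose(diff, -1.0)
        assert np.allclose(scaled[~mask], base[~mask])

    def test_scale_monotone_in_factor(self, small_genome):
        positions = small_genome.positions("chr1")
        mask = (positions >= 5000) & (positions <= 6000)
        lo = expected_occupancy_linear(
            small_genome, ns.PerturbationSpec(occupancy_scale_map=[("chr1", 5000, 6000, 0.5)]), "chr1")
        hi = expected_occupancy_linear(
            small_genome, ns.PerturbationSpec(occupancy_scale_map=[("chr1", 5000, 6000, 0.8)]), "chr1")
        assert np.all(hi[mask] >= lo[mask])

    def test_off_gene_shift_rejected_with_gene_and_index(self, small_genome):
        gene = small_genome.genes[0]
        pert = ns.PerturbationSpec(shift_map={gene.gene_id: {1: -5000}})
        with pytest.raises(ValueError, match=f"{gene.gene_id}.*\\+1"):
            perturbed_centers(small_genome, pert)

    def test_determinism(self, small_genome):
        a = ns.simulate_occupancy(small_genome, None, noise_sd=0.3, seed=9)["chr1"]
        b = ns.simulate_occupancy(small_genome, None, noise_sd=0.3, seed=9)["chr1"]
        pd.testing.assert_frame_equal(a.data, b.data)


class TestSimulateExpression:
    def test_cryptic_fold_only_on_its_strand(self, small_genome):
        gene = next(g for g in small_genome.genes if g.strand == "+")
        interval = (gene.start + 100, gene.start + 500)
        pert = ns.PerturbationSpec(cryptic_transcripts=[("chr1", *interval, "-", 4.0)])
        sets = {es.strand: es for es in
                ns.simulate_expression(small_genome, pert, noise_sd=0.0, n_replicates=1, seed=0)}
        for strand, expected in (("-", 2.0), ("+", 0.0)):
            es = sets[strand]
            mask = (es.positions >= interval[0]) & (es.positions <= interval[1])
            diff = np.log2(es.treatment.to_numpy()[mask, 0] / es.control.to_numpy()[mask, 0])
            assert np.allclose(diff, expected)

    def test_no_cryptics_means_identical_channels(self, small_genome):
        for es in ns.simulate_expression(small_genome, None, noise_sd=0.0, n_replicates=1, seed=0):
            assert np.allclose(es.treatment.to_numpy()[:, 0], es.control.to_numpy()[:, 0])

    def test_cryptic_outside_chromosome_rejected(self, small_genome):
        pert = ns.PerturbationSpec(cryptic_transcripts=[("chr1", 59_000, 70_000, "+", 4.0)])
        with pytest.raises(ValueError, match="outside"):
            ns.simulate_expression(small_genome, pert, seed=0)


class TestSimulateReadpairs:
    def test_zero_jitter_midpoints_equal_true_centers(self, small_genome):
        pairs = ns.simulate_readpairs(small_genome, jitter_sd=0, depth=5, seed=3)
        mids = set(((pairs["start"] + pairs["end"]) // 2).tolist())
        truth = {c for centers in small_genome.truth.true_centers.values() for c in centers}
        assert mids <= truth

    def test_histogram_modes_recover_centers(self, small_genome):
        pairs = ns.simulate_readpairs(small_genome, depth=50, jitter_sd=10, seed=4)
        mids = ((pairs["start"] + pairs["end"]) // 2).to_numpy()
        hits = total = 0
        grid = np.arange(-40, 41)
        for centers in small_genome.truth.true_centers.values():
            for c in centers:
                local = mids[np.abs(mids - c) <= 60] - c
                # kernel-smoothed midpoint histogram; mode estimates the center
                density = np.exp(-0.5 * ((grid[:, None] - local[None, :]) / 8.0) ** 2).sum(axis=1)
                mode = grid[np.argmax(density)] + c
                total += 1
                hits += abs(mode - c) <= 5
        assert hits / total >= 0.95

    def test_output_sorted(self, small_genome):
        pairs = ns.simulate_readpairs(small_genome, depth=10, seed=6)
        assert (pairs["start"].diff().dropna() >= 0).all()


class TestRoundTrips:
    def test_probe_table_round_trip(self, tmp_path, noisefree_occupancy):
        path = tmp_path / "probes.tsv"
        ns.synthio.write_probe_table(noisefree_occupancy, path)
        back = ns.synthio.read_probe_table(path)
        assert np.array_equal(back.positions, noisefree_occupancy.positions)
        assert np.allclose(back.data.to_numpy(), noisefree_occupancy.data.to_numpy(),
                           rtol=1e-5)

    def test_gff3_round_trip(self, tmp_path, small_genome):
        path = tmp_path / "genes.gff3"
        ns.synthio.write_gff3(small_genome.genes, path)
        assert ns.synthio.read_gff3(path) == small_genome.genes

    def test_bedpe_round_trip_preserves_fragments(self, tmp_path, small_genome):
        pairs = ns.simulate_readpairs(small_genome, depth=3, seed=8)
        path = tmp_path / "frags.bedpe"
        ns.synthio.write_bedpe(pairs, path)
        back = ns.synthio.read_bedpe(path)
        assert np.array_equal(back["start"].to_numpy(), pairs["start"].to_numpy())
        assert np.array_equal(back["end"].to_numpy(), pairs["end"].to_numpy())
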