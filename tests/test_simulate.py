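"""Synthetic-data generator: determinism, packing, signal shape, truth."""

import io as stdio

import numpy as np
import pytest

from tespread import io as tio
from tespread import pipeline, simulate as sim


def small_config(**kw):
    defaults = dict(genome_length=1_000_000, n_tes=10, n_genes=10, seed=1)
    defaults.update(kw)
    return sim.SimulationConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"genome_length": 0},
            {"spread_amplitude": -1},
            {"decay_length": 0},
            {"genic_restraint_factor": 0},
            {"genic_restraint_factor": 1.5},
            {"mean_input_coverage": 0},
            {"spikein_ratio": -2},
        ],
    )
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)


class TestGenerateAnnotations:
    def test_empty_te_set(self):
        tes, genes, _ = sim.generate_annotations(small_config(n_tes=0, n_genes=7))
        assert tes == [] and len(genes) == 7

    def test_determinism_identical_files(self, tmp_path):
        """Same seed and config produce byte-identical annotation files."""
        outputs = []
        for run in range(2):
            cfg = small_config(seed=99)
            tes, genes, bounds = sim.generate_annotations(cfg)
            buf = stdio.StringIO()
            for t in tes:
                buf.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.te_id}\t{t.family}\n")
            for g in genes:
                buf.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t{g.rpkm_rep1}\n")
            outputs.append(buf.getvalue())
        assert outputs[0] == outputs[1]

    def test_50_tes_on_1mb_non_overlapping(self):
        cfg = small_config(n_tes=50, n_genes=0, te_length_range=(500, 5000), seed=7)
        tes, _, _ = sim.generate_annotations(cfg)
        assert len(tes) == 50
        # brute-force interval sweep
        ivs = sorted((t.start, t.end) for t in tes)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2
        assert all(0 <= s < e <= cfg.genome_length for s, e in ivs)

    def test_infeasible_packing_rejected(self):
        with pytest.raises(sim.CapacityError):
            sim.generate_annotations(
                small_config(genome_length=10_000, n_tes=50, te_length_range=(500, 5000))
            )

    def test_multi_chromosome_layout(self):
        cfg = small_config(n_chromosomes=3, n_tes=9, n_genes=9)
        tes, genes, bounds = sim.generate_annotations(cfg)
        assert {t.chrom for t in tes} <= {"chr1", "chr2", "chr3"}
        assert len(bounds) == 3


class TestSimulateCoverage:
    def test_no_signal_mean_near_background(self):
        cfg = small_config(n_tes=5, n_genes=0, spread_amplitude=0.0,
                           mean_input_coverage=50, seed=3)
        tes, genes, _ = sim.generate_annotations(cfg)
        cov = sim.simulate_coverage(tes, genes, cfg)
        tracks = pipeline.hmd_tracks_from_coverage(cov)
        vals = tracks["chr1"].values[~tracks["chr1"].missing]
        assert vals.mean() == pytest.approx(1.0, abs=0.05)

    def test_first_flank_closed_form_mean(self):
        """Deep coverage, A=2, lambda=2 kb: mean HMD over the first 1-kb
        flank approaches 1 + A*(lambda/1kb)*(1 - exp(-1kb/lambda)) ~ 2.574."""
        cfg = small_config(
            genome_length=2_000_000, n_tes=20, n_genes=0, spread_amplitude=2.0,
            amplitude_cv=0.0, decay_length=2000, mean_input_coverage=500,
            min_gap=50_000, mean_barcode_fragments=1e6, seed=5,
        )
        tes, genes, _ = sim.generate_annotations(cfg)
        cov = sim.simulate_coverage(tes, genes, cfg, amplitudes=np.full(20, 2.0))
        tracks = pipeline.hmd_tracks_from_coverage(cov)
        track = tracks["chr1"]
        flank_means = []
        for te in tes:
            for lo, hi in [(te.start // 25 - 40, te.start // 25), (te.end // 25, te.end // 25 + 40)]:
                vals = track.valid_values(lo, hi)
                if len(vals):
                    flank_means.append(vals.mean())
        closed_form = 1 + 2 * 2 * (1 - np.exp(-0.5))
        assert np.mean(flank_means) == pytest.approx(closed_form, rel=0.03)

    def test_spikein_counts_track_ratio(self):
        cfg = small_config(spikein_ratio=4.0, mean_barcode_fragments=10_000, seed=2)
        tes, genes, _ = sim.generate_annotations(cfg)
        cov = sim.simulate_coverage(tes, genes, cfg)
        assert cov.chip_barcode / cov.input_barcode == pytest.approx(4.0, rel=0.1)

    def test_coverage_determinism(self):
        cfg = small_config(seed=8)
        tes, genes, _ = sim.generate_annotations(cfg)
        c1 = sim.simulate_coverage(tes, genes, cfg)
        c2 = sim.simulate_coverage(tes, genes, cfg)
        assert np.array_equal(c1.chip["chr1"], c2.chip["chr1"])
        assert np.array_equal(c1.input["chr1"], c2.input["chr1"])

    def test_replicates_differ(self):
        cfg = small_config(seed=8)
        tes, genes, _ = sim.generate_annotations(cfg)
        c1 = sim.simulate_coverage(tes, genes, cfg, replicate=1)
        c2 = sim.simulate_coverage(tes, genes, cfg, replicate=2)
        assert not np.array_equal(c1.chip["chr1"], c2.chip["chr1"])


class TestGenicRestraint:
    def test_genic_side_decays_faster(self):
        """With a busy promoter nearby, the expected profile on the genic
        side sits below the intergenic side at matched distances."""
        from tespread.annotation import TeRecord
        from tespread.genes import GeneRecord

        cfg = small_config(genic_restraint_factor=0.2, n_tes=1, n_genes=0)
        te = TeRecord("te1", "chr1", 500_000, 502_000)
        gene = GeneRecord("g1", "chr1", 505_000, 508_000, strand="+",
                          rpkm_rep1=50.0, rpkm_rep2=50.0, rpkm_mean=50.0)
        eh = sim.expected_hmd([te], [gene], cfg, amplitudes=np.array([2.0]))["chr1"]
        d_bins = 60  # 1.5 kb out
        left = eh[te.start // 25 - d_bins]
        right = eh[te.end // 25 + d_bins - 1]
        assert right < left

    def test_estimated_extent_shorter_on_genic_side(self):
        """Monte-Carlo over >=100 TEs: estimated genic-side extent is
        shorter than intergenic-side extent in expectation."""
        from tespread.annotation import TeRecord
        from tespread.genes import GeneRecord
        from tespread import effects as fx, hmd as hm

        cfg = sim.SimulationConfig(
            genome_length=100_000 * 110, n_tes=0, n_genes=0,
            spread_amplitude=2.0, amplitude_cv=0.0, decay_length=2000,
            genic_restraint_factor=0.2, mean_input_coverage=100, seed=21,
        )
        tes, genes = [], []
        for i in range(110):
            base = i * 100_000 + 45_000
            tes.append(TeRecord(f"te{i}", "chr1", base, base + 2000))
            genes.append(
                GeneRecord(f"g{i}", "chr1", base + 4000, base + 7000, strand="+",
                           rpkm_mean=50.0)
            )
        cov = sim.simulate_coverage(tes, genes, cfg, amplitudes=np.full(110, 2.0))
        tracks = pipeline.hmd_tracks_from_coverage(cov)
        left, right = [], []
        for te in tes:
            eff = fx.te_effect(tracks["chr1"], te)
            if eff.extent_left is not None and eff.extent_right is not None:
                left.append(eff.extent_left)    # intergenic side
                right.append(eff.extent_right)  # faces the busy promoter
        assert len(left) >= 100
        assert np.mean(right) < np.mean(left)


class TestPopulationEvidence:
    def test_all_strains_carry_all_present(self):
        cfg = small_config(high_frequency_fraction=1.0, presence_prob=1.0, seed=6)
        tes, _, _ = sim.generate_annotations(cfg)
        from tespread import popfreq as pf

        evidence, truth = sim.simulate_population(tes, cfg)
        for te in tes:
            for alns in evidence[te.te_id].values():
                assert pf.call_te_state(alns, te.start, te.end)[0] == pf.PRESENT

    def test_singleton_classed_low(self):
        cfg = small_config(high_frequency_fraction=0.0, seed=6)
        tes, _, _ = sim.generate_annotations(cfg)
        from tespread import popfreq as pf

        evidence, truth = sim.simulate_population(tes, cfg)
        for te in tes:
            calls = [
                pf.PopulationCall(te.te_id, s, pf.call_te_state(a, te.start, te.end)[0])
                for s, a in evidence[te.te_id].items()
            ]
            assert pf.classify_frequency(calls) == pf.LOW


class TestTruth:
    def test_every_te_has_truth_entry(self):
        cfg = small_config(seed=12)
        tes, genes, _ = sim.generate_annotations(cfg)
        truth = sim.build_truth(tes, genes, cfg)
        assert set(truth.te_table.index) == {t.te_id for t in tes}
        assert set(truth.gene_table.index) == {g.gene_id for g in genes}

    def test_true_magnitude_closed_form_no_restraint(self):
        from tespread.annotation import TeRecord

        cfg = small_config(decay_length=2000, genic_restraint_factor=1.0)
        te = TeRecord("t", "chr1", 500_000, 501_000)
        # median of 1 + A exp(-d/lambda) over bin centers = value at d=500
        got = sim.true_magnitude(te, [], cfg, amplitude=2.0)
        assert got == pytest.approx(1 + 2 * np.exp(-500 / 2000), rel=1e-3)

    def test_bedgraph_roundtrip_byte_identical(self, tmp_path):
        """Writing the same simulated track twice is byte-identical."""
        cfg = small_config(seed=31)
        tes, genes, _ = sim.generate_annotations(cfg)
        paths = []
        for run in range(2):
            cov = sim.simulate_coverage(tes, genes, cfg)
            df = tio.bins_to_bedgraph(cov.chip["chr1"], "chr1", cfg.bin_size)
            p = tmp_path / f"run{run}.bedGraph"
            tio.write_bedgraph(df, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]
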