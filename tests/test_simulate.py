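"""Generator contracts: determinism, ground-truth structure, read anatomy."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from apakit._util import revcomp
from apakit.motif import scan_flank, extract_flank
from apakit.simulate import (
    SimulationConfig,
    SizingError,
    TruthTable,
    build_toy_genome,
    draw_pas_counts,
    plan_truth,
    simulate_sample_reads,
    write_fixture_bundle,
)


class TestConfig:
    def test_fractions_validated(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, frac_low_mapq=1.5)

    def test_tail_probs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, tail_probs=(0.5, 0.2))

    def test_roundtrip_through_dict(self):
        cfg = SimulationConfig(seed=9, n_genes=3)
        again = SimulationConfig.from_dict(cfg.to_dict())
        assert again == cfg


class TestGenome:
    def test_single_gene_config_forces_multiple_pas(self):
        cfg = SimulationConfig(seed=7, n_genes=1)
        assets = build_toy_genome(cfg)
        assert len(assets.annotation) == 1
        assert len(assets.annotation[0].pas_list) >= 2

    def test_deterministic_per_seed(self):
        cfg = SimulationConfig(seed=7, n_genes=4)
        a = build_toy_genome(cfg)
        b = build_toy_genome(cfg)
        assert a.contigs == b.contigs
        assert a.annotation_frame().equals(b.annotation_frame())

    def test_too_small_contig_raises_sizing_error(self):
        with pytest.raises(SizingError):
            build_toy_genome(SimulationConfig(seed=1, n_genes=10, contig_length=500))

    def test_genes_do_not_overlap(self):
        assets = build_toy_genome(SimulationConfig(seed=5, n_genes=20))
        spans = sorted(g.gene_span for g in assets.annotation)
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            assert e0 <= s1

    def test_flanking_window_inside_contig(self, small_assets):
        length = len(small_assets.contigs["chr1"])
        for gene in small_assets.annotation:
            for pas in gene.pas_list:
                assert 100 <= pas.position < length - 100

    def test_planted_motif_fraction_one_gives_consensus_in_window(self):
        # Every flagged PAS must carry at least one exact consensus 7-mer
        # in its -100..-41 upstream window, verified with the motif module.
        cfg = SimulationConfig(seed=13, n_genes=8, planted_motif_fraction=1.0)
        assets = build_toy_genome(cfg)
        consensus = cfg.pfm.consensus
        top = 7 * float(np.max(cfg.pfm.freqs) * cfg.pfm.information_content[0])
        for gene in assets.annotation:
            for pas in gene.pas_list:
                assert pas.motif_planted
                flank = extract_flank(assets, gene.contig, pas.position, gene.strand)
                offsets, scores = scan_flank(flank, cfg.pfm)
                window = (offsets >= -100) & (offsets <= -47)
                best = scores[window].max()
                assert best == pytest.approx(top)


class TestTruth:
    def test_usage_sums_to_one_per_condition(self, small_truth):
        small_truth.validate()

    def test_zero_shift_keeps_conditions_identical(self):
        cfg = SimulationConfig(seed=5, n_genes=10, planted_shift_log2=0.0)
        truth = plan_truth(build_toy_genome(cfg), cfg)
        assert np.allclose(truth.pas["usage_ctrl"], truth.pas["usage_kd"])
        assert (truth.genes["planted_direction"] == "none").all()

    def test_worked_shift_example(self):
        # usage (0.5, 0.5) with a -1 log2 distal shift renormalises to
        # (2/3, 1/3).
        shifted = np.array([0.5, 0.5 * 2.0 ** -1])
        shifted /= shifted.sum()
        assert np.allclose(shifted, [2 / 3, 1 / 3])
        cfg = SimulationConfig(
            seed=2,
            n_genes=6,
            n_pas_per_gene={2: 1.0},
            planted_shift_fraction=1.0,
            planted_shift_log2=-1.0,
        )
        truth = plan_truth(build_toy_genome(cfg), cfg)
        for gid, grp in truth.pas.groupby("gene_id"):
            grp = grp.sort_values("pas_index")
            expect = grp["usage_ctrl"].to_numpy().copy()
            expect[-1] *= 0.5
            expect /= expect.sum()
            assert np.allclose(grp["usage_kd"], expect)

    def test_exact_planted_count(self):
        cfg = SimulationConfig(seed=4, n_genes=100, planted_shift_fraction=0.3)
        truth = plan_truth(build_toy_genome(cfg), cfg)
        assert (truth.genes["planted_direction"] != "none").sum() == 30

    def test_frame_roundtrip(self, small_truth):
        frame = small_truth.to_frame()
        again = TruthTable.from_frame(frame, small_truth.conditions)
        pd.testing.assert_frame_equal(
            again.pas.reset_index(drop=True),
            small_truth.pas.reset_index(drop=True),
            check_like=True,
        )


class TestReads:
    def test_exact_read_count_and_determinism(self, small_assets, small_truth, small_config):
        a = simulate_sample_reads(small_assets, small_truth, "ctrl", 1000, 5, small_config)
        b = simulate_sample_reads(small_assets, small_truth, "ctrl", 1000, 5, small_config)
        assert len(a) == 1000 and a == b

    def test_unknown_condition_rejected(self, small_assets, small_truth, small_config):
        with pytest.raises(ValueError):
            simulate_sample_reads(small_assets, small_truth, "mock", 10, 5, small_config)

    def test_tailless_configuration_yields_no_pass_reads(self, small_assets, small_truth):
        cfg = SimulationConfig(
            seed=3, n_genes=30, tail_probs=(1.0,),
        )
        reads = simulate_sample_reads(small_assets, small_truth, "ctrl", 500, 5, cfg)
        assert all(r.tail_len == 0 for r in reads)
        assert not any(r.qualifies_pass for r in reads)

    def test_usage_proportions_respected(self, small_assets, small_truth, small_config):
        # Chi-square goodness of fit of PAS draws for the deepest gene at
        # 10,000 reads.
        reads = simulate_sample_reads(
            small_assets, small_truth, "ctrl", 10_000, 17, small_config
        )
        counts = pd.DataFrame(
            [(r.gene_id, r.pas_index) for r in reads], columns=["gene", "pas"]
        )
        gene = counts["gene"].value_counts().idxmax()
        observed = counts[counts["gene"] == gene]["pas"].value_counts().sort_index()
        usage = (
            small_truth.pas[small_truth.pas["gene_id"] == gene]
            .sort_values("pas_index")["usage_ctrl"]
            .to_numpy()
        )
        obs = np.zeros(len(usage))
        obs[observed.index.to_numpy()] = observed.to_numpy()
        _, p = chisquare(obs, usage * obs.sum())
        assert p > 0.001

    def test_read_anatomy_tail_adjacent_to_cleavage(self, small_assets, small_reads):
        # For every simulated read the soft-clipped stretch sits genomically
        # adjacent to the cleavage end and reverse-complements to poly(A).
        contig = small_assets.contigs["chr1"]
        for read in small_reads["ctrl_rep1"][:500]:
            if read.tail_len == 0:
                continue
            if read.pas_strand == "+":
                assert read.cigar.endswith(f"M{read.tail_len}S")
                clip = read.seq[-read.tail_len:]
                assert clip == "A" * read.tail_len  # SAM orientation
                aligned_end = read.seq[: -read.tail_len][-1]
                assert aligned_end == contig[read.cleavage_pos]
            else:
                assert read.cigar.startswith(f"{read.tail_len}S")
                clip = read.seq[: read.tail_len]
                assert revcomp(clip) == "A" * read.tail_len
                assert read.seq[read.tail_len] == contig[read.cleavage_pos]

    def test_gene_draw_follows_binomial_error(self, small_assets, small_truth, small_config):
        # A two-PAS gene with known usage: observed fraction within three
        # binomial standard deviations.
        reads = simulate_sample_reads(
            small_assets, small_truth, "ctrl", 10_000, 23, small_config
        )
        frame = pd.DataFrame([(r.gene_id, r.pas_index) for r in reads],
                             columns=["gene", "pas"])
        gene = frame["gene"].value_counts().idxmax()
        usage = (
            small_truth.pas[small_truth.pas["gene_id"] == gene]
            .sort_values("pas_index")["usage_ctrl"].to_numpy()
        )
        sub = frame[frame["gene"] == gene]
        n = len(sub)
        p0 = usage[0]
        observed = (sub["pas"] == 0).mean()
        assert abs(observed - p0) <= 3 * np.sqrt(p0 * (1 - p0) / n)


class TestBundle:
    def test_minimal_bundle_manifest(self, tmp_path):
        cfg = SimulationConfig(
            seed=1, n_genes=1, samples=(("only", "ctrl", 50),), conditions=("ctrl",)
        )
        assets = build_toy_genome(cfg)
        truth = plan_truth(assets, cfg)
        reads = simulate_sample_reads(assets, truth, "ctrl", 50, 9, cfg)
        manifest = write_fixture_bundle(assets, truth, {"only": reads}, tmp_path, cfg)
        assert sorted(manifest) == [
            "annotation.tsv",
            "config.yaml",
            "genome.fa",
            "reads_only.sam",
            "truth.tsv",
        ]

    def test_rerun_identical_checksums(self, tmp_path, small_config, small_assets,
                                       small_truth, small_reads):
        m1 = write_fixture_bundle(
            small_assets, small_truth, small_reads, tmp_path / "a", small_config
        )
        m2 = write_fixture_bundle(
            small_assets, small_truth, small_reads, tmp_path / "b", small_config
        )
        assert m1 == m2

    def test_sam_validates_against_header(self, small_bundle):
        import pysam

        out, _ = small_bundle
        with pysam.AlignmentFile(str(out / "reads_ctrl_rep1.sam"), "r") as handle:
            lengths = dict(zip(handle.references, handle.lengths))
            n = 0
            for aln in handle:
                assert aln.reference_end <= lengths[aln.reference_name]
                n += 1
        assert n == 8000

    def test_manifest_written_to_disk(self, small_bundle):
        out, manifest = small_bundle
        on_disk = json.loads((out / "manifest.json").read_text())
        assert on_disk == manifest


class TestCountsLevelDraw:
    def test_fixed_depth_per_gene(self, small_truth):
        counts = draw_pas_counts(small_truth, 100, seed=3)
        per_gene = counts.groupby("gene_id")[["count_ctrl", "count_kd"]].sum()
        assert (per_gene == 100).all().all()
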