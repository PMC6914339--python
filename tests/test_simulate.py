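"""The synthetic-data generator: planted truth, determinism, conservation."""

import filecmp

import numpy as np
import pytest

from seedreg.imprinting import CROSS_2X, imprinting_thresholds
from seedreg.motifs import scan_consensus
from seedreg.peaks import common_peaks
from seedreg.simulate import (
    SimulationConfig,
    planted_fraction,
    simulate_annotation,
    simulate_bundle,
    simulate_peaks,
    write_bundle,
)


class TestConfig:
    def test_fraction_bounds_validated(self):
        with pytest.raises(ValueError):
            SimulationConfig(helitron_motif_fraction=1.5)

    def test_meg_peg_budget_validated(self):
        with pytest.raises(ValueError):
            SimulationConfig(meg_fraction=0.6, peg_fraction=0.6)

    def test_peak_longer_than_promoter_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(peak_length=(3500, 4000))

    def test_yaml_round_trip(self, tmp_path, small_config):
        path = tmp_path / "cfg.yaml"
        small_config.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == small_config

    def test_genome_capacity_validated(self):
        with pytest.raises(ValueError, match="cannot hold"):
            simulate_annotation(SimulationConfig(chrom_length=50_000,
                                                 n_genes=100))


class TestAnnotation:
    def test_carrier_count_by_construction(self, small_bundle):
        te = small_bundle.annotation.te_table
        assert te["motif_carrier"].sum() == round(0.5 * 40)
        assert (te.loc[te["motif_carrier"], "superfamily"]
                == "RC/Helitron").all()

    def test_planted_motifs_are_the_only_te_matches(self, small_bundle):
        ann = small_bundle.annotation
        matches = scan_consensus(ann.genome)
        te_set = ann.te_intervals
        inside = [
            m for m in matches
            for iv in te_set.by_chrom(m.chrom)
            if m.start >= iv.start and m.end <= iv.end
        ]
        carriers = ann.te_table[ann.te_table["motif_carrier"]]
        assert {(m.chrom, m.start) for m in inside} == set(
            zip(carriers["chrom"], carriers["motif_start"])
        )
        assert all(m.match_class == "perfect" for m in inside)

    def test_zero_fraction_leaves_helitrons_motif_free(self):
        cfg = SimulationConfig(
            seed=3, chrom_length=400_000, n_genes=60,
            te_counts={"RC/Helitron": 40, "LTR/Gypsy": 20},
            helitron_motif_fraction=0.0, peak_motif_targeting=0.0,
            peak_count=40, n_expressed_genes=40,
        )
        ann = simulate_annotation(cfg)
        hel = ann.te_by_superfamily()["RC/Helitron"]
        matches = scan_consensus(ann.genome)
        inside = [
            m for m in matches
            for iv in hel.by_chrom(m.chrom)
            if m.start >= iv.start and m.end <= iv.end
        ]
        assert inside == []

    def test_genes_do_not_overlap(self, small_bundle):
        genes = sorted(small_bundle.annotation.genes,
                       key=lambda g: (g.chrom, g.body.start))
        for a, b in zip(genes, genes[1:]):
            assert a.chrom != b.chrom or a.body.end <= b.body.start


class TestPeaks:
    def test_no_jitter_no_specific_gives_exact_common_count(self):
        cfg = SimulationConfig(
            seed=5, chrom_length=400_000, n_genes=60,
            te_counts={"RC/Helitron": 40}, peak_count=40,
            replicate_jitter=0, replicate_specific_fraction=0.0,
            n_expressed_genes=40,
        )
        ann = simulate_annotation(cfg)
        peaks = simulate_peaks(ann, cfg)
        sites = common_peaks(peaks.rep1, peaks.rep2)
        assert len(peaks.rep1) == len(peaks.truth) == 40
        # every peak replicates exactly; sites differ only by merging of
        # peaks that happen to share a promoter
        assert len(sites.sites) == len(peaks.rep1.merged())
        assert sites.reproducibility == {"rep1": 1.0, "rep2": 1.0}

    def test_replicate_specific_fraction_halves_commonality(self):
        cfg = SimulationConfig(
            seed=5, chrom_length=400_000, n_genes=60,
            te_counts={"RC/Helitron": 40}, peak_count=40,
            replicate_jitter=0, replicate_specific_fraction=0.5,
            peak_motif_targeting=0.2, n_expressed_genes=40,
        )
        peaks = simulate_peaks(simulate_annotation(cfg), cfg)
        assert len(peaks.rep1) == 40
        assert len(peaks.truth) == 20  # shared peaks carry the truth targets

    def test_full_targeting_places_peaks_on_carrier_promoters(self):
        cfg = SimulationConfig(
            seed=6, chrom_length=400_000, n_genes=60,
            te_counts={"RC/Helitron": 50}, helitron_motif_fraction=1.0,
            peak_count=40, peak_motif_targeting=1.0,
            replicate_specific_fraction=0.0, n_expressed_genes=40,
        )
        ann = simulate_annotation(cfg)
        peaks = simulate_peaks(ann, cfg)
        carriers = ann.te_table[ann.te_table["motif_carrier"]]
        hosts = set(carriers["host_gene"])
        assert peaks.truth["on_motif_te"].all()
        assert set(peaks.truth["target_gene"]) <= hosts


class TestAllelicData:
    def test_zero_dispersion_biallelic_mean(self):
        cfg = SimulationConfig(
            seed=8, chrom_length=400_000, n_genes=60,
            te_counts={"RC/Helitron": 40}, peak_count=40,
            n_expressed_genes=50, allelic_dispersion=0.0,
            meg_fraction=0.0, peg_fraction=0.0, depth_range=(300, 301),
        )
        bundle = simulate_bundle(cfg)
        counts = bundle.allelic.counts
        sub = counts[counts["cross"] == CROSS_2X]
        fractions = sub["maternal"] / (sub["maternal"] + sub["paternal"])
        assert fractions.mean() == pytest.approx(2 / 3, abs=0.01)

    def test_planted_megs_exceed_threshold_without_noise(self):
        cfg = SimulationConfig(
            seed=9, chrom_length=400_000, n_genes=60,
            te_counts={"RC/Helitron": 40}, peak_count=40,
            n_expressed_genes=50, allelic_dispersion=0.0,
            meg_fraction=0.3, peg_fraction=0.0, depth_range=(500, 501),
        )
        bundle = simulate_bundle(cfg)
        truth = bundle.allelic.gene_truth
        megs = set(truth.loc[truth["label"] == "MEG", "gene_id"])
        counts = bundle.allelic.counts
        thr = imprinting_thresholds(CROSS_2X)
        sub = counts[(counts["cross"] == CROSS_2X)
                     & counts["gene_id"].isin(megs)]
        fractions = sub["maternal"] / (sub["maternal"] + sub["paternal"])
        assert (fractions >= thr.meg_min_fraction).all()

    def test_allele_tracks_sum_to_total(self, small_bundle):
        tracks = small_bundle.allelic.tracks
        mat = tracks["h3k27me3_maternal"]["value"].to_numpy()
        pat = tracks["h3k27me3_paternal"]["value"].to_numpy()
        tot = tracks["h3k27me3_total"]["value"].to_numpy()
        assert np.allclose(mat + pat, tot)

    def test_planted_margin_on_log_odds_scale(self):
        # imprinted genes sit at fold**margin odds deviation
        f = planted_fraction(CROSS_2X, "MEG", fold=4.0, margin=1.5)
        assert f == pytest.approx(16 / 17)
        f = planted_fraction(CROSS_2X, "PEG", fold=4.0, margin=1.5)
        assert f == pytest.approx((2 / 8) / (2 / 8 + 1))


class TestDeterminism:
    def test_same_seed_byte_identical_bundle(self, tmp_path, small_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = write_bundle(simulate_bundle(small_config), d1)
        p2 = write_bundle(simulate_bundle(small_config), d2)
        assert sorted(p1) == sorted(p2)
        for name in p1:
            assert filecmp.cmp(p1[name], p2[name], shallow=False), name

    def test_different_seed_differs(self, tmp_path, small_config):
        import dataclasses

        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        b1 = simulate_bundle(small_config)
        b2 = simulate_bundle(other)
        assert b1.annotation.genome != b2.annotation.genome
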