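"""Signal binning, profile clustering, gene-body scores and methylation
contrasts."""

import numpy as np
import pandas as pd
import pytest

from seedreg.intervals import GenomicInterval, GeneModel, IntervalSet
from seedreg.profiles import (
    BinnedSignal,
    bin_signal,
    cluster_sites,
    gene_body_score,
    methylation_contrast,
    standardize_track,
)


def track_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def sites_at(*midpoints, chrom="chr1", half=75):
    return IntervalSet(
        GenomicInterval(chrom, m - half, m + half, ".", f"s{i}")
        for i, m in enumerate(midpoints)
    )


class TestBinSignal:
    def test_constant_track_gives_flat_bins(self):
        track = track_df([("chr1", 0, 100_000, 3.5)])
        signal = bin_signal(track, sites_at(5000, 9000))
        assert np.allclose(signal.matrix.to_numpy(), 3.5)
        assert np.allclose(signal.metagene.to_numpy(), 3.5)

    def test_allele_matrices_sum_to_total(self, rng):
        bins = [("chr1", s, s + 50, float(v))
                for s, v in zip(range(0, 20_000, 50), rng.normal(1, 0.3, 400))]
        mat = track_df(bins)
        pat = track_df([(c, s, e, float(v))
                        for (c, s, e, _), v in zip(bins, rng.normal(2, 0.3, 400))])
        total = track_df([
            (c, s, e, m + p)
            for (c, s, e, m), (_, _, _, p) in zip(
                mat.itertuples(index=False), pat.itertuples(index=False))
        ])
        sites = sites_at(5000, 9000, 15_000)
        bm = bin_signal(mat, sites)
        bp = bin_signal(pat, sites)
        bt = bin_signal(total, sites)
        assert np.allclose(bm.matrix.to_numpy() + bp.matrix.to_numpy(),
                           bt.matrix.to_numpy())
        assert np.allclose(bm.metagene + bp.metagene, bt.metagene)

    def test_step_track_matches_per_base_oracle(self, rng):
        edges = np.sort(rng.choice(np.arange(1, 20_000), 60, replace=False))
        spans = np.concatenate([[0], edges, [20_000]])
        values = rng.normal(size=len(spans) - 1)
        track = track_df([
            ("chr1", int(s), int(e), float(v))
            for s, e, v in zip(spans[:-1], spans[1:], values)
        ])
        per_base = np.repeat(values, np.diff(spans))
        signal = bin_signal(track, sites_at(6000), window=2000, bin_size=50)
        start = 6000 - 1000
        for b in range(40):
            expected = per_base[start + b * 50 : start + (b + 1) * 50].mean()
            assert signal.matrix.iloc[0, b] == pytest.approx(expected)

    def test_sites_near_chromosome_end_dropped_and_reported(self):
        track = track_df([("chr1", 0, 10_000, 1.0)])
        signal = bin_signal(track, sites_at(500, 5000),
                            chrom_sizes={"chr1": 10_000})
        assert signal.dropped_sites == ["s0"]
        assert list(signal.matrix.index) == ["s1"]

    def test_translation_equivariance(self, rng):
        bins = [("chr1", s, s + 50, float(v))
                for s, v in zip(range(0, 10_000, 50), rng.normal(size=200))]
        track = track_df(bins)
        shifted = track_df([(c, s + 777, e + 777, v)
                            for c, s, e, v in bins])
        a = bin_signal(track, sites_at(5000))
        b = bin_signal(shifted, sites_at(5777))
        assert np.allclose(a.matrix.to_numpy(), b.matrix.to_numpy())

    def test_uncovered_bins_stay_missing(self):
        track = track_df([("chr1", 0, 4100, 1.0)])  # covers half the window
        signal = bin_signal(track, sites_at(4100))
        values = signal.matrix.to_numpy()[0]
        assert np.isnan(values[25:]).all() and not np.isnan(values[:20]).any()

    def test_window_bin_divisibility_enforced(self):
        with pytest.raises(ValueError):
            bin_signal(track_df([]), sites_at(100), window=2000, bin_size=33)


def archetype_matrix(rng, n_sites=60, noise=0.0):
    flank = np.full(40, 2.0)
    flank[15:25] = 0.0
    flat = np.full(40, 0.2)
    rows, truth = [], []
    for i in range(n_sites):
        base = flank if i % 2 == 0 else flat
        rows.append(base + rng.normal(0, noise, 40))
        truth.append(1 if i % 2 == 0 else 2)
    matrix = pd.DataFrame(rows, index=[f"s{i}" for i in range(n_sites)],
                          columns=range(-1000, 1000, 50))
    return BinnedSignal(matrix, 2000, 50), truth


class TestClusterSites:
    def test_cluster_one_is_flank_enriched(self, rng):
        signal, truth = archetype_matrix(rng, noise=0.1)
        labels, degenerate = cluster_sites(signal, seed=0)
        assert not degenerate
        assert list(labels) == truth  # numbering follows flank signal

    def test_numbering_stable_across_seeds(self, rng):
        signal, truth = archetype_matrix(rng, noise=0.1)
        for seed in (0, 1, 2):
            labels, _ = cluster_sites(signal, seed=seed)
            assert list(labels) == truth

    def test_identical_rows_degenerate(self):
        matrix = pd.DataFrame(np.ones((8, 40)),
                              index=[f"s{i}" for i in range(8)])
        labels, degenerate = cluster_sites(BinnedSignal(matrix, 2000, 50))
        assert degenerate and set(labels) == {1}


class TestGeneBodyScore:
    def gene(self, start, end):
        return GeneModel(
            "g", GenomicInterval("chr1", start, end, "+", "g"), "+"
        )

    def test_constant_track_scores_zero(self):
        track = track_df([("chr1", s, s + 50, 2.0) for s in range(0, 5000, 50)])
        scores = gene_body_score(track, [self.gene(1000, 2000)])
        assert scores.iloc[0]["score"] == pytest.approx(0.0)

    def test_mean_of_bin_values(self):
        track = track_df([("chr1", 0, 50, 1.0), ("chr1", 50, 100, 3.0)])
        scores = gene_body_score(track, [self.gene(0, 100)], standardize=False)
        assert scores.iloc[0]["score"] == pytest.approx(2.0)

    def test_uncovered_gene_omitted(self):
        track = track_df([("chr1", 0, 100, 1.0)])
        scores = gene_body_score(track, [self.gene(5000, 6000)],
                                 standardize=False)
        assert scores.empty

    def test_standardize_track_moments(self, rng):
        track = track_df([("chr1", s, s + 50, float(v))
                          for s, v in zip(range(0, 10_000, 50),
                                          rng.normal(3, 2, 200))])
        z = standardize_track(track)
        assert z["value"].mean() == pytest.approx(0.0, abs=1e-9)
        assert z["value"].std(ddof=0) == pytest.approx(1.0)

    def test_planted_maternal_elevation_detected(self, rng):
        # PEG-associated genes with maternal H3K27me3 two sd above background
        from seedreg.enrichment import compare_groups_mw

        genes = [self.gene(i * 2000, i * 2000 + 1000) for i in range(100)]
        genes = [
            GeneModel(f"g{i}", GenomicInterval("chr1", g.body.start,
                                               g.body.end, "+", f"g{i}"), "+")
            for i, g in enumerate(genes)
        ]
        rows = []
        for i, g in enumerate(genes):
            level = 2.0 if i < 50 else 0.0
            for s in range(g.body.start, g.body.end, 50):
                rows.append(("chr1", s, s + 50, level + rng.normal(0, 1)))
        scores = gene_body_score(track_df(rows), genes, standardize=False)
        peg = scores.iloc[:50]["score"].to_numpy()
        rest = scores.iloc[50:]["score"].to_numpy()
        table = compare_groups_mw({"peg_maternal": peg, "background": rest})
        assert table.iloc[0]["p_value"] < 0.01


class TestMethylationContrast:
    def make_signal(self, rng, offset=0.0, groups=("MEG", "PEG", "none")):
        rows = {}
        for i in range(30):
            rows[f"s{i}"] = 0.2 + offset * (i % 3 == 0) + rng.normal(0, 0.01, 40)
        matrix = pd.DataFrame.from_dict(rows, orient="index")
        sig = BinnedSignal(matrix, 2000, 50)
        site_groups = {f"s{i}": groups[i % 3] for i in range(30)}
        return sig, site_groups

    def test_identical_alleles_not_significant(self, rng):
        sig, groups = self.make_signal(rng)
        table, tests = methylation_contrast(sig, sig, groups)
        allele_rows = tests[tests["contrast"].str.startswith("alleles_in")]
        assert (allele_rows["p_value"] > 0.9).all()

    def test_planted_paternal_boost_on_meg_sites(self, rng):
        mat, groups = self.make_signal(rng)
        pat, _ = self.make_signal(rng, offset=0.3)  # boost on MEG sites
        table, tests = methylation_contrast(mat, pat, groups)
        row = tests[tests["contrast"] == "alleles_in_MEG"].iloc[0]
        assert row["p_value"] < 0.01
        by = table[(table["group"] == "MEG")].groupby("allele")["mean_signal"]
        assert by.mean()["paternal"] > by.mean()["maternal"]

    def test_group_means_equal_brute_force(self, rng):
        sig, groups = self.make_signal(rng)
        table, _ = methylation_contrast(sig, sig, groups)
        sub = table[(table["allele"] == "maternal") & (table["site"] == "s0")]
        assert sub.iloc[0]["mean_signal"] == pytest.approx(
            float(np.mean(sig.matrix.loc["s0"].to_numpy()))
        )

    def test_unknown_site_rejected(self, rng):
        sig, groups = self.make_signal(rng)
        groups.pop("s0")
        with pytest.raises(ValueError):
            methylation_contrast(sig, sig, groups)
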