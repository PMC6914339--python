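"""Hypergeometric tests, TF-family enrichment, gene categories, the
Mann-Whitney comparison and seeded k-means."""

import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from seedreg.enrichment import (
    categorize_flanking_genes,
    compare_groups_mw,
    hypergeom_test,
    kmeans_cluster,
    tf_family_enrichment,
)
from seedreg.intervals import GenomicInterval, GeneModel, IntervalSet
from seedreg.motifs import MotifMatch

from .oracles import hypergeom_enumeration, mannwhitney_exact_two_sided


class TestHypergeom:
    def test_zero_successes_over_tail(self):
        assert hypergeom_test(0, 5, 4, 10) == pytest.approx(1.0)

    def test_equals_literal_enumeration(self):
        assert hypergeom_test(3, 5, 4, 10) == pytest.approx(
            hypergeom_enumeration(3, 5, 4, 10)
        )

    def test_most_extreme_term(self):
        # k = min(n, K): the tail reduces to the single most extreme term
        p = hypergeom_test(4, 5, 4, 10)
        expected = math.comb(4, 4) * math.comb(6, 1) / math.comb(10, 5)
        assert p == pytest.approx(expected)

    def test_under_tail(self):
        over = hypergeom_test(3, 5, 4, 10, tail="over")
        under = hypergeom_test(2, 5, 4, 10, tail="under")
        assert over + under == pytest.approx(1.0)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_test(6, 5, 4, 10)


class TestTFFamilyEnrichment:
    def family_map(self):
        fam = {f"tf{i}": "MADS" for i in range(10)}
        fam.update({f"tf{i}": "bZIP" for i in range(10, 100)})
        return fam

    def test_log2_fold_change_arithmetic(self):
        targets = {f"tf{i}" for i in range(5)} | {f"tf{i}" for i in range(10, 25)}
        records = tf_family_enrichment(targets, self.family_map())
        mads = next(r for r in records if r.category == "MADS")
        # 5/20 targeted vs 10/100 genome-wide
        assert mads.log2_fold_change == pytest.approx(np.log2(2.5))

    def test_family_of_five_excluded(self):
        fam = self.family_map()
        fam.update({f"x{i}": "tiny" for i in range(5)})
        records = tf_family_enrichment({"tf0", "x0"}, fam)
        assert all(r.category != "tiny" for r in records)

    def test_proportional_family_has_zero_fold_change(self):
        # targeted share equals genome share
        targets = {"tf0"} | {f"tf{i}" for i in range(10, 19)}
        records = tf_family_enrichment(targets, self.family_map())
        mads = next(r for r in records if r.category == "MADS")
        assert mads.log2_fold_change == pytest.approx(0.0)

    def test_no_targets_rejected(self):
        with pytest.raises(ValueError):
            tf_family_enrichment(set(), self.family_map())


def make_gene(gene_id, tss, strand="+", chrom="chr1", length=1000):
    if strand == "+":
        body = GenomicInterval(chrom, tss, tss + length, strand, gene_id)
    else:
        body = GenomicInterval(chrom, tss - length + 1, tss + 1, strand, gene_id)
    return GeneModel(gene_id, body, strand)


def match_at(chrom, start):
    return MotifMatch(chrom, start, start + 10, "+", "CCAAAAAAGG", "perfect")


class TestCategorizeFlankingGenes:
    def test_bound_motif_helitron(self):
        gene = make_gene("g", 10_000)
        helitrons = IntervalSet([GenomicInterval("chr1", 7900, 8200)])  # -2 kb
        motifs = [match_at("chr1", 8000)]
        sites = IntervalSet([GenomicInterval("chr1", 7950, 8100)])
        cats = categorize_flanking_genes([gene], helitrons, motifs, sites)
        assert cats["g"] == "helitron_motif_bound"

    def test_unbound_and_motifless(self):
        gene = make_gene("g", 10_000)
        helitrons = IntervalSet([GenomicInterval("chr1", 7900, 8200)])
        no_sites = IntervalSet()
        cats = categorize_flanking_genes(
            [gene], helitrons, [match_at("chr1", 8000)], no_sites
        )
        assert cats["g"] == "helitron_motif_unbound"
        cats = categorize_flanking_genes([gene], helitrons, [], no_sites)
        assert cats["g"] == "helitron_no_motif"

    def test_helitron_outside_promoter(self):
        gene = make_gene("g", 10_000)
        helitrons = IntervalSet([GenomicInterval("chr1", 6200, 6500)])  # -3.5 kb
        cats = categorize_flanking_genes([gene], helitrons, [], IntervalSet())
        assert cats["g"] == "no_promoter_helitron"

    def test_counts_match_brute_force_scan(self, rng):
        genes = [
            make_gene(f"g{i}", int(t), str(rng.choice(["+", "-"])))
            for i, t in enumerate(rng.integers(5000, 195_000, 40))
        ]
        helitrons = IntervalSet(
            GenomicInterval("chr1", int(s), int(s) + 300)
            for s in rng.integers(0, 200_000, 60)
        )
        motifs = [match_at("chr1", int(s)) for s in rng.integers(0, 200_000, 80)]
        sites = IntervalSet(
            GenomicInterval("chr1", int(s), int(s) + 150)
            for s in rng.integers(0, 200_000, 50)
        )
        cats = categorize_flanking_genes(genes, helitrons, motifs, sites)
        for g in genes:
            # independent per-gene scan with plain coordinate arithmetic
            if g.strand == "+":
                ps, pe = max(0, g.tss - 3000), g.tss
            else:
                ps, pe = g.tss + 1, g.tss + 1 + 3000
            hels = [h for h in helitrons
                    if h.start < pe and ps < h.end]
            expected = "no_promoter_helitron"
            if hels:
                expected = "helitron_no_motif"
                hits = [
                    m for m in motifs
                    if any(m.start < h.end and h.start < m.end for h in hels)
                    and m.start < pe and ps < m.end
                ]
                if hits:
                    expected = "helitron_motif_unbound"
                    if any(
                        m.start < s.end and s.start < m.end
                        for m in hits for s in sites
                    ):
                        expected = "helitron_motif_bound"
            assert cats[g.gene_id] == expected


class TestMannWhitney:
    def test_exact_small_sample_example(self):
        table = compare_groups_mw({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert table.iloc[0]["p_value"] == pytest.approx(0.1)
        assert table.iloc[0]["method"] == "exact"

    def test_identical_groups_near_one(self):
        table = compare_groups_mw(
            {"a": list(range(20)), "b": list(range(20))}
        )
        assert table.iloc[0]["p_value"] > 0.9

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            x = list(np.round(rng.normal(size=5), 3))
            y = list(np.round(rng.normal(size=6), 3))
            table = compare_groups_mw({"x": x, "y": y})
            assert table.iloc[0]["p_value"] == pytest.approx(
                mannwhitney_exact_two_sided(x, y)
            )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups_mw({"a": [], "b": [1.0]})


class TestKMeans:
    def test_separable_clouds_recovered(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (30, 4)), rng.normal(5, 0.1, (30, 4))])
        truth = [0] * 30 + [1] * 30
        labels, _, dropped = kmeans_cluster(X, k=2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert len(dropped) == 0

    def test_duplicate_rows_share_labels(self, rng):
        row = rng.normal(size=(1, 5))
        X = np.vstack([row, row, rng.normal(10, 1, (10, 5))])
        labels, _, _ = kmeans_cluster(X, k=2, seed=0)
        assert labels[0] == labels[1]

    def test_rows_with_missing_values_dropped(self, rng):
        X = rng.normal(size=(10, 3))
        X[3, 1] = np.nan
        labels, _, dropped = kmeans_cluster(X, k=2, seed=0)
        assert list(dropped) == [3]
        assert len(labels) == 9

    def test_k_larger_than_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            kmeans_cluster(rng.normal(size=(3, 2)), k=5)

    def test_planted_expression_trends_recovered(self, rng):
        # three archetypal trends across five developmental stages
        trends = np.array(
            [[-2, -2.5, -3, -3.5, -4], [0.5, 0.8, 1.0, 1.2, 1.5],
             [-0.2, -0.4, -0.6, -0.8, -1.0]]
        )
        truth, rows = [], []
        for t in range(3):
            for _ in range(60):
                rows.append(trends[t] + rng.normal(0, 0.15, 5))
                truth.append(t)
        labels, _, _ = kmeans_cluster(np.array(rows), k=3, seed=0)
        assert adjusted_rand_score(truth, labels) >= 0.9
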