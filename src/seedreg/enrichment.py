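"""Set-enrichment statistics, gene categorisation and clustering utilities.

Covers the recurring statistical machinery of the analysis: hypergeometric
over/under-representation tests, TF-family enrichment with ratio
normalisation, categorisation of genes by promoter RC/Helitron + motif +
binding status, the Mann-Whitney group comparison, and seeded k-means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .intervals import GeneModel, IntervalSet
from .motifs import MotifMatch


@dataclass(frozen=True)
class EnrichmentRecord:
    category: str
    k: int  # category members inside the query set
    n: int  # query set size
    K: int  # category size in the universe
    N: int  # universe size
    log2_fold_change: float
    p_value: float


def hypergeom_test(k: int, n: int, K: int, N: int, tail: str = "over") -> float:
    """P(X >= k) (or <= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if tail == "over":
        return float(stats.hypergeom.sf(k - 1, N, K, n))
    if tail == "under":
        return float(stats.hypergeom.cdf(k, N, K, n))
    raise ValueError(f"unknown tail {tail!r}")


def tf_family_enrichment(
    target_tf_ids: set[str],
    family_map: dict[str, str],
    min_family_size: int = 6,
    bh_correction: bool = False,
) -> list[EnrichmentRecord]:
    """Per-family enrichment of targeted transcription factors.

    The fold change contrasts the share of targeted TFs belonging to a
    family with that family's share of all TFs; significance comes from the
    hypergeometric test. Families with fewer than ``min_family_size``
    members are excluded.
    """
    n_targeted = len(target_tf_ids)
    if n_targeted == 0:
        raise ValueError("no targeted transcription factors supplied")
    missing = target_tf_ids - set(family_map)
    if missing:
        raise ValueError(f"family map does not cover: {sorted(missing)[:5]}")
    n_total = len(family_map)
    families = sorted(set(family_map.values()))
    records = []
    for family in families:
        members = {tf for tf, fam in family_map.items() if fam == family}
        if len(members) < min_family_size:
            continue
        k = len(members & target_tf_ids)
        targeted_ratio = k / n_targeted
        genome_ratio = len(members) / n_total
        log2fc = (
            np.log2(targeted_ratio / genome_ratio) if k > 0 else -np.inf
        )
        p = hypergeom_test(k, n_targeted, len(members), n_total)
        records.append(
            EnrichmentRecord(family, k, n_targeted, len(members), n_total,
                             float(log2fc), p)
        )
    if bh_correction and records:
        order = np.argsort([r.p_value for r in records])
        m = len(records)
        adj = np.empty(m)
        prev = 1.0
        for rank_pos in range(m - 1, -1, -1):
            idx = order[rank_pos]
            prev = min(prev, records[idx].p_value * m / (rank_pos + 1))
            adj[idx] = prev
        records = [
            EnrichmentRecord(r.category, r.k, r.n, r.K, r.N,
                             r.log2_fold_change, float(adj[i]))
            for i, r in enumerate(records)
        ]
    return records


FLANKING_CATEGORIES = (
    "helitron_motif_bound",      # promoter RC/Helitron + motif + binding site
    "helitron_motif_unbound",    # promoter RC/Helitron + motif, not bound
    "helitron_no_motif",         # promoter RC/Helitron without motif
    "no_promoter_helitron",
)


def categorize_flanking_genes(
    genes: list[GeneModel],
    helitrons: IntervalSet,
    motif_matches: list[MotifMatch],
    bound_sites: IntervalSet,
    promoter_span: int = 3000,
) -> dict[str, str]:
    """Assign each gene to one RC/Helitron promoter category.

    The test is restricted to the promoter, defined as ``promoter_span``
    bases upstream of the TSS in gene orientation. A gene is in the bound
    category when a promoter RC/Helitron carries a motif match and that
    motif is overlapped by a binding site.
    """
    motif_ivs = IntervalSet(m.interval for m in motif_matches)
    out = {}
    for gene in genes:
        promoter = gene.promoter(promoter_span)
        category = "no_promoter_helitron"
        if promoter is not None:
            prom_helitrons = [
                h for h in helitrons.by_chrom(gene.chrom) if h.overlaps(promoter)
            ]
            if prom_helitrons:
                category = "helitron_no_motif"
                for h in prom_helitrons:
                    motifs_in_te = [
                        m for m in motif_ivs.by_chrom(gene.chrom)
                        if m.overlaps(h) and m.overlaps(promoter)
                    ]
                    if not motifs_in_te:
                        continue
                    category = "helitron_motif_unbound"
                    if any(
                        s.overlaps(m)
                        for m in motifs_in_te
                        for s in bound_sites.by_chrom(gene.chrom)
                    ):
                        category = "helitron_motif_bound"
                        break
        out[gene.gene_id] = category
    return out


def compare_groups_mw(
    groups: dict[str, np.ndarray | list[float]],
    alternative: str = "two-sided",
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons between named groups.

    Uses exact enumeration when both groups have at most ``exact_max_n``
    tie-free values, otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    arrays = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        arrays[name] = arr
    names = sorted(arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = arrays[names[i]], arrays[names[j]]
            no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
            method = (
                "exact"
                if (len(a) <= exact_max_n and len(b) <= exact_max_n and no_ties)
                else "asymptotic"
            )
            res = stats.mannwhitneyu(
                a, b, alternative=alternative, method=method,
                use_continuity=True,
            )
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "n_a": len(a),
                    "n_b": len(b),
                    "median_a": float(np.median(a)),
                    "median_b": float(np.median(b)),
                    "U": float(res.statistic),
                    "p_value": float(res.pvalue),
                    "method": method,
                }
            )
    return pd.DataFrame(rows)


def kmeans_cluster(
    matrix: np.ndarray | pd.DataFrame,
    k: int,
    seed: int = 0,
    n_init: int = 10,
):
    """Seeded k-means (k-means++ init, best of ``n_init`` restarts).

    Rows with missing values are dropped; their indices are returned so the
    caller can report them. Returns ``(labels, centroids, dropped_rows)``
    with labels aligned to the surviving rows.
    """
    X = np.asarray(matrix, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    complete = ~np.isnan(X).any(axis=1)
    dropped = np.flatnonzero(~complete)
    X = X[complete]
    if X.shape[0] < k:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} complete observations")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return labels, km.cluster_centers_, dropped
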