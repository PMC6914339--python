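"""Monte-Carlo permutation test for binding-site / TE overlap enrichment.

The null model mirrors the observed binding-site set: the same number of
sites with the same length multiset, each placed uniformly inside a gene
promoter drawn uniformly among the promoters large enough to contain it.
The empirical p-value uses the add-one rule (r + 1) / (n_iter + 1), which
never returns zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet, overlap_fraction


@dataclass(frozen=True)
class PermutationResult:
    feature: str
    observed: float
    null_mean: float
    null_sd: float
    z_score: float  # nan when the null distribution is degenerate
    p_value: float
    n_iterations: int
    alternative: str


class _PromoterShuffler:
    """Vectorised placement of length-preserving random sites in promoters."""

    def __init__(self, promoters: IntervalSet):
        if len(promoters) == 0:
            raise ValueError("promoter universe is empty")
        self.chroms = np.array([iv.chrom for iv in promoters])
        self.starts = np.array([iv.start for iv in promoters], dtype=np.int64)
        self.lengths = np.array([len(iv) for iv in promoters], dtype=np.int64)
        self.order = np.argsort(self.lengths, kind="stable")
        self.sorted_lengths = self.lengths[self.order]

    def place(self, site_lengths: np.ndarray, rng: np.random.Generator):
        """Random (promoter_index, start) pairs, one per site length."""
        n_prom = len(self.lengths)
        first_fit = np.searchsorted(self.sorted_lengths, site_lengths, side="left")
        if (first_fit >= n_prom).any():
            too_long = int(site_lengths[first_fit >= n_prom].max())
            raise ValueError(
                f"site of length {too_long} exceeds every promoter length"
            )
        n_eligible = n_prom - first_fit
        pick = first_fit + rng.integers(0, n_eligible)
        prom = self.order[pick]
        max_offset = self.lengths[prom] - site_lengths
        offset = rng.integers(0, max_offset + 1)
        return prom, self.starts[prom] + offset


def shuffle_sites(
    sites: IntervalSet, promoters: IntervalSet, rng: np.random.Generator
) -> IntervalSet:
    """One random site set with the observed cardinality and length multiset."""
    lengths = np.array([len(iv) for iv in sites], dtype=np.int64)
    shuffler = _PromoterShuffler(promoters)
    prom, starts = shuffler.place(lengths, rng)
    return IntervalSet(
        GenomicInterval(shuffler.chroms[p], int(s), int(s) + int(l))
        for p, s, l in zip(prom, starts, lengths)
    )


def permutation_test(
    sites: IntervalSet,
    te_by_feature: dict[str, IntervalSet],
    promoters: IntervalSet,
    n_iter: int = 10_000,
    seed: int | np.random.Generator = 0,
    alternative: str = "enrichment",
) -> list[PermutationResult]:
    """Permutation test of site overlap with each TE feature.

    A single sequence of ``n_iter`` random site sets is drawn and scored
    against every feature, matching the use of one random control set for
    all TE superfamilies/families. ``alternative`` selects the tail:
    ``enrichment`` counts null overlap fractions >= observed, ``depletion``
    counts <= observed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if alternative not in {"enrichment", "depletion"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sites = len(sites)
    lengths = np.array([len(iv) for iv in sites], dtype=np.int64)
    shuffler = _PromoterShuffler(promoters)

    # draw all null placements once; evaluate every feature on the same nulls
    prom = np.empty((n_iter, n_sites), dtype=np.int64)
    starts = np.empty((n_iter, n_sites), dtype=np.int64)
    for i in range(n_iter):
        prom[i], starts[i] = shuffler.place(lengths, rng)
    flat_chroms = shuffler.chroms[prom.ravel()]
    flat_starts = starts.ravel()
    flat_ends = flat_starts + np.tile(lengths, n_iter)

    results = []
    for feature in sorted(te_by_feature):
        te_set = te_by_feature[feature]
        observed = overlap_fraction(sites, te_set)
        hits = np.zeros(n_iter * n_sites, dtype=bool)
        for chrom in np.unique(flat_chroms):
            mask = flat_chroms == chrom
            hits[mask] = te_set.overlaps_any(
                flat_starts[mask], flat_ends[mask], chrom
            )
        null = hits.reshape(n_iter, n_sites).mean(axis=1)
        null_mean = float(null.mean())
        null_sd = float(null.std(ddof=0))
        if alternative == "enrichment":
            r = int((null >= observed).sum())
        else:
            r = int((null <= observed).sum())
        p = (r + 1) / (n_iter + 1)
        z = (observed - null_mean) / null_sd if null_sd > 0 else float("nan")
        results.append(
            PermutationResult(
                feature, observed, null_mean, null_sd, z, p, n_iter, alternative
            )
        )
    return results


def results_table(results: list[PermutationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "observed_overlap": [r.observed for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_sd": [r.null_sd for r in results],
            "z_score": [r.z_score for r in results],
            "p_value": [r.p_value for r in results],
            "n_iterations": [r.n_iterations for r in results],
            "alternative": [r.alternative for r in results],
        }
    )
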