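"""Allele-specific chromatin signal around binding sites.

Signal tracks (bedGraph, one per parental allele) are quantified in fixed
bins across a window centered on each binding-site midpoint (default 2 kb,
50-bp bins, i.e. 40 bins). Bin values are coverage-weighted means of the
track; bins without coverage stay missing rather than being zero-filled.
Sites are clustered by signal shape with k-means, numbering cluster 1 as
the flank-enriched pattern, and gene bodies are scored by mean z-score of
a standardised track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import compare_groups_mw, kmeans_cluster
from .intervals import GeneModel, IntervalSet


@dataclass
class BinnedSignal:
    """Sites x bins signal matrix plus its across-site metagene."""

    matrix: pd.DataFrame  # index = site names, columns = bin start offsets
    window: int
    bin_size: int
    dropped_sites: list[str] = field(default_factory=list)

    @property
    def metagene(self) -> pd.Series:
        return self.matrix.mean(axis=0, skipna=True)


class _Track:
    """Per-chromosome sorted arrays of a bedGraph track."""

    def __init__(self, df: pd.DataFrame):
        self.by_chrom = {}
        for chrom, sub in df.groupby("chrom"):
            sub = sub.sort_values("start")
            self.by_chrom[chrom] = (
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
                sub["value"].to_numpy(float),
            )

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Coverage-weighted mean of the track over [start, end); nan if bare."""
        if chrom not in self.by_chrom:
            return np.nan
        starts, ends, values = self.by_chrom[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return np.nan
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        ov = np.clip(ov, 0, None)
        total = ov.sum()
        if total == 0:
            return np.nan
        return float((values[lo:hi] * ov).sum() / total)

    def length_weighted_moments(self) -> tuple[float, float]:
        lengths = np.concatenate(
            [e - s for s, e, _ in self.by_chrom.values()]
        ).astype(float)
        values = np.concatenate([v for _, _, v in self.by_chrom.values()])
        mean = float(np.average(values, weights=lengths))
        var = float(np.average((values - mean) ** 2, weights=lengths))
        return mean, np.sqrt(var)


def bin_signal(
    track: pd.DataFrame,
    sites: IntervalSet,
    window: int = 2000,
    bin_size: int = 50,
    chrom_sizes: dict[str, int] | None = None,
) -> BinnedSignal:
    """Bin a track in a centered window around every site midpoint.

    Sites whose window would run off a chromosome end are dropped and
    reported in ``dropped_sites``.
    """
    if window % bin_size != 0:
        raise ValueError("window must be divisible by bin_size")
    half = window // 2
    n_bins = window // bin_size
    tr = _Track(track)
    offsets = [-half + b * bin_size for b in range(n_bins)]
    rows, names, dropped = [], [], []
    for iv in sites:
        mid = iv.midpoint
        start = mid - half
        end = mid + half
        limit = chrom_sizes.get(iv.chrom) if chrom_sizes else None
        if start < 0 or (limit is not None and end > limit):
            dropped.append(iv.name or f"{iv.chrom}:{iv.start}-{iv.end}")
            continue
        rows.append(
            [tr.window_mean(iv.chrom, start + b * bin_size,
                            start + (b + 1) * bin_size) for b in range(n_bins)]
        )
        names.append(iv.name or f"{iv.chrom}:{iv.start}-{iv.end}")
    matrix = pd.DataFrame(rows, index=names, columns=offsets)
    return BinnedSignal(matrix, window, bin_size, dropped)


def cluster_sites(
    signal: BinnedSignal, k: int = 2, seed: int = 0, flank_fraction: float = 0.25
):
    """Cluster sites by H3K27me3 shape; cluster 1 = higher mean flank signal.

    Returns ``(labels, degenerate)`` where labels is a Series of 1-based
    cluster numbers ordered by decreasing mean signal in the outer
    ``flank_fraction`` of bins on each side, and ``degenerate`` flags an
    all-identical input matrix (a single effective cluster).
    """
    X = signal.matrix.dropna(axis=0)
    if len(X) and np.allclose(X.to_numpy(), X.to_numpy()[0]):
        return pd.Series(1, index=X.index, name="cluster"), True
    labels, centroids, _ = kmeans_cluster(X.to_numpy(), k=k, seed=seed)
    n_bins = X.shape[1]
    n_flank = max(1, int(round(n_bins * flank_fraction)))
    flank_cols = np.r_[0:n_flank, n_bins - n_flank : n_bins]
    flank_means = centroids[:, flank_cols].mean(axis=1)
    order = np.argsort(-flank_means)  # cluster 1 = strongest flanks
    renumber = {int(old): rank + 1 for rank, old in enumerate(order)}
    return (
        pd.Series([renumber[int(l)] for l in labels], index=X.index,
                  name="cluster"),
        False,
    )


def standardize_track(track: pd.DataFrame) -> pd.DataFrame:
    """z-score a track against its genome-wide length-weighted moments."""
    tr = _Track(track)
    mean, sd = tr.length_weighted_moments()
    out = track.copy()
    out["value"] = 0.0 if sd == 0 else (track["value"] - mean) / sd
    return out


def gene_body_score(
    track: pd.DataFrame,
    genes: list[GeneModel],
    standardize: bool = True,
) -> pd.DataFrame:
    """Mean z-score of a track across each gene body.

    Genes without any covered base are omitted from the table (their ids
    appear in the caller's report via the difference of gene sets).
    """
    if standardize:
        track = standardize_track(track)
    tr = _Track(track)
    rows = []
    for gene in genes:
        score = tr.window_mean(gene.chrom, gene.body.start, gene.body.end)
        if not np.isnan(score):
            rows.append({"gene_id": gene.gene_id, "score": score})
    return pd.DataFrame(rows, columns=["gene_id", "score"])


def methylation_contrast(
    maternal: BinnedSignal,
    paternal: BinnedSignal,
    site_groups: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site mean methylation per allele, compared across site groups.

    ``site_groups`` maps site name -> group (e.g. MEG- / PEG- /
    non-imprinted-associated) and must cover every site in the matrices.
    Returns the per-site table and pairwise Mann-Whitney comparisons both
    across groups within each allele and between alleles within each group.
    """
    rows = []
    for allele, signal in (("maternal", maternal), ("paternal", paternal)):
        means = signal.matrix.mean(axis=1, skipna=True)
        for site, value in means.items():
            if site not in site_groups:
                raise ValueError(f"site {site!r} missing from site_groups")
            rows.append(
                {"site": site, "allele": allele,
                 "group": site_groups[site], "mean_signal": float(value)}
            )
    table = pd.DataFrame(rows)
    groups = sorted(table["group"].unique())
    tests = []
    for allele in ("maternal", "paternal"):
        sub = table[table["allele"] == allele]
        named = {
            g: sub.loc[sub["group"] == g, "mean_signal"].to_numpy()
            for g in groups
        }
        named = {g: v for g, v in named.items() if len(v)}
        if len(named) >= 2:
            mw = compare_groups_mw(named)
            mw.insert(0, "contrast", f"within_{allele}")
            tests.append(mw)
    for g in groups:
        sub = table[table["group"] == g]
        named = {
            allele: sub.loc[sub["allele"] == allele, "mean_signal"].to_numpy()
            for allele in ("maternal", "paternal")
        }
        if all(len(v) for v in named.values()):
            mw = compare_groups_mw(named)
            mw.insert(0, "contrast", f"alleles_in_{g}")
            tests.append(mw)
    test_table = (
        pd.concat(tests, ignore_index=True) if tests else pd.DataFrame()
    )
    return table, test_table


def plot_metagene(metagenes: dict[str, pd.Series], path) -> None:
    """Metagene profiles (one line per channel) as an SVG/PNG figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for name, series in metagenes.items():
        ax.plot(series.index, series.to_numpy(), label=name)
    ax.axvline(0, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("distance from site center (bp)")
    ax.set_ylabel("mean signal")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_heatmap(signal: BinnedSignal, labels: pd.Series, path) -> None:
    """Cluster-sorted heatmap of the signal matrix; rows ordered within
    cluster by decreasing mean signal (deterministic)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    X = signal.matrix.loc[labels.index]
    order = (
        pd.DataFrame({"cluster": labels, "mean": X.mean(axis=1)})
        .sort_values(["cluster", "mean"], ascending=[True, False])
        .index
    )
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(X.loc[order].to_numpy(), aspect="auto", cmap="viridis",
              interpolation="nearest")
    ax.set_xlabel("bin")
    ax.set_ylabel("binding sites (cluster-sorted)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
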