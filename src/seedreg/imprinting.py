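"""Parental expression ratios and ploidy-aware MEG/PEG classification.

In the triploid endosperm of a diploid (2x) seed, a biallelically expressed
gene is expected to show two maternal reads per three total reads (maternal
fraction 2/3, maternal:paternal odds 2:1). In triploid seeds from a
paternal-excess cross the extra paternal genome shifts the expectation to
two maternal reads per four total reads (fraction 1/2, odds 1:1). A gene is
called maternally expressed (MEG) or paternally expressed (PEG) when its
mean maternal fraction deviates four-fold from the expected ratio toward
maternal or paternal accumulation. The four-fold deviation is applied on
the maternal:paternal odds scale — the only scale on which both thresholds
stay inside (0, 1) for any expected ratio: with expected odds w the MEG
threshold is 4w/(4w+1) and the PEG threshold (w/4)/(w/4+1), i.e. 8/9 and
1/3 for 2x seeds, 4/5 and 1/5 for 3x paternal-excess seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CROSS_2X = "2x"
CROSS_3X = "3x_paternal_excess"
EXPECTED_MATERNAL_FRACTION = {CROSS_2X: 2 / 3, CROSS_3X: 1 / 2}


@dataclass(frozen=True)
class ImprintingThresholds:
    cross: str
    expected_fraction: float
    fold: float
    meg_min_fraction: float
    peg_max_fraction: float


@dataclass(frozen=True)
class ImprintingCall:
    gene_id: str
    cross: str
    maternal_fraction: float  # nan when insufficient data
    label: str  # MEG | PEG | biallelic | insufficient_data


def imprinting_thresholds(cross: str, fold: float = 4.0) -> ImprintingThresholds:
    """MEG/PEG maternal-fraction thresholds from a fold deviation in odds."""
    if cross not in EXPECTED_MATERNAL_FRACTION:
        raise ValueError(
            f"unknown cross {cross!r}; expected one of {sorted(EXPECTED_MATERNAL_FRACTION)}"
        )
    if fold < 1:
        raise ValueError("fold must be >= 1")
    expected = EXPECTED_MATERNAL_FRACTION[cross]
    odds = expected / (1 - expected)
    meg_odds = odds * fold
    peg_odds = odds / fold
    return ImprintingThresholds(
        cross=cross,
        expected_fraction=expected,
        fold=fold,
        meg_min_fraction=meg_odds / (meg_odds + 1),
        peg_max_fraction=peg_odds / (peg_odds + 1),
    )


def parental_ratio(
    records: pd.DataFrame, min_informative: int = 10
) -> pd.DataFrame:
    """Mean maternal fraction per gene and cross.

    ``records`` columns: gene_id, cross, replicate, maternal, paternal.
    Each replicate contributes maternal / (maternal + paternal); replicates
    with fewer than ``min_informative`` informative reads are excluded, and
    the gene fraction is the unweighted mean of the surviving replicates
    (nan when none survive).
    """
    required = {"gene_id", "cross", "replicate", "maternal", "paternal"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"count table lacks columns: {sorted(missing)}")
    if (records["maternal"] < 0).any() or (records["paternal"] < 0).any():
        raise ValueError("negative read counts")
    df = records.copy()
    df["total"] = df["maternal"] + df["paternal"]
    df["fraction"] = np.where(
        df["total"] >= max(min_informative, 1),
        df["maternal"] / df["total"].where(df["total"] > 0),
        np.nan,
    )
    out = (
        df.groupby(["gene_id", "cross"], sort=True)["fraction"]
        .mean()  # skips excluded replicates; all-nan -> nan
        .reset_index()
        .rename(columns={"fraction": "maternal_fraction"})
    )
    return out


def classify_imprinting(
    fractions: pd.DataFrame, fold: float = 4.0
) -> tuple[list[ImprintingCall], pd.DataFrame]:
    """Label each gene x cross as MEG / PEG / biallelic.

    Thresholds are inclusive: fraction >= the MEG minimum is a MEG, fraction
    <= the PEG maximum a PEG. Also returns a 2x-versus-3x label
    cross-tabulation for genes measured in both crosses.
    """
    thresholds = {c: imprinting_thresholds(c, fold) for c in
                  EXPECTED_MATERNAL_FRACTION}
    calls = []
    for row in fractions.itertuples(index=False):
        f = row.maternal_fraction
        thr = thresholds[row.cross]
        if f is None or np.isnan(f):
            label = "insufficient_data"
        else:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"maternal fraction {f} outside [0, 1]")
            if f >= thr.meg_min_fraction:
                label = "MEG"
            elif f <= thr.peg_max_fraction:
                label = "PEG"
            else:
                label = "biallelic"
        calls.append(ImprintingCall(row.gene_id, row.cross, float(f) if f == f else float("nan"), label))
    call_df = pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "cross": [c.cross for c in calls],
            "label": [c.label for c in calls],
        }
    )
    wide = call_df.pivot(index="gene_id", columns="cross", values="label")
    if {CROSS_2X, CROSS_3X} <= set(wide.columns):
        summary = (
            wide.dropna()
            .groupby([CROSS_2X, CROSS_3X])
            .size()
            .reset_index(name="n_genes")
        )
    else:
        summary = pd.DataFrame(columns=[CROSS_2X, CROSS_3X, "n_genes"])
    return calls, summary


def calls_table(calls: list[ImprintingCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "cross": [c.cross for c in calls],
            "maternal_fraction": [c.maternal_fraction for c in calls],
            "label": [c.label for c in calls],
        }
    )
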