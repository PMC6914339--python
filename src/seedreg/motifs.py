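"""CArG-box-like motif scanning and motif-density statistics.

The default motif is the canonical MADS-box CArG-box consensus CC(A/T)6GG,
a 10-bp IUPAC pattern whose match class is closed under reverse complement.
A scan reports every window matching the consensus perfectly or within one
substitution of a perfect word ("nearly perfect"), deduplicated so that a
palindromic double-strand hit yields a single record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, IntervalSet

PERFECT_CARG = "CCWWWWWWGG"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
# base encoding: A=0 C=1 G=2 T=3, anything else (N) = 4 and never matches
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class Motif:
    """An IUPAC consensus motif, optionally backed by a weight matrix."""

    id: str = "CArG"
    consensus: str = PERFECT_CARG
    pwm: np.ndarray | None = None  # shape (L, 4) log-odds, rows ordered ACGT
    pwm_threshold: float | None = None

    def __post_init__(self) -> None:
        if len(self.consensus) < 4:
            raise ValueError("motif consensus shorter than 4 bases")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC codes in consensus: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.consensus)

    def allowed_matrix(self, reverse_complement: bool = False) -> np.ndarray:
        """(L, 5) boolean: is base code b allowed at position j? N never is."""
        consensus = self.consensus.upper()
        if reverse_complement:
            consensus = "".join(
                IUPAC_COMPLEMENT[c] for c in reversed(consensus)
            )
        allowed = np.zeros((len(consensus), 5), dtype=bool)
        for j, code in enumerate(consensus):
            for base in IUPAC[code]:
                allowed[j, "ACGT".index(base)] = True
        return allowed

    def n_perfect_words(self) -> int:
        return int(np.prod([len(IUPAC[c]) for c in self.consensus.upper()]))


IUPAC_COMPLEMENT = {
    code: "".join(
        sorted(c for c in "ACGT" if _COMPLEMENT[c] in IUPAC[code])
    )
    for code in IUPAC
}
# map complement base-set back to its IUPAC letter
_SET_TO_CODE = {frozenset(v): k for k, v in IUPAC.items()}
IUPAC_COMPLEMENT = {
    code: _SET_TO_CODE[frozenset(IUPAC_COMPLEMENT[code])] for code in IUPAC
}


@dataclass(frozen=True)
class MotifMatch:
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str
    match_class: str  # perfect | nearly_perfect

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand,
                               self.match_class)


def _window_distances(seq_codes: np.ndarray, allowed: np.ndarray) -> np.ndarray:
    """Per-window count of positions violating the positional base sets.

    Because the consensus constrains each position independently, this count
    equals the minimal Hamming distance from the window to the full set of
    words spelled by the consensus.
    """
    length = allowed.shape[0]
    n_windows = len(seq_codes) - length + 1
    if n_windows <= 0:
        return np.zeros(0, dtype=np.int32)
    dist = np.zeros(n_windows, dtype=np.int32)
    for j in range(length):
        dist += ~allowed[j, seq_codes[j : j + n_windows]]
    return dist


def scan_consensus(
    sequences: dict[str, str],
    motif: Motif | None = None,
    include_nearly_perfect: bool = True,
) -> list[MotifMatch]:
    """Scan both strands of each sequence for consensus matches.

    Each genomic window is reported at most once: when the forward and the
    reverse-complement reading both match (as every perfect hit of a
    palindromic consensus class does), the record carries the ``+`` strand.
    """
    motif = motif or Motif()
    fwd_allowed = motif.allowed_matrix(reverse_complement=False)
    rev_allowed = motif.allowed_matrix(reverse_complement=True)
    max_dist = 1 if include_nearly_perfect else 0
    matches = []
    for name in sorted(sequences):
        seq = sequences[name].upper()
        codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        d_fwd = _window_distances(codes, fwd_allowed)
        d_rev = _window_distances(codes, rev_allowed)
        if len(d_fwd) == 0:
            continue
        best = np.minimum(d_fwd, d_rev)
        for pos in np.flatnonzero(best <= max_dist):
            strand = "+" if d_fwd[pos] <= d_rev[pos] else "-"
            match_class = "perfect" if best[pos] == 0 else "nearly_perfect"
            matches.append(
                MotifMatch(name, int(pos), int(pos) + len(motif), strand,
                           seq[pos : pos + len(motif)], match_class)
            )
    return matches


def classify_match(word: str, motif: Motif | None = None) -> str:
    """Classify a single k-mer as perfect / nearly_perfect / none.

    The distance is the minimum over both reading orientations of the Hamming
    distance to the nearest word spelled by the consensus; N counts as a
    mismatch at its position.
    """
    motif = motif or Motif()
    if len(word) != len(motif):
        raise ValueError(
            f"word length {len(word)} does not match motif length {len(motif)}"
        )
    codes = _CODE[np.frombuffer(word.upper().encode(), dtype=np.uint8)]
    dist = min(
        int(_window_distances(codes, motif.allowed_matrix(False))[0]),
        int(_window_distances(codes, motif.allowed_matrix(True))[0]),
    )
    if dist == 0:
        return "perfect"
    if dist == 1:
        return "nearly_perfect"
    return "none"


def motif_density(
    regions_by_class: dict[str, IntervalSet],
    matches: list[MotifMatch],
    motif_length: int = len(PERFECT_CARG),
    yates_correction: bool = False,
):
    """Per-class motif densities plus pairwise chi-square tests.

    A match is attributed to a region class when its window lies wholly inside
    one of the class intervals. Density is occurrences per base of the class;
    the chi-square tests compare, between classes, the proportion of bases
    that fall inside motif occurrences versus all remaining bases.

    Returns ``(density_table, chi2_table)`` as DataFrames.
    """
    rows = []
    for name in sorted(regions_by_class):
        regions = regions_by_class[name]
        total = regions.total_length()
        if total == 0:
            raise ValueError(f"region class {name!r} has zero total length")
        starts = np.array([m.start for m in matches], dtype=np.int64)
        ends = np.array([m.end for m in matches], dtype=np.int64)
        count = 0
        for chrom in regions.chroms:
            sel = np.array([m.chrom == chrom for m in matches], dtype=bool)
            if not sel.any():
                continue
            for iv in regions.by_chrom(chrom):
                count += int(
                    (sel & (starts >= iv.start) & (ends <= iv.end)).sum()
                )
        rows.append(
            {
                "region_class": name,
                "bases": total,
                "matches": count,
                "density_per_bp": count / total,
                "motif_base_fraction": min(1.0, count * motif_length / total),
            }
        )
    table = pd.DataFrame(rows)

    chi_rows = []
    for i in range(len(table)):
        for j in range(i + 1, len(table)):
            a, b = table.iloc[i], table.iloc[j]
            contingency = np.array(
                [
                    [a["matches"] * motif_length,
                     a["bases"] - a["matches"] * motif_length],
                    [b["matches"] * motif_length,
                     b["bases"] - b["matches"] * motif_length],
                ]
            )
            if contingency[:, 0].sum() == 0 or (contingency == contingency[0]).all():
                chi2, p = 0.0, 1.0
            else:
                chi2, p, _, _ = stats.chi2_contingency(
                    contingency, correction=yates_correction
                )
            chi_rows.append(
                {
                    "class_a": a["region_class"],
                    "class_b": b["region_class"],
                    "chi2": chi2,
                    "p_value": p,
                }
            )
    return table, pd.DataFrame(chi_rows)
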