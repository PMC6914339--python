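"""Genomic interval model and interval algebra.

All coordinates are 0-based, half-open ``[start, end)`` on named sequences.
Touching intervals (``a.end == b.start``) do not overlap. Iteration order of
an :class:`IntervalSet` is deterministic: ``(chrom, start, end, name)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A located span on a named sequence.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``strand`` is one of
    ``+``, ``-`` or ``.`` (unstranded, e.g. ChIP peaks and TE copies).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def sort_key(self):
        return (self.chrom, self.start, self.end, self.name)


class IntervalSet:
    """Ordered, per-chromosome-indexed collection of :class:`GenomicInterval`.

    Intervals are kept sorted by ``(chrom, start, end, name)`` so that outputs
    derived from a set are reproducible across runs.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._intervals: list[GenomicInterval] = sorted(
            intervals, key=GenomicInterval.sort_key
        )
        self._by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self._intervals:
            self._by_chrom.setdefault(iv.chrom, []).append(iv)
        # per-chrom numpy start/end arrays, sorted by start (build lazily)
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)

    def __getitem__(self, i):
        return self._intervals[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def by_chrom(self, chrom: str) -> list[GenomicInterval]:
        return self._by_chrom.get(chrom, [])

    def total_length(self) -> int:
        return sum(len(iv) for iv in self._intervals)

    def merged(self) -> "IntervalSet":
        """Union of the set: overlapping intervals collapsed per chromosome."""
        out: list[GenomicInterval] = []
        for chrom in self.chroms:
            cur_s = cur_e = None
            for iv in self._by_chrom[chrom]:
                if cur_s is None:
                    cur_s, cur_e = iv.start, iv.end
                elif iv.start < cur_e:  # strict: touching intervals stay separate
                    cur_e = max(cur_e, iv.end)
                else:
                    out.append(GenomicInterval(chrom, cur_s, cur_e))
                    cur_s, cur_e = iv.start, iv.end
            if cur_s is not None:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
        return IntervalSet(out)

    def _merged_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if self._arrays is None:
            self._arrays = {}
            for chrom in self.chroms:
                m = self.merged().by_chrom(chrom)
                self._arrays[chrom] = (
                    np.array([iv.start for iv in m], dtype=np.int64),
                    np.array([iv.end for iv in m], dtype=np.int64),
                )
        return self._arrays

    def overlaps_any(self, starts: np.ndarray, ends: np.ndarray, chrom: str) -> np.ndarray:
        """Vectorised query: does each [start, end) overlap any member interval?

        Uses the merged (disjoint, sorted) representation: the first member
        whose end exceeds ``start`` is the only candidate that can overlap.
        """
        arrays = self._merged_arrays().get(chrom)
        out = np.zeros(len(starts), dtype=bool)
        if arrays is None or len(arrays[0]) == 0:
            return out
        m_starts, m_ends = arrays
        idx = np.searchsorted(m_ends, starts, side="right")
        valid = idx < len(m_starts)
        out[valid] = m_starts[idx[valid]] < ends[valid]
        return out


def intersect(a: IntervalSet, b: IntervalSet, min_overlap: int = 1):
    """All overlapping pairs between two sets.

    Returns a list of ``(interval_from_a, interval_from_b, overlap_bases)``
    with overlap >= ``min_overlap``, under half-open semantics. Pair order
    follows the deterministic iteration order of ``a`` then ``b``.
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    pairs = []
    for chrom in a.chroms:
        bs = b.by_chrom(chrom)
        if not bs:
            continue
        b_starts = np.array([iv.start for iv in bs], dtype=np.int64)
        for iv in a.by_chrom(chrom):
            # candidates: b.start < a.end (prefix of the start-sorted list)
            hi = int(np.searchsorted(b_starts, iv.end, side="left"))
            for jv in bs[:hi]:
                ov = iv.overlap_length(jv)
                if ov >= min_overlap:
                    pairs.append((iv, jv, ov))
    return pairs


def overlap_fraction(query: IntervalSet, subject: IntervalSet) -> float:
    """Fraction of query intervals that overlap at least one subject interval."""
    if len(query) == 0:
        raise ValueError("overlap_fraction is undefined for an empty query set")
    n_hit = 0
    for chrom in query.chroms:
        qs = query.by_chrom(chrom)
        starts = np.array([iv.start for iv in qs], dtype=np.int64)
        ends = np.array([iv.end for iv in qs], dtype=np.int64)
        n_hit += int(subject.overlaps_any(starts, ends, chrom).sum())
    return n_hit / len(query)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its body span and strand-aware transcription start site."""

    gene_id: str
    body: GenomicInterval
    strand: str = field(default="+")

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")

    @property
    def chrom(self) -> str:
        return self.body.chrom

    @property
    def tss(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end - 1

    def promoter(self, span: int = 3000) -> GenomicInterval | None:
        """Upstream span of length <= ``span`` in gene orientation, clipped at 0."""
        if self.strand == "+":
            start, end = max(0, self.tss - span), self.tss
        else:
            start, end = self.tss + 1, self.tss + 1 + span
        if start >= end:
            return None
        return GenomicInterval(self.chrom, start, end, self.strand, self.gene_id)
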