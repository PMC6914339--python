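"""Pairwise homology of motif-carrying TE sequences and cluster merging.

Pairs of sequences are compared by optimal Smith-Waterman local alignment
under BLASTN-style scoring (match +2, mismatch -3, affine gap cost
5 + 2 per gapped base). Exhaustive dynamic programming replaces a seeded
word heuristic: at these sequence counts the exact optimum is affordable
and can only recover more homologies, so the biological decision is carried
entirely by the homology thresholds. A pair is homologous within a genome
when the alignment covers at least 9 bases of the 10-base motif on the
reference sequence, extends over more than 30 columns, and exceeds 70%
identity; across species when it spans more than 100 nt of the reference
TE with more than 60% identity. Homologous pairs are merged into clusters
as connected components of the homology graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class AlignmentScoring:
    """BLASTN-style scores; gap penalties are positive costs."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("match must be positive and mismatch negative")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be positive")


@dataclass(frozen=True)
class HomologyThresholds:
    """Strictness follows the published wording exactly: 'longer than 30 bp'
    and 'more than 70% identity' are strict inequalities, the 9-of-10 motif
    coverage is non-strict."""

    profile: str = "intra_genome"
    min_motif_coverage: int = 9
    alignment_length_gt: int = 30
    identity_gt: float = 70.0
    cross_span_gt: int = 100
    cross_identity_gt: float = 60.0


@dataclass
class LocalAlignment:
    score: float
    a_span: tuple[int, int]  # half-open span on the first (reference) sequence
    b_span: tuple[int, int]
    n_columns: int
    n_identical: int
    a_segments: list[tuple[int, int]] = field(default_factory=list)

    @property
    def identity(self) -> float:
        """Percent identical columns; gap columns count as non-identical."""
        return 100.0 * self.n_identical / self.n_columns if self.n_columns else 0.0


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            # N is scored as a mismatch against everything, itself included
            matrix[x, y] = (
                scoring.match if (x == y and x != "N") else scoring.mismatch
            )
    aligner.substitution_matrix = matrix
    # first gapped base costs open + extend, later ones extend only,
    # so a length-k gap costs open + k * extend as in BLASTN
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def local_align(
    a: str, b: str, scoring: AlignmentScoring | None = None
) -> LocalAlignment:
    """Optimal affine-gap local alignment of two nucleotide sequences."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    bad = (set(a) | set(b)) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    scoring = scoring or AlignmentScoring()
    aligner = _make_aligner(scoring)
    alignments = aligner.align(a, b)
    if len(alignments) == 0 or alignments.score <= 0:
        return LocalAlignment(0.0, (0, 0), (0, 0), 0, 0)
    aln = alignments[0]  # canonical traceback of the aligner: deterministic
    a_segs, b_segs = (
        [tuple(map(int, seg)) for seg in block] for block in aln.aligned
    )
    n_cols = 0
    n_ident = 0
    for i, ((a0, a1), (b0, b1)) in enumerate(zip(a_segs, b_segs)):
        n_cols += a1 - a0
        n_ident += sum(a[a0 + j] == b[b0 + j] != "N" for j in range(a1 - a0))
        if i + 1 < len(a_segs):
            n_cols += (a_segs[i + 1][0] - a1) + (b_segs[i + 1][0] - b1)
    return LocalAlignment(
        float(alignments.score),
        (a_segs[0][0], a_segs[-1][1]),
        (b_segs[0][0], b_segs[-1][1]),
        n_cols,
        n_ident,
        a_segs,
    )


def pair_homology(
    aln: LocalAlignment,
    motif_span: tuple[int, int] | None = None,
    thresholds: HomologyThresholds | None = None,
) -> bool:
    """Apply the homology thresholds to one alignment.

    ``motif_span`` is the half-open motif interval on the reference (first)
    sequence; required for the intra-genome profile.
    """
    thr = thresholds or HomologyThresholds()
    if thr.profile == "intra_genome":
        if motif_span is None:
            raise ValueError("intra_genome homology requires the motif span")
        covered = sum(
            max(0, min(s1, motif_span[1]) - max(s0, motif_span[0]))
            for s0, s1 in aln.a_segments
        )
        return (
            covered >= thr.min_motif_coverage
            and aln.n_columns > thr.alignment_length_gt
            and aln.identity > thr.identity_gt
        )
    if thr.profile == "cross_species":
        ref_span = aln.a_span[1] - aln.a_span[0]
        return ref_span > thr.cross_span_gt and aln.identity > thr.cross_identity_gt
    raise ValueError(f"unknown homology profile {thr.profile!r}")


def cluster_pairs(
    elements: list[str], pairs: list[tuple[str, str]]
) -> dict[str, str]:
    """Connected components of the homology graph.

    Returns element -> cluster id, the cluster id being the lexicographically
    smallest member. Elements without a homologous partner are singletons.
    """
    known = set(elements)
    graph = nx.Graph()
    graph.add_nodes_from(elements)
    for a, b in pairs:
        if a not in known or b not in known:
            raise ValueError(f"pair ({a}, {b}) references unknown element")
        graph.add_edge(a, b)
    assignment = {}
    for component in nx.connected_components(graph):
        cluster_id = min(component)
        for member in component:
            assignment[member] = cluster_id
    return assignment


def homology_clusters(
    sequences: dict[str, str],
    motif_spans: dict[str, tuple[int, int]],
    scoring: AlignmentScoring | None = None,
    thresholds: HomologyThresholds | None = None,
):
    """All-vs-all homology of motif-carrying sequences, then clustering.

    Returns ``(pair_table, clusters)``: a DataFrame of every evaluated pair
    with its alignment statistics and verdict, and the element -> cluster
    mapping from merging homologous pairs.
    """
    thr = thresholds or HomologyThresholds()
    names = sorted(sequences)
    rows = []
    edges = []
    for a, b in itertools.combinations(names, 2):
        aln = local_align(sequences[a], sequences[b], scoring)
        verdict = pair_homology(aln, motif_spans.get(a), thr)
        covered = sum(
            max(0, min(s1, motif_spans[a][1]) - max(s0, motif_spans[a][0]))
            for s0, s1 in aln.a_segments
        ) if a in motif_spans else np.nan
        rows.append(
            {
                "seq_a": a,
                "seq_b": b,
                "score": aln.score,
                "alignment_columns": aln.n_columns,
                "identity_pct": aln.identity,
                "motif_coverage": covered,
                "homologous": verdict,
            }
        )
        if verdict:
            edges.append((a, b))
    clusters = cluster_pairs(names, edges)
    return pd.DataFrame(rows), clusters
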