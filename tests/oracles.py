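"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: quadratic interval
scans, regex/Hamming motif enumeration, a naive full-matrix affine-gap DP,
exhaustive hypergeometric sums and permutation enumeration.
"""

from __future__ import annotations

import itertools
import math
import re

import numpy as np

# --- intervals -------------------------------------------------------------

def brute_force_pairs(a, b, min_overlap=1):
    """All overlapping interval pairs by quadratic scan."""
    pairs = []
    for iv in a:
        for jv in b:
            if iv.chrom != jv.chrom:
                continue
            ov = min(iv.end, jv.end) - max(iv.start, jv.start)
            if ov >= min_overlap:
                pairs.append((iv, jv, ov))
    return pairs


def brute_force_overlap_fraction(query, subject):
    n_hit = sum(
        any(
            iv.chrom == jv.chrom and iv.start < jv.end and jv.start < iv.end
            for jv in subject
        )
        for iv in query
    )
    return n_hit / len(query)


# --- motifs ----------------------------------------------------------------

IUPAC_RE = {
    "A": "A", "C": "C", "G": "G", "T": "T", "W": "[AT]", "S": "[CG]",
    "R": "[AG]", "Y": "[CT]", "K": "[GT]", "M": "[AC]", "B": "[CGT]",
    "D": "[AGT]", "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}
_COMP = str.maketrans("ACGTWSRYKMBDHVN", "TGCAWSYRMKVHDBN")


def consensus_words(consensus):
    """Every concrete word spelled by an IUPAC consensus."""
    from seedreg.motifs import IUPAC  # the code table only, not the scanner

    return ["".join(w) for w in itertools.product(*(IUPAC[c] for c in consensus))]


def revcomp(seq):
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def brute_force_scan(seq, consensus, max_mismatches=1):
    """Regex/Hamming enumeration over both strands of one sequence.

    Returns {(start, strand_of_min, class)} with palindromic double-strand
    hits collapsed to one record (forward strand wins ties), mirroring the
    stated deduplication rule. N counts as a mismatch.
    """
    words = consensus_words(consensus)
    rc_words = [revcomp(w) for w in words]
    L = len(consensus)
    out = {}
    for pos in range(len(seq) - L + 1):
        window = seq[pos : pos + L]
        d_fwd = min(sum(a != b for a, b in zip(window, w)) for w in words)
        d_rev = min(sum(a != b for a, b in zip(window, w)) for w in rc_words)
        d = min(d_fwd, d_rev)
        if d > max_mismatches:
            continue
        strand = "+" if d_fwd <= d_rev else "-"
        klass = "perfect" if d == 0 else "nearly_perfect"
        out[pos] = (strand, klass)
    return out


def hamming_ball_lookup(consensus):
    """word -> (min Hamming distance to the consensus class, <=1 only).

    Built by explicit enumeration: the 2^6 perfect words of CC(W)6GG-like
    consensi plus every single-substitution neighbour.
    """
    table = {}
    for word in consensus_words(consensus):
        table[word] = 0
    for word in list(table):
        for i, base in itertools.product(range(len(word)), "ACGT"):
            neighbour = word[:i] + base + word[i + 1 :]
            if neighbour not in table:
                table[neighbour] = 1
    return table


def brute_force_scan_fast(seq, consensus):
    """Dictionary-lookup variant of :func:`brute_force_scan` for long
    sequences; identical output by construction of the Hamming ball."""
    ball = hamming_ball_lookup(consensus)
    rc_ball = {revcomp(w): d for w, d in ball.items()}
    L = len(consensus)
    out = {}
    for pos in range(len(seq) - L + 1):
        window = seq[pos : pos + L]
        d_fwd = ball.get(window, 2)
        d_rev = rc_ball.get(window, 2)
        d = min(d_fwd, d_rev)
        if d > 1:
            continue
        strand = "+" if d_fwd <= d_rev else "-"
        out[pos] = (strand, "perfect" if d == 0 else "nearly_perfect")
    return out


def chi2_closed_form(table):
    """Sum (O - E)^2 / E for a 2x2 table, hand-evaluated."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            e = row[i] * col[j] / total
            chi2 += (table[i, j] - e) ** 2 / e
    return chi2


# --- alignment -------------------------------------------------------------

def affine_local_align_score(a, b, match=2, mismatch=-3, gap_open=5,
                             gap_extend=2):
    """Naive full-matrix Smith-Waterman with affine gaps.

    A gap of length k costs gap_open + k * gap_extend (BLASTN convention).
    Returns the optimal local score.
    """
    n, m = len(a), len(b)
    neg = -10 ** 9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    F = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          F[i][j - 1] - gap_extend)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def transitive_closure_clusters(elements, pairs):
    """Connected components by repeated relabelling (Floyd-Warshall style)."""
    label = {e: e for e in elements}
    changed = True
    while changed:
        changed = False
        for a, b in pairs:
            lo = min(label[a], label[b])
            for x in (a, b):
                if label[x] != lo:
                    label[x] = lo
                    changed = True
        # propagate through chains
        for e in elements:
            if label[label[e]] != label[e]:
                label[e] = label[label[e]]
                changed = True
    return label


# --- statistics ------------------------------------------------------------

def hypergeom_upper_tail(k, n, K, N):
    """P(X >= k) summed term by term from the pmf definition."""
    total = 0
    for x in range(k, min(n, K) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / math.comb(N, n)


def hypergeom_enumeration(k, n, K, N):
    """P(X >= k) by literal enumeration of all C(N, n) draws."""
    population = [1] * K + [0] * (N - K)
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return hits / total


def mannwhitney_exact_two_sided(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all label assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)

    u_obs = u_stat(range(n1))
    mu = n1 * (len(pooled) - n1) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_stat(idx) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total
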