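"""Independent brute-force oracles used only by the test suite.

Each oracle is written from the definition of the operation it checks, with
no code shared with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def brute_force_orfs(seq: str, starts: set[str], min_len_aa: int):
    """Six-frame ORF set from the definition: per frame, split at stops; each
    stop-bounded segment yields one ORF from its first start codon to the stop
    (inclusive) or, at the contig edge, to the last complete codon (partial).

    Returns a set of (start, end, strand, partial) in forward-strand
    0-based half-open coordinates.
    """
    out = set()
    n = len(seq)
    for strand, s in (("+", seq), ("-", rc(seq))):
        for frame in range(3):
            codon_starts = list(range(frame, n - 2, 3))
            segment: list[int] = []
            for ci in codon_starts:
                codon = s[ci : ci + 3]
                if codon in STOPS:
                    firsts = [p for p in segment if s[p : p + 3] in starts]
                    if firsts:
                        a, b = firsts[0], ci + 3
                        if (b - a) // 3 - 1 >= min_len_aa:
                            out.add(_fwd(a, b, strand, n) + (False,))
                    segment = []
                else:
                    segment.append(ci)
            firsts = [p for p in segment if s[p : p + 3] in starts]
            if firsts:
                a = firsts[0]
                b = codon_starts[-1] + 3 if codon_starts else frame
                if (b - a) // 3 >= min_len_aa:
                    out.add(_fwd(a, b, strand, n) + (True,))
    return out


def _fwd(a: int, b: int, strand: str, n: int):
    if strand == "+":
        return (a, b, strand)
    return (n - b, n - a, strand)


def gotoh_local(query: str, subject: str, matrix, gap_open: int, gap_extend: int) -> float:
    """Quadratic-time affine-gap Smith–Waterman best score.

    Gap of length k costs gap_open + k * gap_extend (both positive).
    """
    m, n = len(query), len(subject)
    NEG = -1e9
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)  # gap in subject (moving along query)
    F = np.full((m + 1, n + 1), NEG)  # gap in query
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_extend, F[i][j - 1] - gap_extend)
            s = matrix[query[i - 1]][subject[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return float(best)


def midranks(values) -> list[float]:
    """Rank with ties averaged, 1-based, from the definition."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def anosim_exhaustive(dmatrix: np.ndarray, labels: list[str]):
    """Clarke's R and exact permutation p by enumerating every distinct
    arrangement of the label multiset."""
    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    dist = [dmatrix[i][j] for i, j in pairs]
    ranks = midranks(dist)
    denom = n * (n - 1) / 4

    def r_of(lab):
        within = [ranks[k] for k, (i, j) in enumerate(pairs) if lab[i] == lab[j]]
        between = [ranks[k] for k, (i, j) in enumerate(pairs) if lab[i] != lab[j]]
        return (sum(between) / len(between) - sum(within) / len(within)) / denom

    r_obs = r_of(labels)
    arrangements = sorted(set(itertools.permutations(labels)))
    count = sum(1 for arr in arrangements if r_of(arr) >= r_obs - 1e-12)
    return r_obs, count / len(arrangements), len(arrangements)
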