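"""Desk-scale local alignment with BLAST-style bit scores and e-values.

A Smith–Waterman stand-in for the external protein search tools normally run
on full metatranscriptomes. The pipeline accepts externally produced tabular
hit files; this module exists so the whole analysis can run end-to-end on
synthetic data with no external binaries. Bit scores follow the
Karlin–Altschul convention bit = (lambda * raw - ln K) / ln 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import brentq


@dataclass(frozen=True)
class ScoringScheme:
    """Protein scoring: substitution matrix + affine gaps + KA constants.

    ``gap_open``/``gap_extend`` are positive penalties in the BLAST
    convention: a gap of length k costs gap_open + k * gap_extend.
    Defaults are BLOSUM62 11/1 with the gapped Karlin–Altschul constants
    lambda = 0.267 nats and K = 0.041.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and K must be positive")

    @property
    def matrix(self):
        return substitution_matrices.load(self.matrix_name)


@dataclass(frozen=True)
class NucleotideScheme:
    """Nucleotide scoring with match/mismatch + affine gaps.

    lambda is solved from the ungapped score distribution at uniform base
    composition; K defaults to a conventional ungapped value. Used only for
    seed-OTU detection e-values at desk scale.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    k: float = 0.41

    @property
    def lam(self) -> float:
        return _nt_lambda(self.match, self.mismatch)


@lru_cache(maxsize=None)
def _nt_lambda(match: int, mismatch: int) -> float:
    # Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 with uniform p = 1/4.
    def f(lam):
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return brentq(f, 1e-6, 10.0)


@dataclass(frozen=True)
class LocalAlignment:
    """Result of one local alignment."""

    raw_score: float
    pct_identity: float
    align_length: int
    bit_score: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int

    @property
    def has_alignment(self) -> bool:
        return self.align_length > 0


def bit_score(raw: float, scheme) -> float:
    """Karlin–Altschul bit score for a raw alignment score."""
    return (scheme.lam * raw - math.log(scheme.k)) / math.log(2.0)


def evalue(raw: float, query_len: int, subject_len: int, scheme) -> float:
    """Karlin–Altschul expected number of chance alignments scoring >= raw."""
    return scheme.k * query_len * subject_len * math.exp(-scheme.lam * raw)


@lru_cache(maxsize=8)
def _protein_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = scheme.matrix
    # Biopython charges open_gap_score on the first gap position; convert from
    # the BLAST open + k*extend convention.
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


@lru_cache(maxsize=8)
def _nt_aligner(scheme: NucleotideScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def _no_alignment() -> LocalAlignment:
    return LocalAlignment(0.0, 0.0, 0, 0.0, 0, 0, 0, 0)


def _summarize(alignment, query: str, subject: str, raw: float, scheme) -> LocalAlignment:
    qblocks, sblocks = alignment.aligned
    matches = 0
    aligned_cols = 0
    gap_cols = 0
    prev_q = prev_s = None
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        if prev_q is not None:
            gap_cols += (qs - prev_q) + (ss - prev_s)
        aligned_cols += qe - qs
        for a, b in zip(query[qs:qe], subject[ss:se]):
            if a == b:
                matches += 1
        prev_q, prev_s = qe, se
    align_length = aligned_cols + gap_cols
    pct_identity = 100.0 * matches / align_length if align_length else 0.0
    return LocalAlignment(
        raw_score=raw,
        pct_identity=pct_identity,
        align_length=align_length,
        bit_score=bit_score(raw, scheme),
        query_start=int(qblocks[0][0]),
        query_end=int(qblocks[-1][1]),
        subject_start=int(sblocks[0][0]),
        subject_end=int(sblocks[-1][1]),
    )


def align_local(
    query: str, subject: str, scheme: ScoringScheme | None = None
) -> LocalAlignment:
    """Smith–Waterman local protein alignment with affine gaps.

    Returns raw score, percent identity and alignment length measured over the
    reported local alignment (columns including gaps, the BLAST tabular
    convention), plus the bit score. A best score <= 0 means no reportable
    alignment. The first optimal traceback reported by the aligner is used,
    which is deterministic for fixed inputs.
    """
    if not query or not subject:
        raise ValueError("align_local requires non-empty sequences")
    scheme = scheme or ScoringScheme()
    aligner = _protein_aligner(scheme)
    raw = aligner.score(query, subject)
    if raw <= 0:
        return _no_alignment()
    alignment = next(iter(aligner.align(query, subject)))
    return _summarize(alignment, query, subject, raw, scheme)


def align_local_score(query: str, subject: str, scheme: ScoringScheme | None = None) -> float:
    """Raw Smith–Waterman score only (no traceback); fast path for searches."""
    if not query or not subject:
        raise ValueError("align_local requires non-empty sequences")
    aligner = _protein_aligner(scheme or ScoringScheme())
    return float(aligner.score(query, subject))


def align_nucleotide(
    query: str, subject: str, scheme: NucleotideScheme | None = None
) -> LocalAlignment:
    """Local nucleotide alignment used for 18S seed-OTU detection."""
    if not query or not subject:
        raise ValueError("align_nucleotide requires non-empty sequences")
    scheme = scheme or NucleotideScheme()
    aligner = _nt_aligner(scheme)
    raw = aligner.score(query, subject)
    if raw <= 0:
        return _no_alignment()
    alignment = next(iter(aligner.align(query, subject)))
    return _summarize(alignment, query, subject, raw, scheme)
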