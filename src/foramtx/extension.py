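"""Greedy iterative seed extension of 18S rRNA barcode fragments.

Starting from a seed OTU detected by nucleotide similarity against full-length
foraminiferal 18S references, reads are recruited by overlap each iteration
and the consensus is extended on both ends by the column-wise majority of the
recruited overhangs, with per-base coverage tracked throughout. The procedure
automates the semi-manual extension workflow common in assembly GUIs: seed
ends are pre-trimmed (default 10 bp) to drop low-quality terminal bases,
extension runs for at most 20 iterations or until no end grows, interior
positions with sufficient coverage are corrected to the column majority, and
ambiguous majority ties emit IUPAC codes rather than arbitrary picks.

Read mapping here is ungapped (substitution-only): a read is placed at the
offset sharing k-mers with the consensus that maximizes identity over the
overlap. This matches the substitution-only error model of the read
simulator; indel-rich data should be mapped externally.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from statistics import median
from typing import Sequence

import edlib
import numpy as np

from .align import NucleotideScheme, align_nucleotide, evalue as ka_evalue
from .io import Read, ReadPair
from .orfs import revcomp

_IUPAC = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

_BASE_INDEX = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T byte values


class ExtensionError(ValueError):
    pass


@dataclass(frozen=True)
class SeedOtu:
    """A putative 18S fragment selected as an extension seed."""

    id: str
    sequence: str
    source_reference: str | None = None
    source_evalue: float | None = None


@dataclass(frozen=True)
class BarcodeRegion:
    """The ~1000-nt 3' barcoding window on the reference frame."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty barcode region")


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    reads_recruited: int
    left_added: int
    right_added: int


@dataclass
class ExtensionState:
    """Evolving consensus, per-base coverage, and the iteration log."""

    consensus: str
    coverage: np.ndarray
    iteration: int = 0
    left_extended: int = 0
    right_extended: int = 0
    extended: bool = False
    log: list[IterationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.coverage) != len(self.consensus):
            raise ExtensionError("coverage length must equal consensus length")


@dataclass(frozen=True)
class ExtensionParams:
    min_overlap: int = 30
    min_identity: float = 0.95
    max_iterations: int = 20
    min_agreement: int = 3
    rescue_identity: float = 0.80
    chimera_anchor: int = 5
    kmer: int = 15


@dataclass(frozen=True)
class CoverageStats:
    mean: float
    median: float
    min: int
    profile: tuple[int, ...]


@dataclass(frozen=True)
class BarcodeResult:
    sequence: str
    partial: bool
    n_differences: int
    reference_start: int
    reference_end: int


def quality_trim(read: Read, q: int = 20) -> Read:
    """Strip leading/trailing bases below Phred ``q`` (simple end trimmer,
    standing in for external trimmers run with default options)."""
    lo, hi = 0, len(read.sequence)
    while lo < hi and ord(read.quality[lo]) - 33 < q:
        lo += 1
    while hi > lo and ord(read.quality[hi - 1]) - 33 < q:
        hi -= 1
    return Read(read.id, read.sequence[lo:hi], read.quality[lo:hi])


def trim_seed(seed: SeedOtu, trim: int = 10) -> SeedOtu:
    """Remove ``trim`` bases from both ends (possible erroneous terminal
    bases); the seed must be longer than twice the trim."""
    if len(seed.sequence) <= 2 * trim:
        raise ExtensionError(
            f"seed {seed.id!r} is {len(seed.sequence)} nt, too short to trim "
            f"{trim} nt from both ends"
        )
    seq = seed.sequence[trim : len(seed.sequence) - trim] if trim else seed.sequence
    return SeedOtu(seed.id, seq, seed.source_reference, seed.source_evalue)


def detect_seed_otus(
    otu_sequences: Sequence[tuple[str, str]],
    references: Sequence[tuple[str, str]],
    evalue_cutoff: float = 1e-10,
    barcode_only: bool = False,
    window: int = 1000,
    scheme: NucleotideScheme | None = None,
    min_length: int = 100,
) -> list[SeedOtu]:
    """Select OTUs with a nucleotide-similarity hit to any 18S reference at
    e-value <= cutoff.

    With ``barcode_only`` the hit must overlap the reference's 3' barcode
    window (last ``window`` nt). OTUs shorter than ``min_length`` are not
    considered seeds. The built-in local aligner stands in for an external
    nucleotide search at desk scale; e-values follow the Karlin–Altschul
    formula for the scheme.
    """
    if not references:
        raise ValueError("reference 18S set must be non-empty")
    scheme = scheme or NucleotideScheme()
    out = []
    for oid, oseq in otu_sequences:
        if len(oseq) < min_length:
            continue
        best = None
        for rid, rseq in references:
            for q in (oseq, revcomp(oseq)):
                aln = align_nucleotide(q, rseq, scheme)
                if not aln.has_alignment:
                    continue
                ev = ka_evalue(aln.raw_score, len(q), len(rseq), scheme)
                if ev > evalue_cutoff:
                    continue
                if barcode_only and aln.subject_end <= len(rseq) - window:
                    continue
                if best is None or ev < best[0]:
                    best = (ev, rid)
        if best is not None:
            out.append(SeedOtu(oid, oseq, best[1], best[0]))
    return out


def _map_read(seq: str, index: dict, cons: np.ndarray, k: int, min_overlap: int):
    """Best ungapped placement of one oriented read on the consensus.

    Returns (offset, overlap_len, identity) or None if no shared k-mer.
    """
    n = len(seq)
    Lc = cons.size
    offsets: set[int] = set()
    step = max(1, k // 2)
    positions = list(range(0, n - k + 1, step))
    if positions and positions[-1] != n - k:
        positions.append(n - k)
    for p in positions:
        for pos in index.get(seq[p : p + k], ()):
            offsets.add(pos - p)
    if not offsets:
        return None
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    best = None
    for off in sorted(offsets):
        a, b = max(0, off), min(Lc, off + n)
        if b - a < min_overlap:
            continue
        matches = int(np.count_nonzero(cons[a:b] == arr[a - off : b - off]))
        ident = matches / (b - a)
        key = (ident, b - a, -off)
        if best is None or key > best[0]:
            best = (key, off, b - a, ident)
    if best is None:
        return None
    return best[1], best[2], best[3]


def greedy_extend(
    seed: SeedOtu | str,
    read_pairs: Sequence[ReadPair],
    params: ExtensionParams | None = None,
) -> ExtensionState:
    """Iteratively extend a seed with overlapping reads.

    Per iteration: (1) recruit reads (either orientation) overlapping the
    consensus by >= min_overlap nt at >= min_identity; (2) rescue mates of
    recruited edge reads at a relaxed identity; (3) extend each end by the
    column-wise majority of the recruited overhangs (reads extend an end only
    when their overlap anchors flush at that end — the chimera guard);
    (4) correct interior positions to the column majority where coverage >=
    min_agreement, and recompute coverage. Stops when neither end grows or at
    max_iterations. Majority ties emit IUPAC codes. If no reads are recruited
    in the first iteration the trimmed seed is returned with ``extended``
    False.
    """
    params = params or ExtensionParams()
    consensus = seed.sequence if isinstance(seed, SeedOtu) else seed
    if len(consensus) < params.min_overlap:
        raise ExtensionError("seed shorter than the minimum overlap")

    reads: list[str] = []
    mate_of: list[int] = []
    for r1, r2 in read_pairs:
        i = len(reads)
        reads.append(r1.sequence.upper())
        reads.append(r2.sequence.upper())
        mate_of.extend([i + 1, i])
    oriented = [(s, revcomp(s)) for s in reads]

    state = ExtensionState(
        consensus=consensus, coverage=np.zeros(len(consensus), dtype=int)
    )
    k = params.kmer
    for iteration in range(1, params.max_iterations + 1):
        cons_str = state.consensus
        Lc = len(cons_str)
        cons = np.frombuffer(cons_str.encode(), dtype=np.uint8)
        index: dict[str, list[int]] = defaultdict(list)
        for i in range(Lc - k + 1):
            index[cons_str[i : i + k]].append(i)

        placements: dict[int, tuple[int, str]] = {}
        for ri, (fwd, rev) in enumerate(oriented):
            best = None
            for seq in (fwd, rev):
                m = _map_read(seq, index, cons, k, params.min_overlap)
                if m and (best is None or (m[2], m[1]) > (best[0][2], best[0][1])):
                    best = (m, seq)
            if best and best[0][2] >= params.min_identity:
                placements[ri] = (best[0][0], best[1])

        # pair rescue: mates of edge-recruited reads may anchor at lower
        # identity over the overhang region
        for ri in list(placements):
            off, seq = placements[ri]
            mi = mate_of[ri]
            if mi in placements:
                continue
            if off < 0 or off + len(seq) > Lc:
                for mseq in oriented[mi]:
                    m = _map_read(mseq, index, cons, k, params.min_overlap)
                    if m and m[2] >= params.rescue_identity:
                        placements[mi] = (m[0], mseq)
                        break

        n_recruited = len(placements)
        if n_recruited == 0:
            state.iteration = iteration
            state.log.append(IterationRecord(iteration, 0, 0, 0))
            break

        span_lo = min(0, min(off for off, _ in placements.values()))
        span_hi = max(Lc, max(off + len(s) for off, s in placements.values()))
        tally = np.zeros((span_hi - span_lo, 4), dtype=int)
        for off, seq in placements.values():
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            base = off - span_lo
            for bi, code in enumerate((65, 67, 71, 84)):
                idx = np.nonzero(arr == code)[0]
                np.add.at(tally, base + idx, np.eye(4, dtype=int)[bi])

        cov_all = tally.sum(axis=1)

        def majority(col: np.ndarray) -> str:
            top = col.max()
            bases = frozenset("ACGT"[i] for i in range(4) if col[i] == top)
            return _IUPAC[bases]

        # contiguous covered run immediately left of position 0
        left_cols = []
        j = -1 - span_lo
        while j >= 0 and cov_all[j] > 0:
            left_cols.append(majority(tally[j]))
            j -= 1
        left_ext = "".join(reversed(left_cols))

        right_cols = []
        j = Lc - span_lo
        while j < tally.shape[0] and cov_all[j] > 0:
            right_cols.append(majority(tally[j]))
            j += 1
        right_ext = "".join(right_cols)

        # interior correction at well-covered columns
        core = list(cons_str)
        core_cov = cov_all[-span_lo : Lc - span_lo]
        for p in range(Lc):
            if core_cov[p] >= params.min_agreement:
                core[p] = majority(tally[p - span_lo])

        new_consensus = left_ext + "".join(core) + right_ext
        new_lo = -len(left_ext) - span_lo
        new_cov = cov_all[new_lo : new_lo + len(new_consensus)].copy()

        state.consensus = new_consensus
        state.coverage = new_cov
        state.iteration = iteration
        state.left_extended = len(left_ext)
        state.right_extended = len(right_ext)
        state.extended = state.extended or bool(left_ext or right_ext)
        state.log.append(
            IterationRecord(iteration, n_recruited, len(left_ext), len(right_ext))
        )
        if not left_ext and not right_ext:
            break
    return state


def coverage_stats(state: ExtensionState) -> CoverageStats:
    """Mean / median / min of the per-base coverage vector."""
    if len(state.consensus) == 0:
        raise ExtensionError("empty extension state")
    cov = state.coverage
    return CoverageStats(
        mean=float(cov.mean()),
        median=float(median(cov.tolist())),
        min=int(cov.min()),
        profile=tuple(int(c) for c in cov),
    )


def restrict_to_barcode(
    state: ExtensionState,
    reference: str,
    window: BarcodeRegion | None = None,
    min_identity: float = 0.80,
    min_span: int = 200,
) -> BarcodeResult:
    """Extract the consensus subsequence co-linear with the reference's 3'
    barcode window (default: the last 1000 nt).

    The consensus is located on the reference by semi-global alignment; the
    window intersection is then cut out assuming co-linearity (the read model
    is substitution-only, so there is no indel drift to track). Partial
    coverage of the window is flagged; differences from the reference over
    the extracted region are counted.
    """
    Lr = len(reference)
    window = window or BarcodeRegion(max(0, Lr - 1000), Lr)
    cons = state.consensus
    res = edlib.align(cons, reference, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        raise ExtensionError("consensus does not align to the reference")
    rs, re_ = res["locations"][0]
    re_ += 1  # half-open
    span = re_ - rs
    identity = 1.0 - res["editDistance"] / max(span, len(cons))
    if span < min_span or identity < min_identity:
        raise ExtensionError(
            f"consensus aligns over {span} nt at {identity:.2f} identity; "
            f"need >= {min_span} nt at >= {min_identity:.2f}"
        )
    a = max(rs, window.start)
    b = min(re_, window.end)
    if b <= a:
        raise ExtensionError("consensus does not reach the barcode window")
    seg = cons[a - rs : b - rs]
    diff = edlib.align(seg, reference[a:b], mode="NW")["editDistance"]
    return BarcodeResult(
        sequence=seg,
        partial=(a > window.start) or (b < window.end),
        n_differences=int(diff),
        reference_start=a,
        reference_end=b,
    )
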