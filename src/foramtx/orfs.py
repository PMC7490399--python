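"""Six-frame ORF prediction on assembled contigs.

Two scanning modes stand in for the two gene callers commonly applied to
mixed-community assemblies: a eukaryote-style mode (ATG starts only) and a
prokaryote-style mode that additionally permits GTG/TTG alternative starts.
Coding-potential scoring is deliberately out of scope: downstream profiling
needs ORF coordinates and translations, not likelihoods, and externally
produced ORF tables in the same schema are accepted by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD.forward_table)
STOP_CODONS = frozenset(_STANDARD.stop_codons)

EUK_STARTS = frozenset({"ATG"})
PROK_STARTS = frozenset({"ATG", "GTG", "TTG"})

DEFAULT_MIN_CONTIG_NT = 300  # assembler minimum contig length, kept as input validation
DEFAULT_MIN_ORF_AA = 100

_VALID_NT = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ContigValidationError(ValueError):
    """Raised when a contig violates the input contract (length, alphabet)."""


class TranslationError(ValueError):
    """Raised when a nucleotide string cannot be translated."""


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Contig:
    """An assembled contig: id plus an upper-case A/C/G/T/N sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ContigValidationError("contig id must be non-empty")
        bad = set(self.sequence) - _VALID_NT
        if bad:
            raise ContigValidationError(
                f"contig {self.id!r}: invalid characters {sorted(bad)} in sequence"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfRecord:
    """A predicted ORF with forward-strand half-open coordinates.

    ``start``/``end`` are 0-based half-open on the forward strand and include
    the stop codon when one terminates the ORF. ``frame`` is the codon phase
    (0/1/2) on the scanned strand. ``partial`` flags ORFs that run into the
    contig edge without reaching a stop codon.
    """

    id: str
    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    aa_sequence: str
    partial: bool

    @property
    def length_aa(self) -> int:
        return len(self.aa_sequence)


def translate(nucleotides: str, code: str = "standard") -> str:
    """Translate a nucleotide string with the standard genetic code.

    Codons containing N translate to X; stop codons render as ``*`` with a
    single terminal ``*`` stripped, so a complete gene translates to its
    protein without the terminator. Length must be a multiple of three.
    """
    if code != "standard":
        raise TranslationError(f"unsupported genetic code {code!r}")
    if len(nucleotides) % 3 != 0:
        raise TranslationError(
            f"sequence length {len(nucleotides)} is not divisible by 3"
        )
    bad = set(nucleotides) - _VALID_NT
    if bad:
        raise TranslationError(f"invalid characters {sorted(bad)}")
    out = []
    for i in range(0, len(nucleotides), 3):
        codon = nucleotides[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append(_CODON_TO_AA[codon])
    aa = "".join(out)
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa


def _scan_frames(seq: str, starts: frozenset, min_len_aa: int):
    """Yield (start, end, frame, partial) ORFs on one strand of ``seq``.

    Within each frame the sequence is split at stop codons; each stop-bounded
    segment contributes at most one ORF, running from its first start codon to
    the stop (inclusive) or to the last complete codon at the contig edge
    (flagged partial).
    """
    n = len(seq)
    for frame in range(3):
        orf_start = None
        i = frame
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if orf_start is not None:
                    end = i + 3
                    if (end - orf_start) // 3 - 1 >= min_len_aa:
                        yield orf_start, end, frame, False
                    orf_start = None
            elif orf_start is None and codon in starts:
                orf_start = i
            i += 3
        if orf_start is not None:
            end = i  # last complete codon boundary in this frame
            if (end - orf_start) // 3 >= min_len_aa:
                yield orf_start, end, frame, True


def find_orfs(
    contig: Contig,
    min_len_aa: int = DEFAULT_MIN_ORF_AA,
    mode: str = "euk",
    min_contig_nt: int = DEFAULT_MIN_CONTIG_NT,
) -> list[OrfRecord]:
    """Scan all six frames of a contig for ORFs of ``min_len_aa`` residues.

    ``mode`` selects the permitted start codons: ``"euk"`` (ATG) or ``"prok"``
    (ATG/GTG/TTG). Records are sorted by (start, strand, frame); ids encode
    the coordinates (``<contig_id>:o<start>-<end><strand>``) so the same ORF
    found by both modes carries the same id.
    """
    if mode == "euk":
        starts = EUK_STARTS
    elif mode == "prok":
        starts = PROK_STARTS
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'euk' or 'prok'")
    if len(contig) < min_contig_nt:
        raise ContigValidationError(
            f"contig {contig.id!r} is {len(contig)} nt, below the minimum "
            f"contig length of {min_contig_nt} nt"
        )
    n = len(contig)
    found = []
    for s, e, frame, partial in _scan_frames(contig.sequence, starts, min_len_aa):
        aa = translate(contig.sequence[s:e])
        found.append((s, e, "+", frame, aa, partial))
    rc = revcomp(contig.sequence)
    for s, e, frame, partial in _scan_frames(rc, starts, min_len_aa):
        aa = translate(rc[s:e])
        found.append((n - e, n - s, "-", frame, aa, partial))
    found.sort(key=lambda t: (t[0], t[2], t[3]))
    return [
        OrfRecord(
            id=f"{contig.id}:o{s}-{e}{strand}",
            contig_id=contig.id,
            start=s,
            end=e,
            strand=strand,
            frame=frame,
            aa_sequence=aa,
            partial=partial,
        )
        for s, e, strand, frame, aa, partial in found
    ]


def find_orfs_eukaryotic(
    contig: Contig,
    min_len_aa: int = DEFAULT_MIN_ORF_AA,
    min_contig_nt: int = DEFAULT_MIN_CONTIG_NT,
) -> list[OrfRecord]:
    """ATG-start six-frame scan (eukaryote-style calling)."""
    return find_orfs(contig, min_len_aa, mode="euk", min_contig_nt=min_contig_nt)


def find_orfs_prokaryotic(
    contig: Contig,
    min_len_aa: int = DEFAULT_MIN_ORF_AA,
    min_contig_nt: int = DEFAULT_MIN_CONTIG_NT,
) -> list[OrfRecord]:
    """ATG/GTG/TTG-start six-frame scan (prokaryote-style calling)."""
    return find_orfs(contig, min_len_aa, mode="prok", min_contig_nt=min_contig_nt)
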