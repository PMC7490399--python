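"""File formats: FASTA (80-column), FASTQ (Sanger Phred+33), tab tables.

Thin wrappers over Biopython SeqIO and pandas so every stage reads and writes
the plain-text formats the pipeline exchanges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import Assignment, HitRecord, ReferenceProtein, parse_header
from .orfs import Contig, OrfRecord


@dataclass(frozen=True)
class Read:
    """One sequencing read (Sanger Phred+33 quality string)."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"read {self.id!r}: sequence/quality length mismatch")


ReadPair = tuple[Read, Read]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) pairs wrapped at 80 columns."""
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(seqs)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.description or r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def read_contigs(path: str | Path) -> list[Contig]:
    return [Contig(id=h.split()[0], sequence=s) for h, s in read_fasta(path)]


def write_reference_fasta(path: str | Path, refs: Sequence[ReferenceProtein]) -> None:
    write_fasta(path, [(r.header, r.sequence) for r in refs])


def read_reference_fasta(path: str | Path) -> list[ReferenceProtein]:
    out = []
    for header, seq in read_fasta(path):
        ident, group, genus, kog = parse_header(header)
        out.append(ReferenceProtein(ident, group, genus, kog, seq))
    return out


def write_fastq(path: str | Path, reads: Iterable[Read]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list[Read]:
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            out.append(Read(header[1:].split()[0], seq, qual))
    return out


def read_paired_fastq(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    """Mate pairing by record order across the two files."""
    r1, r2 = read_fastq(path1), read_fastq(path2)
    if len(r1) != len(r2):
        raise ValueError("paired FASTQ files have unequal record counts")
    return list(zip(r1, r2))


def write_paired_fastq(path1: str | Path, path2: str | Path, pairs: Sequence[ReadPair]) -> None:
    write_fastq(path1, (p[0] for p in pairs))
    write_fastq(path2, (p[1] for p in pairs))


# --- tabular schemas ---------------------------------------------------------

ORF_COLUMNS = [
    "orf_id",
    "contig_id",
    "start_1based",
    "end",
    "strand",
    "frame",
    "partial_flag",
    "aa_len",
]


def orf_table(orfs: Sequence[OrfRecord]) -> pd.DataFrame:
    """ORF table with 1-based inclusive coordinates (bioinformatics-table
    convention; internal coordinates are 0-based half-open)."""
    return pd.DataFrame(
        [
            {
                "orf_id": o.id,
                "contig_id": o.contig_id,
                "start_1based": o.start + 1,
                "end": o.end,
                "strand": o.strand,
                "frame": o.frame,
                "partial_flag": int(o.partial),
                "aa_len": o.length_aa,
            }
            for o in orfs
        ],
        columns=ORF_COLUMNS,
    )


def write_orf_table(path: str | Path, orfs: Sequence[OrfRecord]) -> None:
    orf_table(orfs).to_csv(path, sep="\t", index=False)


HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def write_hit_table(path: str | Path, hits: Sequence[HitRecord]) -> None:
    """Write hits in the 12-column BLAST tabular dialect (coordinates and the
    mismatch/gapopen counts not tracked by HitRecord are written as 0)."""
    rows = [
        {
            "qseqid": h.query_id,
            "sseqid": h.subject_id,
            "pident": round(h.pct_identity, 3),
            "length": h.align_length,
            "mismatch": 0,
            "gapopen": 0,
            "qstart": 0,
            "qend": 0,
            "sstart": 0,
            "send": 0,
            "evalue": h.evalue,
            "bitscore": round(h.bit_score, 1),
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False, header=False)


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tabular hit file; sseqid must follow the
    id|group|genus|kog reference header schema."""
    df = pd.read_csv(path, sep="\t", names=HIT_COLUMNS, comment="#")
    out = []
    for row in df.itertuples(index=False):
        _, group, genus, kog = parse_header(str(row.sseqid))
        out.append(
            HitRecord(
                query_id=str(row.qseqid),
                subject_id=str(row.sseqid),
                pct_identity=float(row.pident),
                align_length=int(row.length),
                evalue=float(row.evalue),
                bit_score=float(row.bitscore),
                subject_group=group,
                subject_genus=genus,
                subject_kog=kog,
            )
        )
    return out


ASSIGNMENT_COLUMNS = ["orf_id", "group", "genus", "kog_class", "bit_score", "contaminant"]


def assignment_table(assignments: Sequence[Assignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "orf_id": a.orf_id,
                "group": a.group,
                "genus": a.genus or "",
                "kog_class": a.kog_class or "",
                "bit_score": round(a.best_hit.bit_score, 1) if a.best_hit else "",
                "contaminant": int(a.contaminant),
            }
            for a in assignments
        ],
        columns=ASSIGNMENT_COLUMNS,
    )


def write_assignment_table(path: str | Path, assignments: Sequence[Assignment]) -> None:
    assignment_table(assignments).to_csv(path, sep="\t", index=False)


def read_assignment_table(path: str | Path) -> list[Assignment]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        Assignment(
            orf_id=str(r.orf_id),
            group=str(r.group),
            genus=str(r.genus) or None,
            kog_class=str(r.kog_class) or None,
            contaminant=bool(int(r.contaminant)),
        )
        for r in df.itertuples(index=False)
    ]


TRUTH_COLUMNS = ["orf_id", "sample", "taxon", "genus", "group", "kog_class"]


def write_truth_table(path: str | Path, truth) -> None:
    """Ground-truth TSV for a simulated sample (orf_id .. kog_class)."""
    rows = [
        {
            "orf_id": e.orf_id,
            "sample": e.sample_id,
            "taxon": e.taxon,
            "genus": e.genus,
            "group": e.group,
            "kog_class": e.kog_class,
        }
        for e in (truth.entries[k] for k in sorted(truth.entries))
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV; must carry at least a 'sample' column."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns:
        raise ValueError("metadata must have a 'sample' column")
    return df
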