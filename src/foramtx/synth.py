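"""Synthetic benthic-community metatranscriptome generator.

Generates ground-truth communities — a Foraminifera-like target group, other
eukaryote groups, prokaryotes and planted contaminant genera — together with
per-sample contigs, paired-end reads, a matching reference protein database
and full-length 18S rRNA references. The generator reproduces the statistical
structure the downstream analysis assumes:

* per-sample shifts in the fraction of the target group's genes that are
  transcribed (the activity signal the profiling statistic measures);
* heavy-tailed per-transcript amplification bias, modelled as an i.i.d.
  log-normal multiplicative depth factor (single-primer isothermal
  amplification kits introduce orders-of-magnitude read-depth variability
  between technical replicates while leaving the set of expressed
  transcripts essentially unchanged);
* substitution sequencing error and constant Phred-30 qualities;
* 18S rRNA read sets drawn from known full-length references, for testing
  barcode reconstruction by greedy seed extension.

Identical (spec, seed) inputs give byte-identical outputs.
"""

from __future__ import annotations

import zlib
from collections import defaultdict
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np

from .annotate import Assignment, HitRecord, KOG_CLASSES, ReferenceProtein
from .io import Read, ReadPair
from .orfs import Contig, STOP_CODONS, revcomp, translate

PHRED30 = "?"  # chr(30 + 33)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


class SpecValidationError(ValueError):
    """Raised when a community spec violates its invariants; names the field."""


@dataclass(frozen=True)
class TaxonSpec:
    """One taxon: its labels, genome size and sequence composition."""

    name: str
    group: str
    genus: str
    n_genes: int
    gene_length_range: tuple[int, int] = (330, 900)
    gc: float = 0.45
    is_contaminant: bool = False


@dataclass(frozen=True)
class SampleSpec:
    """One sample: which fraction of each taxon's genes is transcribed and at
    what depth weight (expected read pairs per transcript before
    amplification)."""

    sample_id: str
    condition: str
    expression_fraction: Mapping[str, float] = field(default_factory=dict)
    depth_weight: float = 30.0

    def fraction_for(self, taxon: str) -> float:
        return float(self.expression_fraction.get(taxon, 0.0))


@dataclass(frozen=True)
class CommunitySpec:
    """Full study design: taxa, samples, noise model, read geometry."""

    taxa: tuple[TaxonSpec, ...]
    samples: tuple[SampleSpec, ...]
    target_group: str = "Foraminifera"
    amplification_sigma: float = 2.0
    read_length: int = 150
    insert_mean: int = 350
    insert_sd: int = 50
    error_rate: float = 0.0
    min_orf_aa: int = 100
    seed: int = 0

    def validate(self) -> None:
        if not self.taxa:
            raise SpecValidationError("taxa: at least one taxon required")
        genera = [t.genus for t in self.taxa]
        if len(set(genera)) != len(genera):
            raise SpecValidationError("taxa: genus must be unique per taxon")
        for t in self.taxa:
            if t.n_genes < 1:
                raise SpecValidationError(f"n_genes: taxon {t.name!r} needs >= 1 gene")
            lo, hi = t.gene_length_range
            min_nt = 3 * self.min_orf_aa + 6  # start + min_orf_aa codons + stop
            if lo < min_nt:
                raise SpecValidationError(
                    f"gene_length_range: taxon {t.name!r} minimum {lo} nt is below "
                    f"{min_nt} nt (3 x min ORF length plus start/stop), so ORFs "
                    f"would not be callable"
                )
            if hi < lo:
                raise SpecValidationError(
                    f"gene_length_range: taxon {t.name!r} has empty range"
                )
            if not 0.0 <= t.gc <= 1.0:
                raise SpecValidationError(f"gc: taxon {t.name!r} outside [0, 1]")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise SpecValidationError("samples: sample_id must be unique")
        for s in self.samples:
            for taxon, f in s.expression_fraction.items():
                if not 0.0 <= f <= 1.0:
                    raise SpecValidationError(
                        f"expression_fraction: sample {s.sample_id!r} taxon "
                        f"{taxon!r} outside [0, 1]"
                    )
        if not 0.0 <= self.error_rate <= 0.1:
            raise SpecValidationError("error_rate: outside [0, 0.1]")
        if self.amplification_sigma < 0:
            raise SpecValidationError("amplification_sigma: must be >= 0")
        if self.read_length < 30:
            raise SpecValidationError("read_length: must be >= 30 nt")

    def sample(self, sample_id: str) -> SampleSpec:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(f"unknown sample_id {sample_id!r}")


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one transcribed gene / contig / ORF."""

    orf_id: str
    sample_id: str
    taxon: str
    genus: str
    group: str
    kog_class: str
    contig_id: str
    gene_start: int  # ORF start on the contig (0-based)
    gene_end: int  # ORF end (half-open, includes the stop codon)
    protein: str
    read_pairs: int
    is_contaminant: bool


@dataclass(frozen=True)
class GroundTruth:
    """Per-sample map from ORF/contig ids to their true labels and depths."""

    sample_id: str
    entries: dict[str, TruthEntry]
    contaminant_ids: frozenset[str]

    def read_counts(self) -> dict[str, int]:
        return {oid: e.read_pairs for oid, e in self.entries.items()}


@dataclass(frozen=True)
class SampleData:
    contigs: list[Contig]
    read_pairs: list[ReadPair]
    truth: GroundTruth


def _stable_hash(text: str) -> int:
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def _rng(*entropy) -> np.random.Generator:
    parts = [p if isinstance(p, int) else _stable_hash(str(p)) for p in entropy]
    return np.random.default_rng(parts)


def _random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ATGC"))[rng.choice(4, size=n, p=p)])


from Bio.Data import CodonTable as _CodonTable

_CODONS_FOR_AA: dict[str, list[str]] = {}
for _c, _aa in _CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _CODONS_FOR_AA.setdefault(_aa, []).append(_c)
for _aa in _CODONS_FOR_AA:
    _CODONS_FOR_AA[_aa].sort()


@lru_cache(maxsize=256)
def _codon_weights(aa: str, gc: float) -> tuple[list[str], tuple[float, ...]]:
    options = _CODONS_FOR_AA[aa]
    w = np.array(
        [
            gc ** sum(c in "GC" for c in o) * (1 - gc) ** sum(c in "AT" for c in o)
            for o in options
        ]
    )
    return options, tuple(w / w.sum())


def _gene_for_protein(rng: np.random.Generator, protein: str, gc: float) -> str:
    """Back-translate, choosing synonymous codons weighted toward the taxon GC.

    Positions are grouped by residue so each amino acid costs one RNG draw.
    """
    codons = [""] * len(protein)
    by_aa: dict[str, list[int]] = defaultdict(list)
    for i, aa in enumerate(protein):
        by_aa[aa].append(i)
    for aa in sorted(by_aa):
        positions = by_aa[aa]
        options, probs = _codon_weights(aa, gc)
        draws = rng.choice(len(options), size=len(positions), p=probs)
        for pos, d in zip(positions, draws):
            codons[pos] = options[d]
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    return "ATG" + "".join(codons) + stop


_GENE_CACHE: dict[tuple, list[tuple[str, str, str]]] = {}


def _taxon_genes(spec: CommunitySpec, taxon_index: int) -> list[tuple[str, str, str]]:
    """Deterministic (gene_id, protein, cds) list for one taxon.

    Gene content depends only on (spec.seed, taxon), never on samples, so the
    reference database and every sample's contigs agree.
    """
    t = spec.taxa[taxon_index]
    cache_key = (spec.seed, spec.min_orf_aa, taxon_index, t)
    cached = _GENE_CACHE.get(cache_key)
    if cached is not None:
        return cached
    rng = _rng(spec.seed, 101, taxon_index)
    lo, hi = t.gene_length_range
    out = []
    for j in range(t.n_genes):
        nt_len = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
        n_aa = nt_len // 3 - 1  # protein includes the start Met; stop excluded
        protein = "M" + "".join(
            np.array(list(_AA20))[rng.integers(0, 20, size=n_aa - 1)]
        )
        cds = _gene_for_protein(rng, protein[1:], t.gc)
        out.append((f"{t.genus}_g{j:04d}", protein, cds))
    _GENE_CACHE[cache_key] = out
    return out


def generate_reference_set(
    spec: CommunitySpec,
) -> tuple[list[ReferenceProtein], dict[str, str]]:
    """Build the reference protein database and full-length 18S references.

    One protein per gene, headers in the id|group|genus|kog schema; KOG
    classes are drawn uniformly over the 25 one-letter classes. 18S
    references (>= 1500 nt) are emitted for every taxon of the target group.
    """
    spec.validate()
    refs: list[ReferenceProtein] = []
    for ti, t in enumerate(spec.taxa):
        krng = _rng(spec.seed, 202, ti)
        for gene_id, protein, _ in _taxon_genes(spec, ti):
            kog = KOG_CLASSES[krng.integers(len(KOG_CLASSES))]
            refs.append(ReferenceProtein(gene_id, t.group, t.genus, kog, protein))
    rrna: dict[str, str] = {}
    for ti, t in enumerate(spec.taxa):
        if t.group == spec.target_group:
            rng = _rng(spec.seed, 303, ti)
            length = int(rng.integers(1500, 1801))
            rrna[t.name] = _random_nt(rng, length, t.gc)
    return refs, rrna


def _expressed_genes(spec: CommunitySpec, sample_id: str) -> dict[int, np.ndarray]:
    """Which gene indices each taxon transcribes in this sample.

    Drawn from an RNG keyed by (spec.seed, sample_id) only, so technical
    replicates share the same composition by construction.
    """
    s = spec.sample(sample_id)
    out = {}
    for ti, t in enumerate(spec.taxa):
        f = s.fraction_for(t.name)
        k = int(round(f * t.n_genes))
        rng = _rng(spec.seed, 404, sample_id, ti)
        out[ti] = np.sort(rng.choice(t.n_genes, size=k, replace=False)) if k else np.array([], dtype=int)
    return out


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < error_rate)[0]
    if hit.size:
        alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in hit:
            choices = alphabet[alphabet != arr[i]]
            arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def _pairs_from_template(
    rng: np.random.Generator,
    template: str,
    n_pairs: int,
    prefix: str,
    spec: CommunitySpec,
) -> list[ReadPair]:
    """Paired reads with fragment positions uniform over the template."""
    L = len(template)
    rl = spec.read_length
    out = []
    for p in range(n_pairs):
        insert = int(np.clip(round(rng.normal(spec.insert_mean, spec.insert_sd)), rl, L))
        u = int(rng.integers(0, L - insert + 1))
        frag = template[u : u + insert]
        r1 = _mutate(rng, frag[:rl], spec.error_rate)
        r2 = _mutate(rng, revcomp(frag[-rl:]), spec.error_rate)
        out.append(
            (
                Read(f"{prefix}:p{p}/1", r1, PHRED30 * rl),
                Read(f"{prefix}:p{p}/2", r2, PHRED30 * rl),
            )
        )
    return out


def simulate_sample(
    spec: CommunitySpec,
    sample_id: str,
    seed: int | None = None,
    emit_reads: bool = True,
) -> SampleData:
    """Simulate one sample: contigs, paired reads and ground truth.

    A gene appears as a contig iff it is transcribed in the sample; each
    transcript's read-pair count is depth_weight x a log-normal(0, sigma^2)
    amplification factor. Contigs embed the gene between short UTRs with an
    in-frame stop immediately 5' of the start codon, so the planted ORF is
    exactly callable. ``seed`` controls amplification and error draws only;
    composition is keyed by (spec.seed, sample_id).
    """
    spec.validate()
    s = spec.sample(sample_id)  # raises KeyError for unknown sample ids
    seed = spec.seed if seed is None else seed
    expressed = _expressed_genes(spec, sample_id)
    contigs: list[Contig] = []
    pairs: list[ReadPair] = []
    entries: dict[str, TruthEntry] = {}
    contaminants: set[str] = set()
    kog_by_gene: dict[str, str] = {}
    for ti, t in enumerate(spec.taxa):
        krng = _rng(spec.seed, 202, ti)
        for gene_id, _, _ in _taxon_genes(spec, ti):
            kog_by_gene[gene_id] = KOG_CLASSES[krng.integers(len(KOG_CLASSES))]
    for ti, t in enumerate(spec.taxa):
        genes = _taxon_genes(spec, ti)
        rng = _rng(seed, 505, sample_id, ti)
        for gi in expressed[ti]:
            gene_id, protein, cds = genes[int(gi)]
            utr5 = _random_nt(rng, int(rng.integers(23, 61)), t.gc)
            utr5 = utr5[:-3] + "TAA"  # in-frame stop right before the start codon
            utr3 = _random_nt(rng, int(rng.integers(20, 61)), t.gc)
            seq = utr5 + cds + utr3
            contig_id = f"{sample_id}:{gene_id}"
            contigs.append(Contig(contig_id, seq))
            amp = float(np.exp(rng.normal(0.0, spec.amplification_sigma))) if spec.amplification_sigma > 0 else 1.0
            n_pairs = int(round(s.depth_weight * amp))
            if emit_reads and n_pairs:
                pairs.extend(_pairs_from_template(rng, seq, n_pairs, contig_id, spec))
            entries[contig_id] = TruthEntry(
                orf_id=contig_id,
                sample_id=sample_id,
                taxon=t.name,
                genus=t.genus,
                group=t.group,
                kog_class=kog_by_gene[gene_id],
                contig_id=contig_id,
                gene_start=len(utr5),
                gene_end=len(utr5) + len(cds),
                protein=protein,
                read_pairs=n_pairs,
                is_contaminant=t.is_contaminant,
            )
            if t.is_contaminant:
                contaminants.add(contig_id)
    truth = GroundTruth(sample_id, entries, frozenset(contaminants))
    return SampleData(contigs=contigs, read_pairs=pairs, truth=truth)


def simulate_technical_replicates(
    spec: CommunitySpec,
    sample_id: str,
    k: int,
    seed: int = 0,
    emit_reads: bool = False,
) -> list[SampleData]:
    """k technical replicates: identical composition and truth labels, only
    the amplification and error draws differ."""
    if k < 2:
        raise ValueError("technical replicates require k >= 2")
    return [
        simulate_sample(spec, sample_id, seed=_rng(seed, 606, r).integers(2**31), emit_reads=emit_reads)
        for r in range(k)
    ]


def simulate_18s_reads(
    reference: str,
    coverage: float,
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
    insert_mean: int = 350,
    insert_sd: int = 50,
) -> list[ReadPair]:
    """Paired reads from a full-length 18S reference at a requested fold
    coverage.

    Whole molecules are sheared into consecutive fragments (random phase), so
    molecule termini are fragment boundaries and the reference ends are
    covered the way real cDNA fragmentation covers them. Molecules are added
    until the emitted bases reach coverage x reference length, which pins the
    realized mean coverage to the request.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    L = len(reference)
    if read_length >= L:
        raise ValueError("read_length must be shorter than the reference")
    rng = np.random.default_rng([seed, 707])
    target_bases = coverage * L
    total = 0
    out: list[ReadPair] = []
    mol = 0
    while total < target_bases:
        pos = -int(rng.integers(0, insert_mean))
        while pos < L:
            flen = max(read_length, int(round(rng.normal(insert_mean, insert_sd))))
            start, end = max(pos, 0), min(pos + flen, L)
            pos += flen
            if end - start < read_length:
                continue
            frag = reference[start:end]
            r1 = _mutate(rng, frag[:read_length], error_rate)
            r2 = _mutate(rng, revcomp(frag[-read_length:]), error_rate)
            prefix = f"rrna:m{mol}:{start}"
            out.append(
                (
                    Read(f"{prefix}/1", r1, PHRED30 * read_length),
                    Read(f"{prefix}/2", r2, PHRED30 * read_length),
                )
            )
            total += 2 * read_length
        mol += 1
    return out


def truth_assignments(truth: GroundTruth, drop_contaminants: bool = True) -> list[Assignment]:
    """Assignments straight from ground truth (annotation bypassed); the
    cheap route to profiles when only the statistic downstream is under test."""
    out = []
    for oid in sorted(truth.entries):
        e = truth.entries[oid]
        if drop_contaminants and e.is_contaminant:
            continue
        out.append(
            Assignment(orf_id=oid, group=e.group, genus=e.genus, kog_class=e.kog_class)
        )
    return out


# --- canned study designs ----------------------------------------------------

PROKARYOTE_GROUPS = frozenset({"Bacteria", "Archaea"})


def _background_taxa(scale: float = 1.0) -> list[TaxonSpec]:
    n = lambda x: max(1, int(round(x * scale)))
    return [
        TaxonSpec("Ciliophora_sp", "Ciliophora", "Pseudocohnilembus", n(60), gc=0.35),
        TaxonSpec("Dinoflagellate_sp", "Dinoflagellata", "Prorocentrum", n(60), gc=0.5),
        TaxonSpec("Chlorophyte_sp", "Chlorophyta", "Ostreococcus", n(40), gc=0.55),
        TaxonSpec("Bacterium_sp", "Bacteria", "Desulfobacter", n(60), gc=0.45),
        TaxonSpec("Archaeon_sp", "Archaea", "Nitrosopumilus", n(40), gc=0.4),
        TaxonSpec(
            "Contaminant_sp", "Bacteria", "Pseudomonas", n(10), gc=0.6, is_contaminant=True
        ),
    ]


def incubation_experiment(
    fold: float = 25.0,
    n_replicates: int = 2,
    depth_weight: float = 30.0,
    amplification_sigma: float = 2.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> CommunitySpec:
    """A two-condition design with a programmed ``fold`` increase in the
    target group's fraction of expressed genes between oxic t0 and anoxia.

    The background community expresses a fixed complement m of genes; the
    target group's expressed-gene count is solved so that the assigned-ORF
    fraction moves from f0 to f1 with f1/f0 = fold and f1 = 0.5.
    """
    taxa = [TaxonSpec("Foraminifera_sp", "Foraminifera", "Bolivina", 200, gc=0.42)]
    taxa += _background_taxa()
    bg_expr = {
        "Ciliophora_sp": 0.75,
        "Dinoflagellate_sp": 0.75,
        "Chlorophyte_sp": 0.75,
        "Bacterium_sp": 0.75,
        "Archaeon_sp": 0.75,
        "Contaminant_sp": 0.5,
    }
    m = sum(
        int(round(bg_expr[t.name] * t.n_genes))
        for t in taxa[1:]
        if not t.is_contaminant
    )
    f1 = 0.5
    x1 = f1 * m / (1 - f1)  # anoxic target expressed count
    f0 = f1 / fold
    x0 = f0 * m / (1 - f0)
    n_target = taxa[0].n_genes
    samples = []
    for r in range(n_replicates):
        samples.append(
            SampleSpec(
                f"t0_r{r + 1}",
                "oxic_t0",
                {**bg_expr, "Foraminifera_sp": round(x0) / n_target},
                depth_weight,
            )
        )
    for r in range(n_replicates):
        samples.append(
            SampleSpec(
                f"anoxic_r{r + 1}",
                "anoxic",
                {**bg_expr, "Foraminifera_sp": round(x1) / n_target},
                depth_weight,
            )
        )
    return CommunitySpec(
        taxa=tuple(taxa),
        samples=tuple(samples),
        amplification_sigma=amplification_sigma,
        error_rate=error_rate,
        seed=seed,
    )


def programmed_fraction(spec: CommunitySpec, condition: str) -> float:
    """The target-group fraction of assigned (non-contaminant) expressed genes
    a condition is programmed to produce."""
    for s in spec.samples:
        if s.condition == condition:
            counts = {
                t.name: int(round(s.fraction_for(t.name) * t.n_genes))
                for t in spec.taxa
                if not t.is_contaminant
            }
            total = sum(counts.values())
            target = sum(
                c
                for name, c in counts.items()
                if next(t for t in spec.taxa if t.name == name).group == spec.target_group
            )
            return target / total
    raise KeyError(f"no sample with condition {condition!r}")


def demo_community(seed: int = 0) -> CommunitySpec:
    """Small two-condition community for the one-command synthetic demo."""
    taxa = [TaxonSpec("Foraminifera_sp", "Foraminifera", "Bolivina", 40, gc=0.42)]
    taxa += _background_taxa(scale=0.4)
    lo = {"Foraminifera_sp": 0.1}
    hi = {"Foraminifera_sp": 0.8}
    bg = {t.name: 0.6 for t in taxa[1:]}
    samples = tuple(
        [
            SampleSpec(f"oxic_r{r}", "oxic", {**bg, **lo}, 8.0)
            for r in (1, 2, 3)
        ]
        + [
            SampleSpec(f"anoxic_r{r}", "anoxic", {**bg, **hi}, 8.0)
            for r in (1, 2, 3)
        ]
    )
    return CommunitySpec(taxa=tuple(taxa), samples=samples, amplification_sigma=1.0, seed=seed)


def structured_profiles_spec(
    low: float = 0.05, high: float = 0.5, n_low: int = 4, n_high: int = 5, seed: int = 0
) -> CommunitySpec:
    """Community whose two condition groups are programmed to strongly
    different target-group fractions (for ordination / ANOSIM power checks)."""
    taxa = [TaxonSpec("Foraminifera_sp", "Foraminifera", "Bolivina", 200, gc=0.42)]
    taxa += _background_taxa()
    bg = {t.name: 0.75 for t in taxa[1:] if not t.is_contaminant}
    m = sum(int(round(0.75 * t.n_genes)) for t in taxa[1:] if not t.is_contaminant)
    x_low = low * m / (1 - low)
    x_high = high * m / (1 - high)
    samples = []
    for r in range(n_low):
        samples.append(
            SampleSpec(f"oxic_r{r + 1}", "oxic", {**bg, "Foraminifera_sp": round(x_low) / 200}, 20.0)
        )
    for r in range(n_high):
        samples.append(
            SampleSpec(f"anoxic_r{r + 1}", "anoxic", {**bg, "Foraminifera_sp": round(x_high) / 200}, 20.0)
        )
    return CommunitySpec(taxa=tuple(taxa), samples=tuple(samples), seed=seed)
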