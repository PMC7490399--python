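"""End-to-end orchestration: synthesize -> ORFs -> annotate -> filter ->
profile -> stats, with the 18S extension branch running on reads.

A single RunConfig drives every stage; all parameters land in a run manifest
(JSON) together with input checksums, record counts per stage, and the seed,
so a re-run with the same config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from . import __version__
from .annotate import (
    DEFAULT_CONTAMINANT_GENERA,
    apply_thresholds,
    assign_all,
    filter_contaminants,
    search,
)
from .extension import ExtensionParams, SeedOtu, coverage_stats, greedy_extend, trim_seed
from .io import (
    read_contigs,
    read_hit_table,
    read_metadata,
    read_paired_fastq,
    read_reference_fasta,
    write_assignment_table,
    write_fasta,
    write_orf_table,
    write_paired_fastq,
    write_reference_fasta,
    write_truth_table,
)
from .orfs import find_orfs_eukaryotic, find_orfs_prokaryotic
from .profiles import build_profile, fold_change, group_fraction
from .stats import anosim, distance_matrix, group_samples_by_condition, upgma
from .synth import demo_community, generate_reference_set, simulate_18s_reads, simulate_sample


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """All tunable pipeline parameters with the study's stated defaults."""

    outdir: str = "run"
    seed: int = 0
    synthetic: bool = True
    contigs_dir: str | None = None  # per-sample FASTA, used when not synthetic
    reference_db: str | None = None
    hits_dir: str | None = None  # precomputed tabular hits per sample
    metadata: str | None = None
    blocklist: str | None = None
    min_bit: float = 50.0
    min_identity: float = 30.0
    min_len: int = 50
    min_contig_nt: int = 300
    min_orf_aa: int = 100
    extension_iterations: int = 20
    seed_trim: int = 10
    min_overlap: int = 30
    extension_min_identity: float = 95.0
    anosim_permutations: int = 999
    distance_metric: str = "braycurtis"
    group_rule: str = "condition"
    target_group: str = "Foraminifera"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest.

    On stage failure, partial outputs are retained next to a FAILED marker
    naming the stage, and a StageError is raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": [],
        "inputs": {},
    }
    stage = "init"
    try:
        # --- stage 1: synthesize (or load) inputs ---------------------------
        stage = "synthesize"
        samples: dict[str, dict] = {}
        if config.synthetic:
            spec = demo_community(seed=config.seed)
            refs, rrna = generate_reference_set(spec)
            db_path = outdir / "reference_db.fasta"
            write_reference_fasta(db_path, refs)
            rrna_path = outdir / "reference_18s.fasta"
            write_fasta(rrna_path, sorted(rrna.items()))
            meta_rows = ["sample\treplicate\tcondition"]
            for s in spec.samples:
                data = simulate_sample(spec, s.sample_id, seed=config.seed)
                cpath = outdir / f"{s.sample_id}.contigs.fasta"
                write_fasta(cpath, [(c.id, c.sequence) for c in data.contigs])
                write_truth_table(outdir / f"{s.sample_id}.truth.tsv", data.truth)
                samples[s.sample_id] = {
                    "contigs": cpath,
                    "condition": s.condition,
                    "truth": data.truth,
                }
                meta_rows.append(f"{s.sample_id}\t{s.sample_id}\t{s.condition}")
            meta_path = outdir / "metadata.tsv"
            meta_path.write_text("\n".join(meta_rows) + "\n")
            block = list(DEFAULT_CONTAMINANT_GENERA)
            (outdir / "blocklist.txt").write_text("\n".join(block) + "\n")
            # 18S reads for the extension branch
            first_ref = sorted(rrna.items())[0]
            pairs = simulate_18s_reads(first_ref[1], coverage=40.0, seed=config.seed)
            write_paired_fastq(outdir / "rrna_R1.fastq", outdir / "rrna_R2.fastq", pairs)
            rrna_refs = sorted(rrna.items())
            metadata = read_metadata(meta_path)
            manifest["stages"].append(
                {"stage": stage, "samples": len(samples), "reference_proteins": len(refs)}
            )
        else:
            if not (config.contigs_dir and config.reference_db and config.metadata):
                raise ValueError(
                    "non-synthetic runs need contigs_dir, reference_db and metadata"
                )
            refs = read_reference_fasta(config.reference_db)
            manifest["inputs"]["reference_db"] = _sha256(Path(config.reference_db))
            metadata = read_metadata(config.metadata)
            manifest["inputs"]["metadata"] = _sha256(Path(config.metadata))
            block = (
                [g for g in Path(config.blocklist).read_text().split() if g]
                if config.blocklist
                else list(DEFAULT_CONTAMINANT_GENERA)
            )
            for row in metadata.itertuples(index=False):
                cpath = Path(config.contigs_dir) / f"{row.sample}.contigs.fasta"
                samples[row.sample] = {
                    "contigs": cpath,
                    "condition": getattr(row, "condition", None),
                    "truth": None,
                }
                manifest["inputs"][cpath.name] = _sha256(cpath)
            rrna_refs = None
            manifest["stages"].append({"stage": stage, "samples": len(samples)})

        # --- stage 2: ORF calling ------------------------------------------
        stage = "orfs"
        orfs_by_sample: dict[str, dict[str, str]] = {}
        n_orfs = 0
        for sid, info in samples.items():
            contigs = read_contigs(info["contigs"])
            seen = {}
            for contig in contigs:
                for rec in find_orfs_eukaryotic(
                    contig, config.min_orf_aa, config.min_contig_nt
                ) + find_orfs_prokaryotic(contig, config.min_orf_aa, config.min_contig_nt):
                    key = (rec.contig_id, rec.start, rec.end, rec.strand)
                    seen.setdefault(key, rec)
            records = sorted(seen.values(), key=lambda r: (r.contig_id, r.start, r.strand))
            write_orf_table(outdir / f"{sid}.orfs.tsv", records)
            write_fasta(
                outdir / f"{sid}.proteins.fasta",
                [(r.id, r.aa_sequence) for r in records],
            )
            orfs_by_sample[sid] = {r.id: r.aa_sequence for r in records}
            n_orfs += len(records)
        manifest["stages"].append({"stage": stage, "orfs": n_orfs})

        # --- stage 3: annotate ---------------------------------------------
        stage = "annotate"
        assignments_by_sample = {}
        n_hits = 0
        for sid, orfs in orfs_by_sample.items():
            if config.hits_dir:
                hits = read_hit_table(Path(config.hits_dir) / f"{sid}.hits.tsv")
            else:
                hits = search(orfs, refs, min_bit=config.min_bit)
            kept = apply_thresholds(
                hits, config.min_bit, config.min_identity, config.min_len
            )
            n_hits += len(kept)
            assignments_by_sample[sid] = assign_all(kept, orf_ids=orfs.keys())
        manifest["stages"].append({"stage": stage, "hits_kept": n_hits})

        # --- stage 4: contaminant filtering --------------------------------
        stage = "filter"
        profiles = []
        contamination = {}
        for sid, assigns in assignments_by_sample.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kept, removed, frac = filter_contaminants(assigns, block)
            contamination[sid] = {"removed": len(removed), "fraction": round(frac, 4)}
            write_assignment_table(outdir / f"{sid}.assignments.tsv", kept + removed)
            cond = samples[sid]["condition"]
            profiles.append(
                build_profile(
                    [a for a in kept], sid, replicate_id=sid, condition=cond
                )
            )
        manifest["stages"].append({"stage": stage, "contamination": contamination})

        # --- stage 5: profiles + fold change -------------------------------
        stage = "profile"
        rows = ["sample\tcondition\tgroup\tn_orfs\tfraction"]
        for p in profiles:
            for g in sorted(p.n_orfs_by_group):
                rows.append(
                    f"{p.sample_id}\t{p.condition}\t{g}\t{p.n_orfs_by_group[g]}\t"
                    f"{group_fraction(p, g):.6f}"
                )
        (outdir / "profiles.tsv").write_text("\n".join(rows) + "\n")
        conditions = list(
            dict.fromkeys(p.condition for p in profiles if p.condition)
        )  # order of first appearance: baseline condition first
        fc_info = None
        if len(conditions) == 2:
            fc = fold_change(profiles, config.target_group, conditions[0], conditions[1])
            fc_info = {
                "group": fc.group,
                "from": fc.condition_a,
                "to": fc.condition_b,
                "ratio": round(fc.ratio, 3),
                "ratio_range": [round(x, 3) for x in fc.ratio_range],
            }
            (outdir / "fold_change.tsv").write_text(
                "group\tcondition_a\tcondition_b\tfraction_a\tfraction_b\tratio\n"
                f"{fc.group}\t{fc.condition_a}\t{fc.condition_b}\t"
                f"{fc.fraction_a:.6f}\t{fc.fraction_b:.6f}\t{fc.ratio:.4f}\n"
            )
        manifest["stages"].append(
            {"stage": stage, "profiles": len(profiles), "fold_change": fc_info}
        )

        # --- stage 6: community statistics ---------------------------------
        stage = "stats"
        dm = distance_matrix(profiles, metric=config.distance_metric)
        dm.to_frame().to_csv(outdir / "distances.tsv", sep="\t")
        grouping = group_samples_by_condition(metadata, config.group_rule)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = anosim(dm, grouping, config.anosim_permutations, seed=config.seed)
        tree = upgma(dm)
        (outdir / "upgma.nwk").write_text(tree.to_newick() + "\n")
        (outdir / "anosim.json").write_text(
            json.dumps(
                {
                    "R": round(res.R, 4),
                    "p_value": round(res.p_value, 6),
                    "n_permutations": res.n_permutations,
                    "exhaustive": res.exhaustive,
                    "group_sizes": res.group_sizes,
                },
                indent=2,
            )
        )
        manifest["stages"].append(
            {"stage": stage, "anosim_R": round(res.R, 4), "anosim_p": round(res.p_value, 6)}
        )

        # --- extension branch (synthetic demo only) ------------------------
        if config.synthetic and rrna_refs:
            stage = "extend"
            ref_id, ref_seq = rrna_refs[0]
            pairs = read_paired_fastq(outdir / "rrna_R1.fastq", outdir / "rrna_R2.fastq")
            seed_otu = trim_seed(
                SeedOtu("seed", ref_seq[700:1000], ref_id), config.seed_trim
            )
            params = ExtensionParams(
                min_overlap=config.min_overlap,
                min_identity=config.extension_min_identity / 100.0,
                max_iterations=config.extension_iterations,
            )
            state = greedy_extend(seed_otu, pairs, params)
            stats = coverage_stats(state)
            write_fasta(outdir / "consensus_18s.fasta", [("consensus", state.consensus)])
            cov_rows = ["position\tdepth"] + [
                f"{i}\t{c}" for i, c in enumerate(stats.profile)
            ]
            (outdir / "coverage.tsv").write_text("\n".join(cov_rows) + "\n")
            manifest["stages"].append(
                {
                    "stage": stage,
                    "consensus_length": len(state.consensus),
                    "mean_coverage": round(stats.mean, 1),
                    "iterations": state.iteration,
                }
            )
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        raise StageError(stage, exc) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
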