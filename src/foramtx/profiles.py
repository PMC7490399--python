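"""Presence/absence activity profiling of annotated ORFs.

The central statistic: per sample, the number of *unique* expressed ORFs
assigned to a taxon group, divided by the total number of ORFs with a
significant database hit. Read counts are ignored by construction, which
makes the statistic invariant to the heavy per-transcript depth bias that
isothermal amplification introduces — the reason this normalization is used
instead of depth-based measures such as RPKM (implemented below only as a
reference for robustness testing, never as a supported output).

Group fractions can be taken over all assigned ORFs (the
eukaryote-vs-prokaryote split) or over eukaryote-assigned ORFs only (the
protist-group composition); KOG-class composition is computed within a group,
with an optional keyword rule aggregating mitochondria-related annotations.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotate import Assignment, UNASSIGNED
from .synth import PROKARYOTE_GROUPS

MITO_KEYWORDS = ("mitochondria", "mitochondrion", "mitochondrial")
MITO_CATEGORY = "mitochondrial proteins"


class ProfileIntegrityError(ValueError):
    """Raised on duplicate ORF ids with conflicting assignments."""


class UndefinedFractionError(ZeroDivisionError):
    """Raised when a fraction's denominator is zero (degenerate sample)."""


@dataclass(frozen=True)
class SampleProfile:
    """Per-sample table of unique assigned ORFs by group and KOG class."""

    sample_id: str
    replicate_id: str | None
    condition: str | None
    n_orfs_by_group: dict[str, int]
    kog_counts: dict[tuple[str, str], int]
    orf_ids_by_group: dict[str, frozenset[str]]

    @property
    def n_total_assigned(self) -> int:
        return sum(self.n_orfs_by_group.values())

    @property
    def degenerate(self) -> bool:
        return self.n_total_assigned == 0

    def orf_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for ids in self.orf_ids_by_group.values():
            out |= ids
        return frozenset(out)


@dataclass(frozen=True)
class FoldChange:
    """Ratio of a group's mean fraction between two conditions."""

    group: str
    condition_a: str
    condition_b: str
    fraction_a: float
    fraction_b: float
    ratio: float
    ratio_range: tuple[float, float]


def build_profile(
    assignments: Iterable[Assignment],
    sample_id: str,
    replicate_id: str | None = None,
    condition: str | None = None,
) -> SampleProfile:
    """Collapse one sample's contaminant-filtered assignments to a profile.

    Each distinct ORF id counts once (presence/absence); unassigned ORFs are
    excluded from the totals. Duplicate ORF ids must agree on their
    assignment, and contaminant-flagged assignments are rejected because
    filtering is a precondition.
    """
    seen: dict[str, Assignment] = {}
    for a in assignments:
        if a.contaminant:
            raise ProfileIntegrityError(
                f"assignment for {a.orf_id!r} is contaminant-flagged; "
                "profiles require contaminant-filtered input"
            )
        prev = seen.get(a.orf_id)
        if prev is None:
            seen[a.orf_id] = a
        elif (prev.group, prev.genus, prev.kog_class) != (a.group, a.genus, a.kog_class):
            raise ProfileIntegrityError(
                f"duplicate ORF id {a.orf_id!r} with conflicting assignments"
            )
    by_group: Counter[str] = Counter()
    kog: Counter[tuple[str, str]] = Counter()
    ids: defaultdict[str, set[str]] = defaultdict(set)
    for a in seen.values():
        if not a.assigned:
            continue
        by_group[a.group] += 1
        ids[a.group].add(a.orf_id)
        if a.kog_class:
            kog[(a.group, a.kog_class)] += 1
    return SampleProfile(
        sample_id=sample_id,
        replicate_id=replicate_id,
        condition=condition,
        n_orfs_by_group=dict(by_group),
        kog_counts=dict(kog),
        orf_ids_by_group={g: frozenset(s) for g, s in ids.items()},
    )


def group_fraction(
    profile: SampleProfile, group: str, within: str = "assigned"
) -> float:
    """Fraction of unique ORFs in ``group``.

    ``within="assigned"`` divides by all assigned ORFs;
    ``within="eukaryote"`` divides by eukaryote-assigned ORFs only (the
    protist-group composition view).
    """
    if within == "assigned":
        denom = profile.n_total_assigned
    elif within == "eukaryote":
        denom = sum(
            n for g, n in profile.n_orfs_by_group.items() if g not in PROKARYOTE_GROUPS
        )
    else:
        raise ValueError(f"unknown denominator {within!r}")
    if denom == 0:
        raise UndefinedFractionError(
            f"sample {profile.sample_id!r}: no ORFs in denominator {within!r}"
        )
    return profile.n_orfs_by_group.get(group, 0) / denom


def kog_composition(
    profile: SampleProfile,
    group: str,
    descriptions: Mapping[str, str] | None = None,
    aggregate_mitochondrial: bool = False,
) -> dict[str, float]:
    """KOG-class fractions within one group (fractions sum to 1).

    With ``aggregate_mitochondrial`` and a class->description map, classes
    whose description mentions mitochondria/mitochondrion/mitochondrial are
    pooled into a single "mitochondrial proteins" category.
    """
    counts = {
        k: n for (g, k), n in profile.kog_counts.items() if g == group
    }
    if not counts:
        raise UndefinedFractionError(
            f"sample {profile.sample_id!r}: group {group!r} has no KOG-classed ORFs"
        )
    if aggregate_mitochondrial:
        if descriptions is None:
            raise ValueError("aggregate_mitochondrial requires a descriptions map")
        pooled: Counter[str] = Counter()
        for k, n in counts.items():
            desc = descriptions.get(k, "").lower()
            if any(w in desc for w in MITO_KEYWORDS):
                pooled[MITO_CATEGORY] += n
            else:
                pooled[k] += n
        counts = dict(pooled)
    total = sum(counts.values())
    return {k: n / total for k, n in sorted(counts.items())}


def fold_change(
    profiles: Sequence[SampleProfile],
    group: str,
    condition_a: str,
    condition_b: str,
    within: str = "assigned",
) -> FoldChange:
    """Fold change of a group's fraction between two conditions.

    Fractions are averaged over replicates within each condition (the mean of
    fractions, not pooled counts); the per-replicate ratio range pairs every
    b-replicate against every a-replicate.
    """
    fa = [
        group_fraction(p, group, within)
        for p in profiles
        if p.condition == condition_a
    ]
    fb = [
        group_fraction(p, group, within)
        for p in profiles
        if p.condition == condition_b
    ]
    if not fa or not fb:
        raise ValueError(
            f"need profiles in both conditions {condition_a!r} and {condition_b!r}"
        )
    mean_a = sum(fa) / len(fa)
    mean_b = sum(fb) / len(fb)
    if mean_a == 0:
        raise UndefinedFractionError(
            f"condition {condition_a!r} has zero mean fraction for {group!r}; "
            "ratio undefined"
        )
    ratios = [b / a for a in fa if a > 0 for b in fb]
    return FoldChange(
        group=group,
        condition_a=condition_a,
        condition_b=condition_b,
        fraction_a=mean_a,
        fraction_b=mean_b,
        ratio=mean_b / mean_a,
        ratio_range=(min(ratios), max(ratios)),
    )


def rpkm(
    read_counts: Mapping[str, int], lengths_nt: Mapping[str, int], total_reads: int | None = None
) -> dict[str, float]:
    """Reads per kilobase per million mapped reads.

    Reference implementation for robustness comparisons only: the pipeline's
    supported statistic is presence/absence, precisely because RPKM inherits
    the amplification depth bias this measures.
    """
    total = total_reads if total_reads is not None else sum(read_counts.values())
    if total == 0:
        return {k: 0.0 for k in read_counts}
    return {
        k: (c * 1e9) / (lengths_nt[k] * total) for k, c in read_counts.items()
    }
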