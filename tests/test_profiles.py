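"""Activity profiling: presence/absence statistic, fold change, robustness."""

import numpy as np
import pytest

from foramtx.annotate import Assignment
from foramtx.profiles import (
    ProfileIntegrityError,
    UndefinedFractionError,
    build_profile,
    fold_change,
    group_fraction,
    kog_composition,
    rpkm,
)
from foramtx.synth import (
    CommunitySpec,
    SampleSpec,
    TaxonSpec,
    simulate_sample,
    simulate_technical_replicates,
    truth_assignments,
)


def assign(orf_id, group="Foraminifera", genus="Bolivina", kog=None):
    return Assignment(orf_id=orf_id, group=group, genus=genus, kog_class=kog)


class TestBuildProfile:
    def test_fraction_arithmetic(self):
        assigns = [assign(f"f{i}") for i in range(10)] + [
            assign(f"o{i}", group="Ciliophora", genus="Euplotes") for i in range(90)
        ]
        p = build_profile(assigns, "s")
        assert p.n_total_assigned == 100
        assert group_fraction(p, "Foraminifera") == pytest.approx(0.10)

    def test_duplicates_count_once_conflicts_raise(self):
        p = build_profile([assign("a"), assign("a")], "s")
        assert p.n_orfs_by_group == {"Foraminifera": 1}
        with pytest.raises(ProfileIntegrityError):
            build_profile([assign("a"), assign("a", group="Ciliophora")], "s")

    def test_contaminant_input_rejected(self):
        bad = Assignment(orf_id="x", group="Bacteria", genus="Pseudomonas", contaminant=True)
        with pytest.raises(ProfileIntegrityError):
            build_profile([bad], "s")

    def test_unassigned_excluded_and_degenerate_flagged(self):
        p = build_profile([Assignment(orf_id="u", group="unassigned")], "s")
        assert p.degenerate
        with pytest.raises(UndefinedFractionError):
            group_fraction(p, "Foraminifera")

    def test_read_depth_invariance(self):
        """An ORF seen with 1 read and one with 10,000 reads weigh the same:
        the profile is built from assignments alone, and replicates with
        wildly different depths give identical profiles."""
        taxa = (TaxonSpec("A", "Foraminifera", "Bolivina", 20),
                TaxonSpec("B", "Ciliophora", "Euplotes", 20))
        spec = CommunitySpec(
            taxa=taxa,
            samples=(SampleSpec("s", "c", {"A": 0.5, "B": 0.5}),),
            amplification_sigma=3.0,
            seed=9,
        )
        reps = simulate_technical_replicates(spec, "s", k=2, seed=9)
        profiles = [build_profile(truth_assignments(r.truth), "s") for r in reps]
        assert profiles[0].n_orfs_by_group == profiles[1].n_orfs_by_group
        counts = [r.truth.read_counts() for r in reps]
        assert counts[0] != counts[1]  # depths differed; profiles did not


class TestGroupFraction:
    def _profile(self):
        assigns = [assign(f"a{i}", group="A", genus="ga") for i in range(30)] + [
            assign(f"b{i}", group="B", genus="gb") for i in range(70)
        ]
        return build_profile(assigns, "s")

    def test_fractions(self):
        p = self._profile()
        assert group_fraction(p, "A") == pytest.approx(0.3)
        assert group_fraction(p, "missing") == 0.0
        total = sum(group_fraction(p, g) for g in p.n_orfs_by_group)
        assert total == pytest.approx(1.0)

    def test_eukaryote_denominator(self):
        assigns = (
            [assign(f"f{i}") for i in range(10)]
            + [assign(f"c{i}", group="Ciliophora", genus="Euplotes") for i in range(10)]
            + [assign(f"p{i}", group="Bacteria", genus="Desulfobacter") for i in range(80)]
        )
        p = build_profile(assigns, "s")
        assert group_fraction(p, "Foraminifera", within="assigned") == pytest.approx(0.1)
        assert group_fraction(p, "Foraminifera", within="eukaryote") == pytest.approx(0.5)

    def test_monotonicity(self):
        p = self._profile()
        before = group_fraction(p, "A")
        grown = build_profile(
            [assign(f"a{i}", group="A", genus="ga") for i in range(31)]
            + [assign(f"b{i}", group="B", genus="gb") for i in range(70)],
            "s",
        )
        assert group_fraction(grown, "A") > before

    def test_programmed_fraction_recovered(self):
        taxa = (
            TaxonSpec("F", "Foraminifera", "Bolivina", 100),
            TaxonSpec("O", "Ciliophora", "Euplotes", 100),
        )
        spec = CommunitySpec(
            taxa=taxa,
            samples=(SampleSpec("s", "c", {"F": 0.25, "O": 0.75}),),
            seed=21,
        )
        data = simulate_sample(spec, "s", emit_reads=False)
        p = build_profile(truth_assignments(data.truth), "s")
        assert 0.23 <= group_fraction(p, "Foraminifera") <= 0.27


class TestKogComposition:
    def test_equal_split(self):
        assigns = [assign(f"t{i}", kog="T") for i in range(2)] + [
            assign(f"z{i}", kog="Z") for i in range(2)
        ]
        p = build_profile(assigns, "s")
        assert kog_composition(p, "Foraminifera") == {"T": 0.5, "Z": 0.5}

    def test_no_kog_classes_raises(self):
        p = build_profile([assign("a")], "s")
        with pytest.raises(UndefinedFractionError):
            kog_composition(p, "Foraminifera")

    def test_mitochondrial_keyword_aggregation(self):
        assigns = [assign(f"c{i}", kog="C") for i in range(3)] + [assign("t0", kog="T")]
        p = build_profile(assigns, "s")
        comp = kog_composition(
            p,
            "Foraminifera",
            descriptions={"C": "Energy production, mitochondrial", "T": "Signal transduction"},
            aggregate_mitochondrial=True,
        )
        assert comp == {"T": 0.25, "mitochondrial proteins": 0.75}

    def test_planted_composition_recovered(self, rng):
        classes = ["C"] * 120 + ["T"] * 80
        rng.shuffle(classes)
        assigns = [assign(f"o{i}", kog=k) for i, k in enumerate(classes)]
        comp = kog_composition(build_profile(assigns, "s"), "Foraminifera")
        assert comp["C"] == pytest.approx(0.6, abs=0.05)


class TestFoldChange:
    def _profiles(self, fa, fb):
        out = []
        for cond, frac in (("a", fa), ("b", fb)):
            n_f = int(round(frac * 100))
            assigns = [assign(f"f{i}") for i in range(n_f)] + [
                assign(f"o{i}", group="Other", genus="g") for i in range(100 - n_f)
            ]
            out.append(build_profile(assigns, f"s_{cond}", condition=cond))
        return out

    def test_ratio_arithmetic(self):
        fc = fold_change(self._profiles(0.02, 0.60), "Foraminifera", "a", "b")
        assert fc.ratio == pytest.approx(30.0)

    def test_identity(self):
        fc = fold_change(self._profiles(0.3, 0.3), "Foraminifera", "a", "b")
        assert fc.ratio == pytest.approx(1.0)

    def test_zero_baseline_raises(self):
        with pytest.raises(UndefinedFractionError):
            fold_change(self._profiles(0.0, 0.5), "Foraminifera", "a", "b")


class TestRobustness:
    def test_presence_fraction_more_stable_than_rpkm(self):
        """The methods claim: under strong amplification bias the group
        fraction's across-replicate CV is >= 5x smaller than the median
        per-ORF RPKM CV on the same data."""
        taxa = (
            TaxonSpec("F", "Foraminifera", "Bolivina", 60),
            TaxonSpec("O", "Ciliophora", "Euplotes", 60),
        )
        spec = CommunitySpec(
            taxa=taxa,
            samples=(SampleSpec("s", "c", {"F": 0.8, "O": 0.8}, depth_weight=30.0),),
            amplification_sigma=2.0,
            seed=31,
        )
        reps = simulate_technical_replicates(spec, "s", k=5, seed=31)
        orf_ids = sorted(reps[0].truth.entries)
        lengths = {
            oid: reps[0].truth.entries[oid].gene_end - reps[0].truth.entries[oid].gene_start
            for oid in orf_ids
        }
        rpkm_rows = []
        fractions = []
        for r in reps:
            counts = r.truth.read_counts()
            rpkm_rows.append([rpkm(counts, lengths)[oid] for oid in orf_ids])
            present = [e for e in r.truth.entries.values() if e.read_pairs > 0]
            fractions.append(
                sum(e.group == "Foraminifera" for e in present) / len(present)
            )
        R = np.array(rpkm_rows)
        cv_rpkm = R.std(axis=0, ddof=1) / np.maximum(R.mean(axis=0), 1e-12)
        cv_frac = np.std(fractions, ddof=1) / np.mean(fractions)
        assert np.median(cv_rpkm) >= 5 * cv_frac
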