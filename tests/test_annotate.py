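"""Annotation: thresholds, best-hit tie-breaks, contaminant filtering, KOG."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foramtx.annotate import (
    Assignment,
    ContaminationWarning,
    HeaderSchemaError,
    HitRecord,
    ReferenceProtein,
    UNASSIGNED,
    annotate_kog,
    apply_thresholds,
    assign_all,
    assign_best_hit,
    filter_contaminants,
    format_header,
    parse_header,
    search,
)


def hit(q="orf1", s="ref|Foraminifera|Bolivina|C", bit=60.0, pid=90.0, length=100, ev=1e-20):
    _, group, genus, kog = parse_header(s)
    return HitRecord(q, s, pid, length, ev, bit, group, genus, kog)


class TestHeaders:
    def test_round_trip(self):
        h = format_header("g1", "Foraminifera", "Bolivina", "C")
        assert parse_header(h) == ("g1", "Foraminifera", "Bolivina", "C")

    def test_missing_kog_allowed(self):
        assert parse_header("g1|Bacteria|Pseudomonas|")[3] is None

    @pytest.mark.parametrize("bad", ["g1|onlygroup", "g1||Bolivina|C", "g1|Grp|Gen|CC"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(HeaderSchemaError):
            parse_header(bad)


class TestThresholds:
    # hand-enumerated 20-row table around the (bit 50, identity 30, length 50)
    # boundaries; "minimum X" is inclusive, so each exact boundary survives
    TABLE = [
        # (bit, pid, length, survives)
        (50.0, 30.0, 50, True),   # all three exactly at the boundary
        (49.9, 95.0, 200, False),  # bit just below
        (50.1, 29.9, 200, False),  # identity just below
        (80.0, 30.0, 49, False),   # length just below
        (50.0, 95.0, 200, True),
        (200.0, 30.0, 50, True),
        (49.0, 29.0, 49, False),
        (51.0, 31.0, 51, True),
        (100.0, 100.0, 500, True),
        (0.1, 100.0, 500, False),
        (100.0, 5.0, 500, False),
        (100.0, 100.0, 1, False),
        (50.0, 30.0, 51, True),
        (50.0, 31.0, 50, True),
        (51.0, 30.0, 50, True),
        (49.99, 30.0, 50, False),
        (50.0, 29.99, 50, False),
        (75.0, 45.0, 75, True),
        (60.0, 30.0, 50, True),
        (45.0, 99.0, 400, False),
    ]

    def test_hand_enumerated_survivors(self):
        hits = [hit(q=f"o{i}", bit=b, pid=p, length=l) for i, (b, p, l, _) in enumerate(self.TABLE)]
        kept = apply_thresholds(hits, 50, 30, 50)
        expected = [f"o{i}" for i, (_, _, _, s) in enumerate(self.TABLE) if s]
        assert [h.query_id for h in kept] == expected

    def test_empty_list(self):
        assert apply_thresholds([]) == []

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 500, allow_nan=False),
                st.floats(0, 100, allow_nan=False),
                st.integers(1, 1000),
            ),
            max_size=30,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_idempotent(self, rows):
        hits = [hit(q=f"o{i}", bit=b, pid=p, length=l) for i, (b, p, l) in enumerate(rows)]
        once = apply_thresholds(hits, 50, 30, 50)
        assert apply_thresholds(once, 50, 30, 50) == once


class TestBestHit:
    def test_highest_bit_wins(self):
        hits = [hit(s="a|GrpA|GenA|C", bit=75), hit(s="b|GrpB|GenB|D", bit=80)]
        assert assign_best_hit("orf1", hits).group == "GrpB"

    def test_tie_broken_by_evalue(self):
        hits = [
            hit(s="a|GrpA|GenA|C", bit=60, ev=1e-8),
            hit(s="b|GrpB|GenB|D", bit=60, ev=1e-10),
        ]
        assert assign_best_hit("orf1", hits).group == "GrpB"

    def test_no_hits_is_unassigned(self):
        a = assign_best_hit("orf1", [])
        assert a.group == UNASSIGNED and not a.assigned

    def test_matches_argmax_oracle_on_random_tables(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 8))
            hits = [
                hit(
                    s=f"r{j}|G{j}|Gen{j}|C",
                    bit=float(rng.integers(50, 55)),
                    ev=float(10.0 ** -rng.integers(5, 15)),
                )
                for j in range(n)
            ]
            best = assign_best_hit("o", hits).best_hit
            # brute-force argmax with the documented tie-break
            oracle = sorted(hits, key=lambda h: (-h.bit_score, h.evalue, h.subject_id))[0]
            assert best == oracle

    def test_order_invariance(self, rng):
        hits = [hit(s=f"r{j}|G|Gen{j}|C", bit=60 + (j % 3)) for j in range(6)]
        perm = [hits[i] for i in rng.permutation(len(hits))]
        assert assign_best_hit("o", hits) == assign_best_hit("o", perm)


class TestContaminants:
    def _assignments(self, genera):
        return [
            Assignment(orf_id=f"o{i}", group="Bacteria", genus=g) for i, g in enumerate(genera)
        ]

    def test_three_of_ten_blocklisted(self):
        assigns = self._assignments(["Pseudomonas"] * 3 + ["Desulfobacter"] * 7)
        with pytest.warns(ContaminationWarning):
            kept, removed, frac = filter_contaminants(assigns, {"Pseudomonas"})
        assert len(kept) == 7 and len(removed) == 3
        assert frac == pytest.approx(0.30)
        assert all(a.contaminant for a in removed)

    def test_empty_blocklist(self):
        kept, removed, frac = filter_contaminants(self._assignments(["X"] * 5), set())
        assert removed == [] and frac == 0.0

    def test_all_contaminant(self):
        with pytest.warns(ContaminationWarning):
            kept, removed, frac = filter_contaminants(
                self._assignments(["Pseudomonas"] * 4), {"Pseudomonas"}
            )
        assert kept == [] and frac == 1.0

    def test_below_warning_threshold_is_silent(self):
        assigns = self._assignments(["Pseudomonas"] + ["Desulfobacter"] * 19)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            _, _, frac = filter_contaminants(assigns, {"Pseudomonas"})
        assert frac == pytest.approx(0.05)


class TestSearchAndKog:
    def test_planted_protein_recovers_taxon_and_kog(self, tiny_spec):
        """Error-free synthetic ORFs assign to their true group at >= 99% and
        planted KOG classes are recovered exactly."""
        from foramtx.synth import generate_reference_set, simulate_sample

        refs, _ = generate_reference_set(tiny_spec)
        data = simulate_sample(tiny_spec, "s1", emit_reads=False)
        queries = {oid: e.protein for oid, e in data.truth.entries.items()}
        hits = apply_thresholds(search(queries, refs), 50, 30, 50)
        assigns = assign_all(hits, orf_ids=queries.keys())
        correct = sum(
            a.group == data.truth.entries[a.orf_id].group
            and a.kog_class == data.truth.entries[a.orf_id].kog_class
            for a in assigns
        )
        assert correct / len(assigns) >= 0.99

    def test_kog_below_bit_threshold_absent(self):
        db = [ReferenceProtein("k1", "Foraminifera", "Bolivina", "T", "MKVLAWFYHQDE" * 10)]
        # a short query: its best hit cannot reach 50 bits
        out = annotate_kog({"o1": "MKVLA"}, db)
        assert out["o1"] is None

    def test_empty_kog_db(self):
        assert annotate_kog({"o1": "MKVLAWFYHQDE" * 10}, []) == {"o1": None}

    def test_exhaustive_and_prefiltered_search_agree(self, tiny_spec):
        from foramtx.synth import generate_reference_set, simulate_sample

        refs, _ = generate_reference_set(tiny_spec)
        data = simulate_sample(tiny_spec, "s1", emit_reads=False)
        queries = dict(
            list({oid: e.protein for oid, e in data.truth.entries.items()}.items())[:5]
        )
        with_filter = search(queries, refs, prefilter_k=6)
        exhaustive = search(queries, refs, prefilter_k=None)
        key = lambda h: (h.query_id, h.subject_id)
        assert sorted(with_filter, key=key) == sorted(exhaustive, key=key)
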