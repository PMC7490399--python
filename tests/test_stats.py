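"""Community statistics: distances, ANOSIM, UPGMA, grouping rules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from foramtx.annotate import Assignment
from foramtx.profiles import build_profile
from foramtx.stats import (
    DistanceMatrix,
    GroupingError,
    anosim,
    distance_matrix,
    distance_matrix_from_vectors,
    group_samples_by_condition,
    n_label_arrangements,
    upgma,
)
from oracles import anosim_exhaustive


def profile_from_counts(sid, counts, condition=None):
    assigns = [
        Assignment(orf_id=f"{sid}_{g}_{i}", group=g, genus="gen")
        for g, n in counts.items()
        for i in range(n)
    ]
    return build_profile(assigns, sid, condition=condition)


class TestDistances:
    def test_identical_profiles_distance_zero(self):
        p1 = profile_from_counts("a", {"F": 3, "O": 7})
        p2 = profile_from_counts("b", {"F": 3, "O": 7})
        dm = distance_matrix([p1, p2])
        assert dm.data[0, 1] == 0.0

    def test_bray_curtis_hand_arithmetic(self):
        # x = (0.2, 0.8), y = (0.6, 0.4) -> (0.4 + 0.4) / 2 = 0.4
        p1 = profile_from_counts("a", {"F": 2, "O": 8})
        p2 = profile_from_counts("b", {"F": 6, "O": 4})
        dm = distance_matrix([p1, p2])
        assert dm.data[0, 1] == pytest.approx(0.4)

    def test_disjoint_presence_sets_jaccard_one(self):
        p1 = profile_from_counts("a", {"F": 5})
        p2 = profile_from_counts("b", {"O": 5})
        dm = distance_matrix([p1, p2], metric="jaccard", feature_space="orf_presence")
        assert dm.data[0, 1] == 1.0

    def test_matrix_invariants(self):
        rng = np.random.default_rng(3)
        profiles = [
            profile_from_counts(f"s{i}", {"F": int(rng.integers(1, 20)), "O": 10})
            for i in range(5)
        ]
        dm = distance_matrix(profiles)
        assert (dm.data >= 0).all() and (dm.data <= 1).all()
        assert np.allclose(dm.data, dm.data.T)


class TestAnosim:
    def _separated(self):
        """Two groups with all between-distances above all within-distances."""
        ids = ["a1", "a2", "a3", "b1", "b2", "b3"]
        d = np.zeros((6, 6))
        for i, j in itertools.combinations(range(6), 2):
            same = (i < 3) == (j < 3)
            d[i, j] = d[j, i] = 0.1 if same else 0.9
        return DistanceMatrix(tuple(ids), d, "braycurtis"), {
            s: s[0] for s in ids
        }

    def test_perfect_separation_gives_r_one(self):
        dm, grouping = self._separated()
        res = anosim(dm, grouping, n_permutations=999, seed=0)
        assert res.R == pytest.approx(1.0)
        assert res.exhaustive  # 20 arrangements <= 999

    def test_all_equal_distances_give_r_zero(self):
        ids = tuple("abcdef")
        d = np.full((6, 6), 0.5)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(ids, d, "braycurtis")
        res = anosim(dm, {s: ("g1" if s < "d" else "g2") for s in ids}, seed=0)
        assert res.R == pytest.approx(0.0)

    def test_matches_exhaustive_enumeration_oracle(self):
        """R and exact p equal independent enumeration over all 6!/(3!3!)
        label arrangements on a hand-made matrix."""
        rng = np.random.default_rng(8)
        d = np.zeros((6, 6))
        for i, j in itertools.combinations(range(6), 2):
            d[i, j] = d[j, i] = round(float(rng.random()), 3)
        ids = tuple(f"s{i}" for i in range(6))
        labels = ["x", "x", "x", "y", "y", "y"]
        dm = DistanceMatrix(ids, d, "braycurtis")
        res = anosim(dm, dict(zip(ids, labels)), n_permutations=999, seed=1)
        r_oracle, p_oracle, n_arr = anosim_exhaustive(d, labels)
        assert n_arr == 20
        assert res.R == pytest.approx(r_oracle)
        assert res.p_value == pytest.approx(p_oracle)

    def test_r_matches_scikit_bio(self):
        """Independent cross-check of Clarke's R against scikit-bio."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import anosim as skbio_anosim

        rng = np.random.default_rng(12)
        d = squareform(rng.random(28))
        ids = [f"s{i}" for i in range(8)]
        labels = ["g1"] * 4 + ["g2"] * 4
        res = anosim(
            DistanceMatrix(tuple(ids), d, "x"), dict(zip(ids, labels)), seed=0
        )
        sk = skbio_anosim(SkbioDM(d, ids), grouping=labels, permutations=99)
        assert res.R == pytest.approx(sk["test statistic"])

    def test_single_group_rejected(self):
        dm, _ = self._separated()
        with pytest.raises(GroupingError):
            anosim(dm, {s: "g" for s in dm.ids})

    def test_singleton_group_warns(self):
        dm, _ = self._separated()
        grouping = {s: ("solo" if s == "a1" else "rest") for s in dm.ids}
        with pytest.warns(UserWarning, match="singleton"):
            anosim(dm, grouping, seed=0)

    def test_permutation_floor_for_study_design(self):
        """9 samples in groups of 2/4/3: 1260 distinct arrangements, so the
        smallest attainable exact p is 1/1260 ~ 0.00079."""
        assert n_label_arrangements((2, 4, 3)) == 1260
        rng = np.random.default_rng(2)
        X = rng.dirichlet(np.ones(5), size=9)
        # strong separation so the observed arrangement is uniquely extreme
        X[:2, 0] += 10
        X[2:6, 1] += 10
        X[6:, 2] += 10
        X = X / X.sum(axis=1, keepdims=True)
        ids = [f"s{i}" for i in range(9)]
        labels = ["t0"] * 2 + ["onset"] * 4 + ["prolonged"] * 3
        dm = distance_matrix_from_vectors(ids, X)
        res = anosim(dm, dict(zip(ids, labels)), n_permutations=1500, seed=0)
        assert res.exhaustive and res.n_permutations == 1260
        assert res.p_value == pytest.approx(1 / 1260)


class TestUpgma:
    def test_two_samples_merge_at_half_distance(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0, 0.4], [0.4, 0]]), "m")
        tree = upgma(dm)
        assert tree.root.height == pytest.approx(0.2)

    def test_three_sample_hand_case(self):
        # d(A,B)=2, d(A,C)=d(B,C)=6 -> merge (A,B) at height 1, then C at 3
        d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float)
        tree = upgma(DistanceMatrix(("A", "B", "C"), d, "m"))
        assert tree.root.height == pytest.approx(3.0)
        inner = [c for c in tree.root.children if not c.is_leaf][0]
        assert sorted(inner.leaves()) == ["A", "B"]
        assert inner.height == pytest.approx(1.0)

    def test_ultrametric_input_is_fixed_point(self):
        d = np.array(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], dtype=float
        )
        dm = DistanceMatrix(("a", "b", "c", "d"), d, "m")
        assert np.allclose(upgma(dm).cophenetic().data, d)

    def test_matches_scipy_average_linkage(self, rng):
        """Cophenetic distances equal scipy's average-linkage agglomeration
        on random 8x8 matrices (my heights are half of scipy's merge
        distances, so cophenetic distances coincide)."""
        for _ in range(10):
            cond = rng.random(28)
            dm = DistanceMatrix(
                tuple(f"s{i}" for i in range(8)), squareform(cond), "m"
            )
            mine = squareform(upgma(dm).cophenetic().data, checks=False)
            ref = cophenet(linkage(cond, method="average"))
            assert np.allclose(mine, ref)

    def test_ultrametric_and_monotone_heights(self, rng):
        cond = rng.random(45)
        tree = upgma(DistanceMatrix(tuple(f"s{i}" for i in range(10)), squareform(cond), "m"))

        def heights(node, acc):
            if not node.is_leaf:
                acc.append(node.height)
                for c in node.children:
                    assert c.height <= node.height
                    heights(c, acc)
            return acc

        heights(tree.root, [])
        coph = tree.cophenetic().data
        # three-point condition: the two largest of any triple are equal
        for i, j, k in itertools.combinations(range(10), 3):
            trio = sorted([coph[i, j], coph[i, k], coph[j, k]])
            assert trio[1] == pytest.approx(trio[2])

    def test_newick_round_trips_through_dendropy(self):
        import dendropy

        d = np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], dtype=float)
        tree = upgma(DistanceMatrix(("A", "B", "C"), d, "m"))
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == {"A", "B", "C"}


class TestGrouping:
    def test_nitrate_rule(self):
        meta = pd.DataFrame(
            {
                "sample": ["ct", "mid", "deep"],
                "depth": ["0-2", "12", "28"],
                "nitrate": ["yes", "yes", "no"],
            }
        )
        g = group_samples_by_condition(meta, "nitrate_present")
        assert g == {
            "ct": "nitrate_present",
            "mid": "nitrate_present",
            "deep": "nitrate_absent",
        }

    def test_incubation_phases_give_2_4_3(self):
        tps = ["t0", "t0", "18h", "1d", "2d", "3d", "7d", "10d", "10d"]
        meta = pd.DataFrame({"sample": [f"s{i}" for i in range(9)], "timepoint": tps})
        g = group_samples_by_condition(meta, "incubation_phase")
        sizes = pd.Series(list(g.values())).value_counts().to_dict()
        assert sizes == {"onset_anoxia": 4, "prolonged_anoxia": 3, "oxic_t0": 2}

    def test_empty_metadata_rejected(self):
        with pytest.raises(GroupingError):
            group_samples_by_condition(pd.DataFrame(), "nitrate_present")

    def test_unknown_rule_rejected(self):
        meta = pd.DataFrame({"sample": ["a"], "condition": ["x"]})
        with pytest.raises(GroupingError):
            group_samples_by_condition(meta, "phase_of_moon")
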