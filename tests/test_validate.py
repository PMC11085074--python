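import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pairgrn.network import EdgeList
from pairgrn.validate import (
    ReferenceNetwork,
    ValidationError,
    bh_adjust,
    count_overlap,
    fold_enrichment,
    hypergeometric_target_overlap,
    overlap_percentage,
    per_tf_enrichment_table,
    permutation_expected_overlap,
)


def _edges(rows):
    return EdgeList(pd.DataFrame(rows, columns=["tf_id", "target_id", "score"]))


class TestCountOverlap:
    def test_identical_networks(self):
        e = _edges([("a", "x", 0.9), ("a", "y", 0.8), ("b", "x", 0.7)])
        ref = ReferenceNetwork({"a": {"x", "y"}, "b": {"x"}})
        observed, comparable = count_overlap(e, ref)
        assert observed == comparable == 3

    def test_disjoint_gene_sets(self):
        e = _edges([("a", "x", 0.9)])
        ref = ReferenceNetwork({"q": {"z"}})
        assert count_overlap(e, ref) == (0, 0)

    def test_comparable_counts_only_shared_tfs(self):
        e = _edges([("a", "x", 0.9)])
        ref = ReferenceNetwork({"a": {"x", "y"}, "b": {"z"}})
        observed, comparable = count_overlap(e, ref)
        assert observed == 1
        assert comparable == 2  # b's edge not comparable

    def test_overlap_percentage(self):
        assert overlap_percentage(1245, 9353) == pytest.approx(13.31, abs=0.005)


class TestFoldEnrichment:
    def test_equal_gives_one(self):
        assert fold_enrichment(42, 42.0) == 1.0

    def test_expected_zero_flagged_infinite(self):
        assert math.isinf(fold_enrichment(5, 0.0))

    def test_negative_expected_rejected(self):
        with pytest.raises(ValidationError):
            fold_enrichment(1, -1.0)


class TestPermutationOverlap:
    def test_saturated_network_fold_one(self):
        universe = [f"g{i}" for i in range(6)]
        e = _edges([("a", g, 0.9) for g in universe])
        ref = ReferenceNetwork({"a": {"g0", "g1"}})
        result = permutation_expected_overlap(e, ref, universe, 200, seed=0)
        assert result.expected_overlap == result.observed_overlap == 2
        assert result.range == (2, 2)
        assert result.fold_enrichment == 1.0
        assert result.empirical_p == 0.0

    def test_mean_matches_closed_form(self):
        # E[overlap] = sum_tf d_tf * r_tf / N under degree-preserving nulls
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(40)]
        rows, ref_targets = [], {}
        for t in range(6):
            tf = f"tf{t}"
            d = int(rng.integers(3, 15))
            rows += [(tf, g, 0.5) for g in rng.choice(universe, d, replace=False)]
            r = int(rng.integers(2, 12))
            ref_targets[tf] = set(rng.choice(universe, r, replace=False))
        e = _edges(rows)
        ref = ReferenceNetwork(ref_targets)
        result = permutation_expected_overlap(e, ref, universe, 10_000, seed=1)
        closed = sum(
            len(e.targets_of()[tf]) * len(ref_targets[tf]) / len(universe)
            for tf in ref_targets
        )
        assert result.expected_overlap == pytest.approx(closed, rel=0.02)

    def test_same_seed_identical_result(self):
        universe = [f"g{i}" for i in range(10)]
        e = _edges([("a", "g0", 0.9), ("a", "g1", 0.8)])
        ref = ReferenceNetwork({"a": {"g1", "g2"}})
        a = permutation_expected_overlap(e, ref, universe, 500, seed=3)
        b = permutation_expected_overlap(e, ref, universe, 500, seed=3)
        assert a == b

    def test_p_label_below_resolution(self):
        universe = [f"g{i}" for i in range(4)]
        e = _edges([("a", g, 0.9) for g in universe])
        ref = ReferenceNetwork({"a": set(universe)})
        result = permutation_expected_overlap(e, ref, universe, 100, seed=0)
        assert result.p_label.startswith("<")

    def test_target_outside_universe_rejected(self):
        e = _edges([("a", "rogue", 0.9)])
        ref = ReferenceNetwork({"a": {"g0"}})
        with pytest.raises(ValidationError, match="universe"):
            permutation_expected_overlap(e, ref, ["g0", "g1"], 10, seed=0)


class TestHypergeometricOverlap:
    def test_hand_computed_tail(self):
        universe = set("abcdefghij")
        p = hypergeometric_target_overlap(set("abcd"), set("abcde"), universe)
        assert p == pytest.approx(5 / 210)

    def test_zero_overlap_large_universe(self):
        universe = {f"g{i}" for i in range(1000)}
        p = hypergeometric_target_overlap({"g0", "g1"}, {"g500", "g501"}, universe)
        assert p == pytest.approx(1.0, abs=0.01)

    def test_predicted_equals_universe(self):
        universe = {f"g{i}" for i in range(8)}
        assert hypergeometric_target_overlap(universe, {"g0"}, universe) == 1.0

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_target_overlap({"z"}, {"a"}, {"a", "b"})

    def test_matches_subset_enumeration_oracle(self):
        # exact check against brute-force enumeration of all draws
        rng = np.random.default_rng(7)
        for _ in range(20):
            n_universe = int(rng.integers(4, 11))
            universe = list(range(n_universe))
            n_draw = int(rng.integers(1, n_universe + 1))
            n_ref = int(rng.integers(1, n_universe + 1))
            ref = set(rng.choice(universe, n_ref, replace=False).tolist())
            pred = set(rng.choice(universe, n_draw, replace=False).tolist())
            k = len(pred & ref)
            total = hits = 0
            for subset in itertools.combinations(universe, n_draw):
                total += 1
                hits += len(set(subset) & ref) >= k
            p = hypergeometric_target_overlap(
                {str(g) for g in pred}, {str(g) for g in ref},
                {str(g) for g in universe},
            )
            assert p == pytest.approx(hits / total, rel=1e-10)


class TestBHAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.random(25))
        q = bh_adjust(p)
        assert (np.diff(q) >= -1e-12).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        p = rng.random(15)
        perm = rng.permutation(15)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_q_at_least_p(self):
        rng = np.random.default_rng(3)
        p = rng.random(20)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestPerTFEnrichment:
    def test_membership_rule(self):
        e = _edges([("a", "x", 0.9)])
        ref = ReferenceNetwork({"a": {"x"}, "only_ref": {"y"}})
        records, summary = per_tf_enrichment_table(e, ref, ["x", "y", "z"])
        assert [r.tf_id for r in records] == ["a"]
        assert summary["n_reference_tfs"] == 2
        assert summary["n_shared_tfs"] == 1
        assert summary["shared_tf_percentage"] == 50.0

    def test_empty_predicted_network(self):
        e = EdgeList(pd.DataFrame(columns=["tf_id", "target_id", "score"]))
        ref = ReferenceNetwork({"a": {"x"}})
        records, summary = per_tf_enrichment_table(e, ref, ["x"])
        assert records == [] and summary["n_shared_tfs"] == 0

    def test_strong_overlap_significant(self):
        universe = [f"g{i}" for i in range(60)]
        shared = {f"g{i}" for i in range(8)}
        e = _edges([("a", g, 0.9) for g in shared])
        ref = ReferenceNetwork({"a": set(shared)})
        records, summary = per_tf_enrichment_table(e, ref, universe)
        assert summary["n_significant"] == 1
        assert records[0].q >= records[0].p


def test_reference_network_empty_target_set_rejected():
    with pytest.raises(ValidationError):
        ReferenceNetwork({"a": set()})


def test_reference_network_from_tsv(tmp_path):
    path = tmp_path / "ref.tsv"
    path.write_text("tf_id\ttarget_id\tsource\na\tx\tChIP\na\ty\tChIP\nb\tz\tChIP\n")
    ref = ReferenceNetwork.from_tsv(path)
    assert ref.targets == {"a": {"x", "y"}, "b": {"z"}}
    assert ref.n_edges == 3
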