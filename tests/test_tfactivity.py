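"""Fold-change computation and TF-activation calls, incl. invariants."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import moarank as mr
from moarank.io import TFTargetMap
from moarank.tfactivity import FoldChangeProfile, activation_score


def profile_of(values: dict) -> FoldChangeProfile:
    return FoldChangeProfile(values=pd.Series(values, dtype=float), mode="ratio")


def expr_of(rows: dict, case, control) -> mr.ExpressionMatrix:
    df = pd.DataFrame(rows, index=case + control).T
    groups = {s: "case" for s in case} | {s: "control" for s in control}
    return mr.ExpressionMatrix(values=df, groups=groups)


class TestFoldChange:
    def test_ratio_of_group_means(self):
        expr = expr_of({"g1": [4, 6, 2, 3]}, ["c1", "c2"], ["n1", "n2"])
        prof = mr.compute_fold_change(expr)
        assert prof["g1"] == pytest.approx(2.0)

    def test_identity_when_groups_equal(self):
        expr = expr_of({"g2": [3, 3]}, ["c1"], ["n1"])
        assert mr.compute_fold_change(expr)["g2"] == pytest.approx(1.0)

    def test_zero_control_mean_gene_dropped(self):
        expr = expr_of({"g1": [4, 2], "g3": [5, 0]}, ["c1"], ["n1"])
        prof = mr.compute_fold_change(expr)
        assert "g3" not in prof and "g1" in prof

    def test_all_zero_control_is_fatal(self):
        expr = expr_of({"g": [1, 0]}, ["c1"], ["n1"])
        with pytest.raises(ValueError):
            mr.compute_fold_change(expr)


class TestActivationScore:
    tfmap = TFTargetMap(targets={"TF": frozenset({"a", "b", "c", "d"}),
                                 "TF2": frozenset({"p", "q"})})

    def test_mean_of_top3_when_enough_targets(self):
        prof = profile_of({"a": 5, "b": 3, "c": 1, "d": 0.5})
        score, chosen = activation_score("TF", prof, self.tfmap)
        assert score == pytest.approx(3.0)
        assert set(chosen) == {"a", "b", "c"}

    def test_mean_of_all_when_two_targets(self):
        prof = profile_of({"p": 1.5, "q": 2.5})
        score, _ = activation_score("TF2", prof, self.tfmap)
        assert score == pytest.approx(2.0)

    def test_insensitive_to_values_below_top3(self):
        hi = profile_of({"a": 4, "b": 4, "c": 4})
        with_low = profile_of({"a": 4, "b": 4, "c": 4, "d": 0.1})
        assert activation_score("TF", hi, self.tfmap)[0] == \
               activation_score("TF", with_low, self.tfmap)[0] == pytest.approx(4.0)

    def test_no_available_targets_yields_nan(self):
        score, chosen = activation_score("TF", profile_of({"zzz": 9}), self.tfmap)
        assert math.isnan(score) and chosen == ()

    def test_unknown_tf_is_named(self):
        with pytest.raises(KeyError, match="NOPE"):
            activation_score("NOPE", profile_of({"a": 1}), self.tfmap)

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=8),
           st.randoms(use_true_random=False))
    def test_permutation_invariant(self, values, rnd):
        genes = [f"g{i}" for i in range(len(values))]
        tfmap = TFTargetMap(targets={"T": frozenset(genes)})
        base = activation_score("T", profile_of(dict(zip(genes, values))), tfmap)[0]
        shuffled = list(zip(genes, values))
        rnd.shuffle(shuffled)
        again = activation_score("T", profile_of(dict(shuffled)), tfmap)[0]
        assert base == pytest.approx(again)

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=8),
           st.integers(0, 7), st.floats(0.1, 10))
    def test_raising_a_target_never_lowers_score(self, values, idx, bump):
        genes = [f"g{i}" for i in range(len(values))]
        tfmap = TFTargetMap(targets={"T": frozenset(genes)})
        before = activation_score("T", profile_of(dict(zip(genes, values))), tfmap)[0]
        raised = list(values)
        raised[idx % len(values)] += bump
        after = activation_score("T", profile_of(dict(zip(genes, raised))), tfmap)[0]
        assert after >= before - 1e-9


class TestIdentifyActivated:
    def test_threshold_is_inclusive_at_exactly_2(self):
        tfmap = TFTargetMap(targets={"T": frozenset({"a"})})
        acts = mr.identify_activated_tfs(profile_of({"a": 2.0}), tfmap, threshold=2.0)
        assert acts[0].activated is True

    def test_flat_profile_activates_nothing(self):
        tfmap = TFTargetMap(targets={"T1": frozenset({"a", "b"}), "T2": frozenset({"c"})})
        acts = mr.identify_activated_tfs(
            profile_of({"a": 1.0, "b": 1.0, "c": 1.0}), tfmap, threshold=2.0
        )
        assert not any(a.activated for a in acts)

    def test_case_equal_control_means_no_activation(self):
        expr = expr_of({"a": [7, 7], "b": [3, 3]}, ["c1"], ["n1"])
        prof = mr.compute_fold_change(expr)
        tfmap = TFTargetMap(targets={"T": frozenset({"a", "b"})})
        acts = mr.identify_activated_tfs(prof, tfmap)
        assert [a.activated for a in acts] == [False]

    def test_planted_activations_recovered_exactly(self, universe):
        prof = mr.compute_fold_change(universe["expr"])
        acts = mr.identify_activated_tfs(prof, universe["tfmap"])
        called = {a.tf for a in acts if a.activated}
        planted = set(universe["truth"].activated_tfs)
        # drug-private TFs are never activated in the patient profile
        assert called == planted

    def test_empty_tfmap_fatal(self):
        with pytest.raises(ValueError):
            mr.identify_activated_tfs(profile_of({"a": 1}), TFTargetMap(targets={}))


class TestUpregulatedTargets:
    tfmap = TFTargetMap(targets={"T1": frozenset({"g1", "g2"}), "T2": frozenset({"g1"})})

    def act(self, tf, activated=True):
        return mr.TFActivation(tf=tf, score=3.0, activated=activated,
                               contributing_targets=())

    def test_threshold_inclusive_and_filtering(self):
        prof = profile_of({"g1": 3, "g2": 1})
        assert mr.upregulated_targets([self.act("T1")], prof, self.tfmap) == {"g1"}

    def test_no_activated_tfs_gives_empty_set(self):
        assert mr.upregulated_targets([], profile_of({"g1": 9}), self.tfmap) == set()
        assert mr.upregulated_targets(
            [self.act("T1", activated=False)], profile_of({"g1": 9}), self.tfmap
        ) == set()

    def test_shared_target_counted_once_at_boundary(self):
        prof = profile_of({"g1": 2.0})
        out = mr.upregulated_targets([self.act("T1"), self.act("T2")], prof, self.tfmap)
        assert out == {"g1"}
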