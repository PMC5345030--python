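"""Selection cutoffs, contact classification and incremental restraint sets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tracefold.io import ContactPrediction
from tracefold.restraints import (
    CutoffRule,
    classify,
    cutoff_count,
    error_rate_cutoff,
    incremental_sets,
    select_top,
)
from tracefold.structure import BasePair, Chain, SecondaryStructure


def preds_with_labels(labels):
    return [
        ContactPrediction(k, k + 10, score=float(len(labels) - k), rank=k + 1,
                          category=lab)
        for k, lab in enumerate(labels)
    ]


def brute_force_error_cutoff(labels, e):
    """Largest prefix whose false fraction stays within e (oracle)."""
    best = 0
    for k in range(1, len(labels) + 1):
        if labels[:k].count("false") / k <= e:
            best = k
    return best


class TestCutoffCount:
    @pytest.mark.parametrize("L, expected", [(100, 30), (4, 6), (94, 28), (400, 105)])
    def test_default_rule_values(self, L, expected):
        assert cutoff_count(L) == expected

    def test_monotone_in_length(self):
        counts = [cutoff_count(L) for L in range(1, 400)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_sits_below_the_all_pairs_line_for_long_molecules(self):
        # 5 + L/4 <= L/3 once L >= 60
        assert all(5 + L / 4 <= L / 3 for L in range(60, 1000))

    def test_custom_rule(self):
        assert cutoff_count(100, CutoffRule(intercept=0, divisor=2)) == 50


class TestSelectTop:
    def test_truncates_to_cutoff(self):
        preds = preds_with_labels(["non_local"] * 50)
        assert len(select_top(preds, L=100)) == 30

    def test_short_supply_keeps_all(self, caplog):
        preds = preds_with_labels(["non_local"] * 10)
        assert len(select_top(preds, L=100)) == 10

    def test_empty_input(self):
        assert len(select_top([], L=100)) == 0


class TestClassify:
    @pytest.fixture()
    def scene(self):
        # a straight trace: residue k at (6k, 0, 0); distances are 6*|i-j|
        chain = Chain.from_coords(
            np.column_stack([6.0 * np.arange(12), np.zeros(12), np.zeros(12)])
        )
        observed = SecondaryStructure.from_pairs(
            [BasePair(0, 11), BasePair(1, 10), BasePair(2, 9)], 12
        )
        rnafold = {BasePair(0, 11)}
        return chain, observed, rnafold

    def test_priority_shared_then_extra_then_distance(self, scene):
        chain, observed, rnafold = scene
        preds = [
            ContactPrediction(0, 11, 4.0, 1),   # in rnafold (and observed)
            ContactPrediction(1, 10, 3.0, 2),   # observed nested only
            ContactPrediction(3, 5, 2.0, 3),    # 12 A apart -> non-local
            ContactPrediction(3, 8, 1.0, 4),    # 30 A apart -> false
        ]
        cats = [p.category for p in classify(preds, chain, observed, rnafold)]
        assert cats == ["shared_local", "extra_local", "non_local", "false"]

    def test_exact_21A_is_still_non_local(self, scene):
        chain, observed, rnafold = scene
        chain2 = chain.with_coords(
            np.vstack([chain.coords[:-1], [[chain.coords[0, 0] + 21.0, 0, 0]]])
        )
        empty = SecondaryStructure.from_pairs([], 12)
        (got,) = classify(
            [ContactPrediction(0, 11, 1.0, 1)], chain2, empty, rnafold_pairs=[]
        )
        assert got.category == "non_local"

    def test_out_of_range_contact_raises(self, scene):
        chain, observed, rnafold = scene
        with pytest.raises(IndexError):
            classify([ContactPrediction(0, 99, 1.0, 1)], chain, observed, rnafold)

    def test_recovers_planted_labels_on_synthetic_fixture(self, y_linked):
        from tracefold.synthetic import synth_predictions

        preds, labels = synth_predictions(
            y_linked, n_true_nonlocal=1, n_false=3, seed=5
        )
        got = classify(preds, y_linked.chain, y_linked.ss, y_linked.ss.nested)
        for p in got:
            planted = labels[p.pair]
            if planted == "local":
                assert p.category in ("shared_local", "extra_local")
            else:
                assert p.category == planted


class TestErrorRateCutoff:
    def test_worked_example(self):
        preds = preds_with_labels(["non_local", "non_local", "false", "non_local"])
        assert error_rate_cutoff(preds, 0.5) == 4

    def test_all_true_runs_to_the_end(self):
        preds = preds_with_labels(["shared_local"] * 7)
        assert error_rate_cutoff(preds, 0.0) == 7

    def test_false_first_with_zero_budget(self):
        preds = preds_with_labels(["false", "non_local"])
        assert error_rate_cutoff(preds, 0.0) == 0

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        labels=st.lists(st.sampled_from(["non_local", "false"]), max_size=12),
        e=st.sampled_from([0.0, 0.01, 0.05, 0.25, 0.5, 1.0]),
    )
    def test_matches_brute_force_and_is_monotone_in_budget(self, labels, e):
        preds = preds_with_labels(labels)
        assert error_rate_cutoff(preds, e) == brute_force_error_cutoff(labels, e)
        assert error_rate_cutoff(preds, min(1.0, e + 0.3)) >= error_rate_cutoff(preds, e)


class TestIncrementalSets:
    def test_prefix_chain(self, y_predictions):
        preds, _ = y_predictions
        from tracefold.restraints import RestraintSet

        subsets = incremental_sets(RestraintSet(tuple(preds)))
        assert [len(s) for s in subsets] == list(range(len(preds) + 1))
        for a, b in zip(subsets, subsets[1:]):
            assert a.entries == b.entries[: len(a.entries)]
        scores = [e.score for e in subsets[-1].entries]
        assert scores == sorted(scores, reverse=True)
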