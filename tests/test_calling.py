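import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_table
from ligasetrap.calling import (
    CallingConfig,
    call_candidates,
    enrichment_score,
    nsaf,
    rank_candidates,
)
from ligasetrap.io import RunMetadata, SpectralCountTable
from oracles import brute_force_calls


def make_table(counts, n_bait=3, n_control=2, lengths=None):
    counts = np.asarray(counts)
    runs = [RunMetadata(f"b{i}", "bait", i + 1) for i in range(n_bait)] + [
        RunMetadata(f"c{i}", "control", i + 1) for i in range(n_control)
    ]
    return SpectralCountTable(
        proteins=[f"p{i}" for i in range(counts.shape[0])],
        runs=runs,
        counts=counts,
        lengths=lengths,
    )


class TestEnrichmentScore:
    def test_mean_over_mean(self):
        assert enrichment_score([12, 11, 13], [2, 2]) == 6.0

    def test_zero_bait_is_zero(self):
        assert enrichment_score([0, 0, 0], [3, 4]) == 0.0

    def test_pseudocount_floors_zero_background(self):
        assert enrichment_score([10], [0, 0], pseudocount=0.5) == 20.0

    def test_zero_pseudocount_flags_infinite(self):
        assert math.isinf(enrichment_score([10], [0, 0], pseudocount=0.0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            enrichment_score([-1], [0])


class TestCallCandidates:
    def test_clean_candidate_called(self, small_table):
        calls = {c.protein: c for c in call_candidates(small_table, "bait")}
        assert calls["clean"].is_candidate
        assert calls["clean"].n_bait_detected == 3
        assert calls["clean"].n_control_detected == 0

    def test_control_detection_disqualifies(self, small_table):
        calls = {c.protein: c for c in call_candidates(small_table, "bait")}
        assert not calls["sticky"].is_candidate
        assert calls["sticky"].n_control_detected >= 1

    def test_all_zero_protein_not_candidate(self, small_table):
        calls = {c.protein: c for c in call_candidates(small_table, "bait")}
        assert not calls["silent"].is_candidate

    def test_two_of_three_rule(self):
        t = make_table([[3, 3, 0, 0, 0], [3, 0, 0, 0, 0]])
        calls = {c.protein: c for c in call_candidates(t, "bait")}
        assert calls["p0"].is_candidate  # SUN2-like (3,3,0)
        assert not calls["p1"].is_candidate  # single run only

    def test_unknown_bait_raises(self, small_table):
        with pytest.raises(KeyError, match="nonesuch"):
            call_candidates(small_table, "nonesuch")

    def test_no_controls_degraded_mode_warns(self):
        t = make_table([[5, 5, 5]], n_control=0)
        with pytest.warns(UserWarning, match="control"):
            calls = call_candidates(t, "bait")
        assert calls[0].is_candidate

    def test_family_exclusion_poisons_whole_group(self):
        # one HLA-like allele in controls excludes the control-clean one too
        t = make_table([[5, 5, 5, 0, 0], [4, 4, 4, 2, 0], [6, 6, 6, 0, 0]])
        cfg = CallingConfig(exclusion_groups=(frozenset({"p0", "p1"}),))
        calls = {c.protein: c for c in call_candidates(t, "bait", cfg)}
        assert not calls["p0"].is_candidate
        assert "p1" in calls["p0"].excluded_reason
        assert not calls["p1"].is_candidate
        assert calls["p2"].is_candidate  # outside the group, unaffected

    def test_exclusion_group_inert_when_no_member_in_controls(self):
        t = make_table([[5, 5, 5, 0, 0], [4, 4, 4, 0, 0]])
        cfg = CallingConfig(exclusion_groups=(frozenset({"p0", "p1"}),))
        assert all(c.is_candidate for c in call_candidates(t, "bait", cfg))

    @settings(deadline=None, max_examples=60)
    @given(
        st.integers(0, 2**31 - 1),
        st.integers(2, 3),
        st.integers(1, 3),
    )
    def test_matches_brute_force_oracle(self, seed, min_runs, threshold):
        """Calling equals an independent re-derivation of the rule on
        small random tables."""
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_proteins=6, max_count=3)
        cfg = CallingConfig(min_bait_runs=min_runs, presence_threshold=threshold)
        got = {c.protein for c in call_candidates(t, "bait", cfg) if c.is_candidate}
        counts = {
            p: {r.run_id: int(t.counts[i, j]) for j, r in enumerate(t.runs)}
            for i, p in enumerate(t.proteins)
        }
        baits = {r.run_id: r.bait for r in t.runs}
        expected = brute_force_calls(t.proteins, counts, baits, min_runs, threshold)
        assert got == expected

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_raising_thresholds_never_adds_candidates(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_proteins=8, max_count=4)
        base = {c.protein for c in call_candidates(t, "bait") if c.is_candidate}
        for cfg in (
            CallingConfig(min_bait_runs=3),
            CallingConfig(presence_threshold=2),
            CallingConfig(min_bait_runs=3, presence_threshold=3),
        ):
            stricter = {
                c.protein for c in call_candidates(t, "bait", cfg) if c.is_candidate
            }
            assert stricter <= base

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2**31 - 1), st.integers(0, 7))
    def test_adding_control_evidence_only_removes(self, seed, victim):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_proteins=8, max_count=4)
        before = {c.protein for c in call_candidates(t, "bait") if c.is_candidate}
        extra = np.zeros((len(t.proteins), 1), dtype=int)
        extra[victim, 0] = 1
        t2 = SpectralCountTable(
            proteins=t.proteins,
            runs=t.runs + [RunMetadata("c_extra", "control", 9)],
            counts=np.hstack([t.counts, extra]),
        )
        after = {c.protein for c in call_candidates(t2, "bait") if c.is_candidate}
        assert after <= before
        assert before - after <= {t.proteins[victim]}


class TestNsaf:
    def test_equal_counts_equal_lengths_split_evenly(self):
        t = make_table([[10, 0, 0, 0, 0], [10, 0, 0, 0, 0]], lengths={"p0": 100, "p1": 100})
        assert nsaf(t, "b0") == {"p0": 50000.0, "p1": 50000.0}

    def test_equal_saf_split_evenly(self):
        t = make_table(
            [[10, 0, 0, 0, 0], [20, 0, 0, 0, 0], [30, 0, 0, 0, 0]],
            lengths={"p0": 100, "p1": 200, "p2": 300},
        )
        vals = nsaf(t, "b0")
        assert all(v == pytest.approx(1e5 / 3) for v in vals.values())

    def test_all_zero_run_warns_empty(self):
        t = make_table([[0, 1, 0, 0, 0]], lengths={"p0": 100})
        with pytest.warns(UserWarning, match="no nonzero"):
            assert nsaf(t, "b0") == {}

    def test_missing_lengths_rejected(self):
        t = make_table([[10, 0, 0, 0, 0]])
        with pytest.raises(ValueError, match="lengths"):
            nsaf(t, "b0")

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation_sums_to_1e5(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_proteins=int(rng.integers(1, 30)), max_count=50)
        for run in t.run_ids:
            vals = nsaf(t, run) if t.counts[:, t.run_index(run)].sum() else {}
            if vals:
                assert sum(vals.values()) == pytest.approx(1e5, rel=1e-9)


class TestRankCandidates:
    def test_fixture_order_by_abundance(self, table1):
        from ligasetrap.pipeline import fixture_with_controls

        t = fixture_with_controls(table1)
        calls = [c for c in call_candidates(t, "bTRCP") if c.is_candidate]
        ranked = rank_candidates(calls)
        assert ranked[0].protein == "HIVEP1/2"  # 82 total TSC
        crep_pos = [c.protein for c in ranked].index("CReP")
        assert crep_pos > 0  # below HIVEP1/2 (36 vs 82)

    def test_ties_break_lexically(self):
        t = make_table([[5, 5, 5, 0, 0], [5, 5, 5, 0, 0]])
        ranked = rank_candidates(call_candidates(t, "bait"))
        assert [c.protein for c in ranked] == ["p0", "p1"]

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_proteins=10, max_count=6)
        calls = call_candidates(t, "bait")
        perm = list(rng.permutation(len(calls)))
        shuffled = [calls[i] for i in perm]
        assert [c.protein for c in rank_candidates(shuffled)] == [
            c.protein for c in rank_candidates(calls)
        ]
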