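import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ligasetrap.degron import (
    ACIDIC_VARIANT,
    CANONICAL,
    RELAXED,
    DegronModel,
    DegronMatch,
    best_degron,
    compare_orthologs,
    scan,
)
from ligasetrap.io import ProteinRecord
from oracles import brute_force_degron_windows

MODEL = DegronModel()

sequences = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60)


def rec(seq, pid="x"):
    return ProteinRecord(pid, seq)


class TestScan:
    def test_canonical_minimal_window(self):
        (m,) = scan(rec("DSGAS"), MODEL)
        assert (m.start, m.end, m.spacer_len) == (1, 5, 1)
        assert m.matched_string == "DSGAS"
        assert m.variant_class == CANONICAL
        assert m.score == pytest.approx(3.0)

    def test_crep_region_top_hit(self):
        hits = scan(rec("DDGFDSDSSLSDSD"), MODEL)
        top = hits[0]
        assert top.start == 1
        assert top.matched_string.startswith("DDGFDSD")
        assert top.variant_class == ACIDIC_VARIANT

    def test_poly_alanine_empty(self):
        assert scan(rec("A" * 50), MODEL) == []

    def test_too_short_sequence_empty(self):
        assert scan(rec("DSG"), MODEL) == []

    def test_planted_motif_is_top_hit(self):
        rng = np.random.default_rng(7)
        bg = "".join(rng.choice(list("ACFHIKLMNPQRVWY"), size=200))
        seq = bg[:56] + "DSGNNS" + bg[62:]
        top = scan(rec(seq), MODEL)[0]
        assert top.start == 57
        assert top.matched_string == "DSGNNS"

    def test_min_score_filters(self):
        hits = scan(rec("DDGFDSDSSLSDSD"), MODEL, min_score=2.9)
        assert hits and all(h.score >= 2.9 for h in hits)

    def test_sorted_by_score_then_start(self):
        hits = scan(rec("DSGASAAADSGAS"), MODEL)
        scores = [h.score for h in hits]
        assert scores == sorted(scores, reverse=True)
        same = [h for h in hits if h.score == hits[0].score]
        assert [h.start for h in same] == sorted(h.start for h in same)

    @settings(max_examples=300)
    @given(sequences)
    def test_agrees_with_brute_force_enumeration(self, seq):
        """Scanner output equals exhaustive substring enumeration scored
        by an independent implementation of the same model."""
        got = {(m.start, m.end): m.score for m in scan(rec(seq), MODEL)}
        expected = {k: s for k, (s, _) in brute_force_degron_windows(seq).items()}
        assert set(got) == set(expected)
        for k in got:
            assert got[k] == pytest.approx(expected[k])

    @settings(max_examples=100)
    @given(sequences, st.integers(0, 10_000))
    def test_upgrading_a_class_residue_never_lowers_score(self, seq, choice):
        """Replacing a class residue with a higher-weighted residue of
        the same class never lowers that window's score."""
        hits = scan(rec(seq), MODEL)
        if not hits:
            return
        m = hits[choice % len(hits)]
        # upgrade p1 to D (top weight) and p_last to S
        chars = list(seq)
        chars[m.start - 1] = "D"
        chars[m.end - 1] = "S"
        upgraded = "".join(chars)
        again = {(h.start, h.end): h.score for h in scan(rec(upgraded), MODEL)}
        assert again[(m.start, m.end)] >= m.score - 1e-12


class TestBestDegron:
    def test_fnip1_style_window(self):
        m = best_degron(rec("AAADSGIARSAAA"), MODEL)
        assert m.matched_string == "DSGIARS"
        assert m.spacer_len == 3

    def test_tie_breaks_on_spacer_then_start(self):
        # two canonical windows with identical residues: equal score
        m = best_degron(rec("DSGASAAADSGAS"), MODEL)
        assert m.start == 1

    def test_znf704_best_of_two_motifs(self):
        seq = "AAA" + "DDGIDEAE" + "AAAA" + "SDGEED" + "AAA"
        m = best_degron(rec(seq), MODEL)
        hits = scan(rec(seq), MODEL)
        assert m.score == max(h.score for h in hits)
        assert {h.start for h in hits} >= {4, 16}  # both motifs reported

    def test_none_when_nothing_passes(self):
        assert best_degron(rec("AAAAAAA"), MODEL) is None


class TestRelaxedWindows:
    def test_gless_degron_matches_as_relaxed(self):
        hits = scan(rec("DTTFLLD"), MODEL)
        assert hits and hits[0].variant_class == RELAXED
        assert hits[0].matched_string == "DTTFLLD"

    def test_gless_never_beats_overlapping_glycine_window(self):
        hits = scan(rec("DSGASDSD"), MODEL)
        assert hits[0].variant_class in (CANONICAL, ACIDIC_VARIANT)

    def test_transposed_glycine_requires_opt_in(self):
        assert scan(rec("DGDFFSYT"), MODEL) == []
        relaxed = DegronModel(allow_transposed_g=True)
        hits = scan(rec("DGDFFSYT"), relaxed)
        assert hits and hits[0].variant_class == RELAXED

    def test_strict_model_rejects_gless(self):
        strict = DegronModel(allow_gless=False)
        assert scan(rec("DTTFLLD"), strict) == []


class TestModelValidation:
    def test_score_bound(self):
        assert MODEL.max_score == pytest.approx(3.2)

    def test_bad_weight_rejected(self):
        with pytest.raises(ValueError):
            DegronModel(p1_weights=(("D", 1.5),))

    def test_empty_spacer_range_rejected(self):
        with pytest.raises(ValueError):
            DegronModel(spacer_min=3, spacer_max=2)

    def test_match_coordinates_consistent(self):
        with pytest.raises(ValueError):
            DegronMatch("x", 1, 5, "DSGA", 1, 3.0, CANONICAL)


class TestCompareOrthologs:
    def test_identical_sequences_full_identity(self):
        seqs = {
            "p": {
                "human": rec("AAADSGASAAA", "p"),
                "mouse": rec("AAADSGASAAA", "p"),
            }
        }
        df = compare_orthologs(seqs)
        mouse = df[df.species == "mouse"].iloc[0]
        assert mouse.identity == 1.0

    def test_single_substitution_identity(self):
        human = "AAAADSGASAAAA"
        mouse = "AAAADSGATAAAA"  # S->T in final degron position
        df = compare_orthologs(
            {"p": {"human": rec(human, "p"), "mouse": rec(mouse, "p")}}
        )
        m = df[df.species == "mouse"].iloc[0]
        L = len(df[df.species == "human"].iloc[0].best_degron)
        assert m.identity == pytest.approx((L - 1) / L)

    def test_conserved_degron_in_shuffled_flanks(self):
        rng = np.random.default_rng(3)
        bg = lambda n: "".join(rng.choice(list("ACFHIKLMNPQRVWY"), size=n))
        degron = "DSGNNS"
        human = bg(30) + degron + bg(30)
        mouse = bg(30) + degron + bg(30)
        df = compare_orthologs(
            {"p": {"human": rec(human, "p"), "mouse": rec(mouse, "p")}}
        )
        m = df[df.species == "mouse"].iloc[0]
        assert m.identity == 1.0  # degron conserved though flanks differ
        pos = df[df.species == "human"].iloc[0].positional_identity
        assert pos == [1.0] * len(degron)

    def test_ortholog_without_window_recorded_absent(self):
        df = compare_orthologs(
            {"p": {"human": rec("AAADSGASAAA", "p"), "chicken": rec("MKVLRIW", "p")}}
        )
        assert df[df.species == "chicken"].iloc[0].best_degron == "absent"

    def test_requires_two_species(self):
        with pytest.raises(ValueError):
            compare_orthologs({"p": {"human": rec("DSGAS", "p")}})
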