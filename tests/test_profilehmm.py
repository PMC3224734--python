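import math

import numpy as np
import pytest

from cypmod.profilehmm import (
    BuildParams,
    FragmentError,
    ProfileError,
    align_query,
    build_profile,
    forward_score,
    profile_from_json,
    profile_to_json,
    sample_path,
)
from cypmod.seqio import AMINO_ACIDS, ProteinSequence

from bruteforce import (
    brute_forward,
    brute_viterbi,
    random_profile,
    random_query,
)
from toys import gapfree_toy, insert_column_toy, pseudocount_toy


class TestBuildProfile:
    def test_gapfree_alignment_makes_every_column_a_match_state(self):
        profile = build_profile(*gapfree_toy())
        assert profile.n_match == 4
        assert [m.source_column for m in profile.match_states] == [1, 2, 3, 4]

    def test_pseudocount_emission_formula(self):
        # column 2 holds {A, A, V}; alpha=1, uniform background:
        # e(A) = (2 + 0.05)/4, e(V) = (1 + 0.05)/4, others 0.05/4
        profile = build_profile(*pseudocount_toy())
        e = profile.match_states[1].emissions
        idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
        assert e[idx["A"]] == pytest.approx(0.5125, abs=1e-12)
        assert e[idx["V"]] == pytest.approx(0.2625, abs=1e-12)
        assert e[idx["W"]] == pytest.approx(0.0125, abs=1e-12)

    def test_low_occupancy_column_becomes_insert(self):
        profile = build_profile(*insert_column_toy())
        assert profile.n_match == 4
        assert [m.source_column for m in profile.match_states] == [1, 2, 4, 5]

    def test_anchor_column_forced_despite_low_occupancy(self):
        seed, ann = insert_column_toy()
        # re-annotate the sparse column 3 as the hotspot anchor
        from toys import make_toy_seed

        seed, ann = make_toy_seed(
            [("REF", "EFACR"), ("S1", "EY-CR"), ("S2", "EL-CR")],
            f87_col=3, glu_col=1, arg_col=5, cys_col=4,
        )
        profile = build_profile(seed, ann)
        assert profile.n_match == 5
        assert profile.anchor_states["f87"] == 2

    def test_normalisation_of_all_probability_groups(self, default_profile):
        p = default_profile
        for m in p.match_states:
            assert math.isclose(sum(m.emissions), 1.0, abs_tol=1e-9)
        for m in p.match_states[:-1]:
            assert math.isclose(m.m_to_m + m.m_to_i + m.m_to_d, 1.0, abs_tol=1e-9)
        for k in range(p.n_match - 1):
            assert math.isclose(p.i_to_m[k] + p.i_to_i[k], 1.0, abs_tol=1e-9)
            assert math.isclose(p.d_to_m[k] + p.d_to_d[k], 1.0, abs_tol=1e-9)
        assert math.isclose(p.begin_to_m + p.begin_to_d, 1.0, abs_tol=1e-9)

    def test_anchor_columns_always_match_states(self, default_profile, seed_annotation):
        cols = {m.source_column for m in default_profile.match_states}
        assert set(seed_annotation.anchor_columns.values()) <= cols


class TestAlignQuery:
    def test_reference_self_alignment_is_identity(self, default_profile, seed_alignment):
        from cypmod.seedmodel import column_to_row_pos_or_none

        ref = seed_alignment.reference
        mapping = align_query(default_profile, ref.to_sequence())
        # identity: each match state maps to the reference position of its
        # source column (or is deleted where the reference shows a gap);
        # reference residues in low-occupancy linker columns come back as
        # insertions, exactly as laid out in the seed
        expected = [
            column_to_row_pos_or_none(ref, m.source_column)
            for m in default_profile.match_states
        ]
        assert list(mapping.assignments) == expected

    def test_gapfree_reference_self_alignment_has_no_indels(self):
        seed, ann = gapfree_toy()
        profile = build_profile(seed, ann)
        mapping = align_query(
            profile, seed.reference.to_sequence(), allow_fragment=True
        )
        assert mapping.assignments == (1, 2, 3, 4)
        assert mapping.insertions == ()
        assert (mapping.n_flank, mapping.c_flank) == (0, 0)

    def test_viterbi_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            L = int(rng.integers(1, 7))
            n = int(rng.integers(1, 9))
            profile = random_profile(rng, L)
            s = random_query(rng, n)
            got = align_query(
                profile, ProteinSequence(id="q", residues=s), allow_fragment=True
            ).score_bits
            want = brute_viterbi(profile, s)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_mapping_partitions_query_positions(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            profile = random_profile(rng, int(rng.integers(2, 7)))
            n = int(rng.integers(1, 12))
            s = random_query(rng, n)
            m = align_query(
                profile, ProteinSequence(id="q", residues=s), allow_fragment=True
            )
            assert m.all_positions_partition(n)

    def test_near_deterministic_emissions_recover_generating_path(self, default_profile):
        rng = np.random.default_rng(11)
        seq, truth = sample_path(default_profile, rng, mode="mainline")
        mapping = align_query(default_profile, seq, allow_fragment=True)
        assert mapping.assignments == truth.assignments
        assert mapping.insertions == ()

    def test_fragment_guard(self, default_profile):
        short = ProteinSequence(id="frag", residues="MKVLY" * 6)  # 30 aa
        with pytest.raises(FragmentError, match="fragment"):
            align_query(default_profile, short)


class TestForwardScore:
    def test_forward_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(60):
            profile = random_profile(rng, int(rng.integers(1, 7)))
            s = random_query(rng, int(rng.integers(1, 9)))
            got = forward_score(
                profile, ProteinSequence(id="q", residues=s), allow_fragment=True
            )
            want = brute_forward(profile, s)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_single_state_single_residue_closed_form(self):
        rng = np.random.default_rng(3)
        profile = random_profile(rng, 1)
        seq = ProteinSequence(id="q", residues="A")
        e_a = profile.match_states[0].emissions[0]
        q_a = profile.background[0]
        # two paths: B->M1 emitting 'A', or B->D1 with 'A' as flank; the
        # flank split of the delete path gives it multiplicity 2.
        expected = math.log2(
            profile.begin_to_m * (e_a / q_a) + 2 * profile.begin_to_d
        )
        assert forward_score(profile, seq, allow_fragment=True) == pytest.approx(
            expected, rel=1e-12
        )

    def test_forward_dominates_viterbi(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            profile = random_profile(rng, int(rng.integers(1, 6)))
            seq = ProteinSequence(id="q", residues=random_query(rng, int(rng.integers(1, 10))))
            v = align_query(profile, seq, allow_fragment=True).score_bits
            f = forward_score(profile, seq, allow_fragment=True)
            assert f >= v - 1e-12


class TestSamplePath:
    def test_mainline_has_no_indels_and_full_length(self, default_profile):
        seq, mapping = sample_path(default_profile, 1, mode="mainline")
        assert len(seq) == default_profile.n_match
        assert mapping.insertions == ()
        assert all(p is not None for p in mapping.assignments)

    def test_fixed_seed_is_deterministic(self, default_profile):
        s1, m1 = sample_path(default_profile, 123, mode="faithful")
        s2, m2 = sample_path(default_profile, 123, mode="faithful")
        assert s1.residues == s2.residues
        assert m1.assignments == m2.assignments

    def test_faithful_sampling_matches_emission_table(self):
        rng = np.random.default_rng(9)
        profile = random_profile(rng, 1)
        counts = np.zeros(20)
        draws = 10_000
        srng = np.random.default_rng(10)
        for _ in range(draws):
            seq, _ = sample_path(profile, srng, mode="faithful")
            counts[AMINO_ACIDS.index(seq.residues)] += 1
        freq = counts / draws
        e = np.asarray(profile.match_states[0].emissions)
        se = np.sqrt(e * (1 - e) / draws)
        assert np.all(np.abs(freq - e) <= 3 * se + 1e-12)


class TestFlanksAndSerialization:
    def test_flanking_residues_do_not_move_anchors(self, default_profile, seed_alignment):
        rng = np.random.default_rng(8)
        ref = seed_alignment.reference.to_sequence()
        base = align_query(default_profile, ref)
        anchors = {
            name: base.assignments[k]
            for name, k in default_profile.anchor_states.items()
        }
        for _ in range(20):
            nf = random_query(rng, int(rng.integers(1, 30)))
            cf = random_query(rng, int(rng.integers(1, 30)))
            padded = ProteinSequence(id="p", residues=nf + ref.residues + cf)
            m = align_query(default_profile, padded)
            for name, k in default_profile.anchor_states.items():
                assert m.assignments[k] == anchors[name] + len(nf)

    def test_json_round_trip_is_exact(self, default_profile):
        back = profile_from_json(profile_to_json(default_profile))
        assert back == default_profile

    def test_bad_payload_rejected(self):
        with pytest.raises(ProfileError):
            profile_from_json({"format": "something-else"})
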