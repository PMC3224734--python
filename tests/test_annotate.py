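import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cypmod.annotate import (
    ABSENT,
    REDOX_CLASSES,
    UNDEFINED,
    ClassThresholds,
    GateParams,
    annotate_sequence,
    applicability_gate,
    classify_redox,
    measure_ris,
    predict_f87,
    transfer_scrs,
)
from cypmod.profilehmm import FragmentError, QueryMapping, align_query
from cypmod.seqio import ProteinSequence
from cypmod.synthetic import generate_queries


def _identity_mapping(profile, seq):
    return align_query(profile, seq, allow_fragment=True)


class TestTransferScrs:
    def test_identity_transfer_matches_seed_truth(
        self, default_profile, seed_alignment, seed_annotation, seed_truth
    ):
        ref = seed_alignment.reference.to_sequence()
        mapping = _identity_mapping(default_profile, ref)
        got = transfer_scrs(mapping, seed_annotation, default_profile)
        truth = seed_truth[0].scr_intervals
        assert got == truth

    def test_fully_deleted_scr_reported_absent(
        self, default_profile, seed_annotation
    ):
        ref_map = None
        # construct a path deleting every state of SCR5
        scr = seed_annotation.scr_by_name("SCR5")
        states = default_profile.match_states_in_span(scr.start_col, scr.end_col)
        L = default_profile.n_match
        assignments = []
        pos = 0
        for k in range(L):
            if k in states:
                assignments.append(None)
            else:
                pos += 1
                assignments.append(pos)
        mapping = QueryMapping(
            query_id="q",
            assignments=tuple(assignments),
            insertions=(),
            n_flank=0,
            c_flank=0,
            score_bits=0.0,
        )
        got = transfer_scrs(mapping, seed_annotation, default_profile)
        assert got["SCR5"] is ABSENT
        assert got["SCR6"] is not ABSENT

    def test_leading_deletion_shifts_interval_start(
        self, default_profile, seed_annotation
    ):
        scr = seed_annotation.scr_by_name("SCR2")
        states = default_profile.match_states_in_span(scr.start_col, scr.end_col)
        L = default_profile.n_match
        assignments = []
        pos = 0
        for k in range(L):
            if k == states[0]:
                assignments.append(None)  # first state of SCR2 deleted
            else:
                pos += 1
                assignments.append(pos)
        mapping = QueryMapping(
            query_id="q",
            assignments=tuple(assignments),
            insertions=(),
            n_flank=0,
            c_flank=0,
            score_bits=0.0,
        )
        got = transfer_scrs(mapping, seed_annotation, default_profile)
        assert got["SCR2"][0] == assignments[states[1]]


class TestPredictF87:
    def test_reference_hotspot_recovered(
        self, default_profile, seed_alignment, seed_truth
    ):
        ref = seed_alignment.reference.to_sequence()
        mapping = _identity_mapping(default_profile, ref)
        call = predict_f87(mapping, default_profile, ref)
        assert call == (seed_truth[0].anchor_pos, seed_truth[0].anchor_res)

    def test_deleted_anchor_state_gives_gap_call(self, default_profile):
        L = default_profile.n_match
        k87 = default_profile.anchor_states["f87"]
        assignments = tuple(
            None if k == k87 else k + 1 if k < k87 else k for k in range(L)
        )
        mapping = QueryMapping(
            query_id="q",
            assignments=assignments,
            insertions=(),
            n_flank=0,
            c_flank=0,
            score_bits=0.0,
        )
        seq = ProteinSequence(id="q", residues="A" * L)
        assert predict_f87(mapping, default_profile, seq) is None

    def test_generated_query_anchor_recovered(self, default_profile, seed_annotation):
        seqs, truths = generate_queries(n=5, rng_seed=99)
        for seq, t in zip(seqs, truths):
            mapping = _identity_mapping(default_profile, seq)
            assert predict_f87(mapping, default_profile, seq) == (
                t.anchor_pos,
                t.anchor_res,
            )


class TestMeasureRis:
    def test_identity_lengths_match_seed_truth(
        self, default_profile, seed_alignment, seed_annotation, seed_truth
    ):
        for row, truth in zip(seed_alignment.rows, seed_truth):
            mapping = _identity_mapping(default_profile, row.to_sequence())
            assert measure_ris(mapping, seed_annotation, default_profile, "RIS1") == truth.ris1_len
            assert measure_ris(mapping, seed_annotation, default_profile, "RIS2") == truth.ris2_len

    @pytest.mark.parametrize("k", [1, 6])
    def test_constructed_insertion_adds_exactly_its_length(
        self, default_profile, seed_alignment, seed_annotation, k
    ):
        # path-level oracle: splice an insert run into the mapping itself,
        # midway between the RIS1 anchors, and shift downstream positions
        ref = seed_alignment.reference.to_sequence()
        base_map = _identity_mapping(default_profile, ref)
        base = measure_ris(base_map, seed_annotation, default_profile, "RIS1")
        base_scrs = transfer_scrs(base_map, seed_annotation, default_profile)
        left = default_profile.anchor_states["ris1_left"]
        right = default_profile.anchor_states["ris1_right"]
        host = (left + right) // 2  # emitting state inside the span
        p = base_map.assignments[host]
        assert p is not None

        def shift(pos):
            return pos if pos is None or pos <= p else pos + k

        padded_map = QueryMapping(
            query_id="ins",
            assignments=tuple(shift(x) for x in base_map.assignments),
            insertions=tuple(
                sorted(
                    [(s, tuple(shift(x) for x in run)) for s, run in base_map.insertions]
                    + [(host, tuple(range(p + 1, p + k + 1)))]
                )
            ),
            n_flank=base_map.n_flank,
            c_flank=base_map.c_flank,
            score_bits=0.0,
        )
        got = measure_ris(padded_map, seed_annotation, default_profile, "RIS1")
        assert got == base + k
        scrs = transfer_scrs(padded_map, seed_annotation, default_profile)
        for name, iv in base_scrs.items():
            assert scrs[name][1] - scrs[name][0] == iv[1] - iv[0]

    def test_midspan_insertion_recovered_after_realignment(
        self, default_profile, seed_alignment, seed_annotation
    ):
        # away from the anchors, a real spliced insertion survives Viterbi
        # realignment and is counted in full
        ref = seed_alignment.reference.to_sequence()
        base_map = _identity_mapping(default_profile, ref)
        base = measure_ris(base_map, seed_annotation, default_profile, "RIS1")
        lk = default_profile.anchor_states["ris1_left"]
        rk = default_profile.anchor_states["ris1_right"]
        mid = (base_map.assignments[lk] + base_map.assignments[rk]) // 2
        padded = ProteinSequence(
            id="ins", residues=ref.residues[:mid] + "WHWDEK" + ref.residues[mid:]
        )
        m = _identity_mapping(default_profile, padded)
        assert measure_ris(m, seed_annotation, default_profile, "RIS1") == base + 6

    def test_adjacent_anchors_measure_zero(self, default_profile, seed_annotation):
        # a path emitting consecutive positions at the two anchors
        L = default_profile.n_match
        mapping = QueryMapping(
            query_id="q",
            assignments=tuple(range(1, L + 1)),
            insertions=(),
            n_flank=0,
            c_flank=0,
            score_bits=0.0,
        )
        left = default_profile.anchor_states["ris1_left"]
        right = default_profile.anchor_states["ris1_right"]
        got = measure_ris(mapping, seed_annotation, default_profile, "RIS1")
        assert got == (right - left - 1)  # all-match path: states in between

    def test_undefined_when_flanking_scr_fully_deleted(
        self, default_profile, seed_annotation
    ):
        scr = next(
            s
            for s in seed_annotation.scrs
            if s.end_col == seed_annotation.ris1[0]
        )
        states = default_profile.match_states_in_span(scr.start_col, scr.end_col)
        L = default_profile.n_match
        assignments = []
        pos = 0
        for k in range(L):
            if k in states:
                assignments.append(None)
            else:
                pos += 1
                assignments.append(pos)
        mapping = QueryMapping(
            query_id="q",
            assignments=tuple(assignments),
            insertions=(),
            n_flank=0,
            c_flank=0,
            score_bits=0.0,
        )
        assert measure_ris(mapping, seed_annotation, default_profile, "RIS1") is UNDEFINED


class TestClassifyRedox:
    @pytest.mark.parametrize(
        "ris1,ris2,expected",
        [
            (4, 4, "classI"),
            (21, 14, "classII"),
            (22, 23, "classII_verylongRIS2"),
            (5, 11, "discordant"),
            (12, 9, "ambiguous"),
            (40, 14, "unusual_flagged"),
            (21, 7, "ambiguous"),  # RIS2 of exactly 7 is unassignable
            (21, 18, "classII_verylongRIS2"),  # 18 closes the very-long gap
            (4, 14, "discordant"),
            (None, 4, "discordant"),
            (4, None, "discordant"),
        ],
    )
    def test_printed_and_boundary_examples(self, ris1, ris2, expected):
        assert classify_redox(ris1, ris2) == expected

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            classify_redox(-1, 4)

    def test_partitions_all_length_pairs(self):
        for a in range(100):
            for b in range(100):
                assert classify_redox(a, b) in REDOX_CLASSES

    @given(st.integers(0, 2000), st.integers(0, 2000))
    @settings(deadline=None, max_examples=200)
    def test_total_on_large_lengths(self, a, b):
        assert classify_redox(a, b) in REDOX_CLASSES


class TestApplicabilityGate:
    def test_reference_passes(self, default_profile, seed_alignment):
        ref = seed_alignment.reference.to_sequence()
        ok, bits = applicability_gate(default_profile, ref)
        assert ok and bits > 100

    def test_random_sequences_fail(self, default_profile):
        rng = np.random.default_rng(17)
        from cypmod.seqio import AMINO_ACIDS

        for _ in range(20):
            seq = ProteinSequence(
                id="rand",
                residues="".join(rng.choice(list(AMINO_ACIDS), size=450)),
            )
            ok, bits = applicability_gate(default_profile, seq)
            assert not ok and bits < 100

    def test_cys_mutation_fails_when_required(
        self, default_profile, seed_alignment
    ):
        ref = seed_alignment.reference.to_sequence()
        mapping = align_query(default_profile, ref)
        cpos = mapping.assignments[default_profile.anchor_states["cys"]]
        mutated = ProteinSequence(
            id="mut",
            residues=ref.residues[: cpos - 1] + "A" + ref.residues[cpos:],
        )
        ok, _ = applicability_gate(default_profile, mutated, require_cys=True)
        assert not ok
        ok2, _ = applicability_gate(default_profile, mutated, require_cys=False)
        assert ok2


class TestAnnotateSequence:
    def test_reference_composite(
        self, default_profile, seed_alignment, seed_annotation, seed_truth
    ):
        ref = seed_alignment.reference.to_sequence()
        res = annotate_sequence(default_profile, seed_annotation, ref)
        assert res.gate_pass
        assert all(iv is not ABSENT for iv in res.scr_intervals.values())
        assert len(res.scr_intervals) == 19
        assert res.f87_call == (seed_truth[0].anchor_pos, seed_truth[0].anchor_res)
        assert res.redox_class == seed_truth[0].class_label

    def test_synthetic_classI_query_classified_classI(
        self, default_profile, seed_annotation
    ):
        seqs, truths = generate_queries(
            n=3, class_mix={"classI": 1.0}, rng_seed=4
        )
        for seq in seqs:
            res = annotate_sequence(default_profile, seed_annotation, seq)
            assert res.redox_class == "classI"

    def test_fragment_error_propagates(self, default_profile, seed_annotation):
        with pytest.raises(FragmentError):
            annotate_sequence(
                default_profile,
                seed_annotation,
                ProteinSequence(id="f", residues="MKWLYACDEF" * 3),
            )

    def test_gate_failure_still_reports_structure(
        self, default_profile, seed_alignment, seed_annotation
    ):
        ref = seed_alignment.reference.to_sequence()
        res = annotate_sequence(
            default_profile,
            seed_annotation,
            ref,
            gate_params=GateParams(min_bits=1e9),
        )
        assert not res.gate_pass
        assert res.f87_call is not None
        assert res.ris1_len is not None


class TestThresholdValidation:
    def test_misordered_bands_rejected(self):
        with pytest.raises(ValueError):
            ClassThresholds(ris1_short_max=20, ris1_long_min=16)
        with pytest.raises(ValueError):
            ClassThresholds(ris2_long_hi=20, ris2_verylong_min=18)
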