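"""Core matching engine: scores, motif search, tier criteria, assignment."""

import random
import re

import pytest
from hypothesis import given, settings, strategies as st

from cllsls.catalog import AA_ALPHABET, SubsetDefinition
from cllsls.io import Rearrangement
from cllsls.matching import (
    DEFAULT_SIMILARITY_GROUPS,
    Assignment,
    aa_identity,
    aa_similarity,
    assign_all,
    find_motif,
    match_satellite,
    match_standard,
)

# ---- independent brute-force oracles ---------------------------------------


def oracle_identity(a, b):
    hits = 0
    for i in range(len(a)):
        if a[i] == b[i]:
            hits += 1
    return hits / len(a)


def oracle_similarity(a, b):
    group = {}
    for g in DEFAULT_SIMILARITY_GROUPS:
        for aa in g:
            group[aa] = g
    hits = 0
    for i in range(len(a)):
        if a[i] == b[i] or b[i] in group[a[i]]:
            hits += 1
    return hits / len(a)


def oracle_motif(cdr3, motif):
    pattern = "(?=" + motif.replace("X", ".") + ")"
    return [m.start() for m in re.finditer(pattern, cdr3)]


aa_text = st.text(alphabet=AA_ALPHABET, min_size=1, max_size=25)


class TestScores:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ARDA", "ARDA", 1.0), ("ARDA", "ARDG", 0.75), ("AAAA", "CCCC", 0.0)],
    )
    def test_identity_examples(self, a, b, expected):
        assert aa_identity(a, b) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("KRDA", "RKDA", 1.0),  # K/R conservative swap
            ("ARDA", "ARDG", 1.0),  # A/G conservative swap
            ("ARDA", "ARDW", 0.75),
        ],
    )
    def test_similarity_examples(self, a, b, expected):
        assert aa_similarity(a, b) == pytest.approx(expected)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            aa_identity("AR", "ARD")
        with pytest.raises(ValueError):
            aa_similarity("AR", "ARD")
        with pytest.raises(ValueError):
            aa_identity("", "")

    def test_residue_outside_alphabet_errors(self):
        with pytest.raises(ValueError):
            aa_similarity("AB", "AA")

    @given(st.data())
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_scores_agree_with_oracles(self, data):
        a = data.draw(aa_text)
        b = data.draw(st.text(alphabet=AA_ALPHABET, min_size=len(a), max_size=len(a)))
        assert aa_identity(a, b) == pytest.approx(oracle_identity(a, b))
        assert aa_similarity(a, b) == pytest.approx(oracle_similarity(a, b))

    @given(st.data())
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_identity_never_exceeds_similarity(self, data):
        a = data.draw(aa_text)
        b = data.draw(st.text(alphabet=AA_ALPHABET, min_size=len(a), max_size=len(a)))
        assert aa_identity(a, b) <= aa_similarity(a, b) + 1e-12


class TestFindMotif:
    @pytest.mark.parametrize(
        "cdr3,motif,expected",
        [
            ("ARGGYYGMDV", "GYY", [3]),
            ("GYYGYY", "GYY", [0, 3]),
            ("GYGYGY", "GYG", [0, 2]),  # overlapping occurrences
            ("ARGAYYGMDV", "GXY", [2]),  # wildcard: G-any-Y
            ("ARDA", "ARDAX", []),  # motif longer than CDR3
            ("AAAA", "C", []),
        ],
    )
    def test_examples(self, cdr3, motif, expected):
        assert find_motif(cdr3, motif) == expected

    def test_empty_motif_errors(self):
        with pytest.raises(ValueError):
            find_motif("ARDA", "")

    @given(aa_text, st.text(alphabet=AA_ALPHABET + "X", min_size=1, max_size=6))
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_agrees_with_regex_oracle(self, cdr3, motif):
        assert find_motif(cdr3, motif) == oracle_motif(cdr3, motif)


def _heavy(cdr3, v_call="IGHV1-69*01", j_call="IGHJ4*01", sid="q", v_identity=None):
    return Rearrangement(sid, v_call, j_call, f"C{cdr3}W", v_identity=v_identity)


class TestMatchStandard:
    def test_self_match(self, toy_by_id):
        s = toy_by_id["T1"]
        a = match_standard(_heavy(s.consensus_cdr3), s)
        assert a is not None and a.match_type == "standard"
        assert a.identity == 1.0 and a.similarity == 1.0
        assert a.length_delta == 0 and a.offset_delta == 0

    def test_shorter_cdr3_rejected(self, toy_by_id):
        s = toy_by_id["T1"]
        assert match_standard(_heavy(s.consensus_cdr3[:-1]), s) is None

    def test_shifted_motif_rejected(self, toy_by_id):
        """The motif present only at offset+1 violates the identical-offset criterion."""
        s = toy_by_id["T1"]  # ARDKGYYSYGMDV, motif GYYS at 4
        shifted = "ARDKAGYYSGMDV"  # GYYS now at offset 5
        assert find_motif(shifted, s.motif) == [5]
        assert match_standard(_heavy(shifted), s) is None

    def test_wrong_clan_rejected(self, toy_by_id):
        s = toy_by_id["T1"]  # clan I
        assert match_standard(_heavy(s.consensus_cdr3, v_call="IGHV3-23*01"), s) is None

    def test_low_identity_rejected(self, toy_by_id):
        """Keep the motif but replace everything else with dissimilar residues."""
        s = toy_by_id["T1"]
        chars = list("PPPP" + s.motif + "PPPPP")
        assert len(chars) == s.cdr3_length
        assert match_standard(_heavy("".join(chars)), s) is None

    def test_light_chain_input_rejected(self, toy_by_id):
        r = Rearrangement("q", "IGKV2-30*01", "IGKJ1*01", "CMQGTHWPYTF")
        with pytest.raises(ValueError):
            match_standard(r, toy_by_id["T1"])


class TestMatchSatellite:
    def test_two_longer_with_shifted_motif(self, toy_by_id):
        """Length +2 and offset +2 sit exactly on the satellite bounds."""
        s = toy_by_id["T1"]
        cdr3 = "AR" + s.consensus_cdr3  # motif shifts from 4 to 6, length 15
        a = match_satellite(_heavy(cdr3), s)
        assert a is not None and a.match_type == "satellite"
        assert a.length_delta == 2 and a.offset_delta == 2

    def test_three_longer_rejected(self, toy_by_id):
        s = toy_by_id["T1"]
        assert match_satellite(_heavy("ARG" + s.consensus_cdr3), s) is None

    def test_offset_past_bound_rejected(self, toy_by_id):
        s = toy_by_id["T2"]  # ARDANGMDV, ANG at 3
        cdr3 = "ARDAAADANG"  # ANG at offset 7, |delta| = 4 > 2, length delta +1
        assert find_motif(cdr3, s.motif) == [7]
        assert match_satellite(_heavy(cdr3, v_call="IGHV3-21*01"), s) is None

    def test_minimal_offset_ties_break_negative(self):
        s = SubsetDefinition(
            subset_id="S",
            ighv_genes=frozenset({"IGHV1-69"}),
            cdr3_length=9,
            consensus_cdr3="AAAGYGYAA",
            motif="GY",
            motif_offset=3,
            mutation_class="U",
        )
        # motif occurs at 2 and 4: |delta| ties at 1, the more negative wins
        a = match_satellite(_heavy("AAGYGYAAA"), s)
        assert a is not None and a.offset_delta == -1

    def test_standard_implies_satellite(self, toy_catalog):
        rng = random.Random(7)
        checked = 0
        for s in toy_catalog:
            free = [i for i in range(s.cdr3_length)
                    if not s.motif_offset <= i < s.motif_offset + len(s.motif)]
            for _ in range(400):
                chars = list(s.consensus_cdr3)
                for i in rng.sample(free, k=rng.randint(0, len(free))):
                    chars[i] = rng.choice(AA_ALPHABET)
                r = _heavy("".join(chars), v_call=sorted(s.ighv_genes)[0])
                if match_standard(r, s) is not None:
                    assert match_satellite(r, s) is not None
                    checked += 1
        assert checked > 100


class TestAssignAll:
    def test_planted_consensus_recovered_per_subset(self, toy_catalog):
        rs = [
            _heavy(s.consensus_cdr3, v_call=sorted(s.ighv_genes)[0] + "*01", sid=s.subset_id)
            for s in toy_catalog
        ]
        result = {a.subset_id: a.match_type for a in assign_all(rs, toy_catalog)}
        assert result == {s.subset_id: "standard" for s in toy_catalog}

    def test_standard_takes_precedence_over_satellite(self):
        a_def = SubsetDefinition(
            subset_id="A",
            ighv_genes=frozenset({"IGHV1-69"}),
            cdr3_length=13,
            consensus_cdr3="ARDKGYYSYGMDV",
            motif="GYYS",
            motif_offset=4,
            mutation_class="U",
        )
        b_def = SubsetDefinition(
            subset_id="B",
            ighv_genes=frozenset({"IGHV1-2"}),
            cdr3_length=12,
            consensus_cdr3="ARKGYYSYGMDV",
            motif="GYYS",
            motif_offset=3,
            mutation_class="U",
        )
        r = _heavy(a_def.consensus_cdr3)
        assert match_standard(r, a_def) is not None
        assert match_satellite(r, b_def) is not None
        (res,) = assign_all([r], [a_def, b_def])
        assert (res.subset_id, res.match_type) == ("A", "standard")

    def test_empty_repertoire(self, toy_catalog):
        assert assign_all([], toy_catalog) == []

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            assign_all([], [])

    def test_output_independent_of_input_order(self, toy_catalog):
        rng = random.Random(3)
        rs = []
        for s in toy_catalog:
            for k in range(5):
                chars = list(s.consensus_cdr3)
                i = rng.randrange(s.cdr3_length)
                if not s.motif_offset <= i < s.motif_offset + len(s.motif):
                    chars[i] = rng.choice(AA_ALPHABET)
                rs.append(_heavy("".join(chars), v_call=sorted(s.ighv_genes)[0], sid=f"{s.subset_id}.{k}"))
        forward = assign_all(rs, toy_catalog)
        shuffled = rs[:]
        rng.shuffle(shuffled)
        assert assign_all(shuffled, toy_catalog) == forward

    def test_raising_similarity_threshold_never_adds_matches(self, toy_catalog):
        rng = random.Random(11)
        rs = []
        for s in toy_catalog:
            for k in range(50):
                chars = list(s.consensus_cdr3)
                for i in rng.sample(range(s.cdr3_length), k=rng.randint(0, 6)):
                    if not s.motif_offset <= i < s.motif_offset + len(s.motif):
                        chars[i] = rng.choice(AA_ALPHABET)
                rs.append(_heavy("".join(chars), v_call=sorted(s.ighv_genes)[0], sid=f"{s.subset_id}.{k}"))
        keys_at = {}
        for thr in (0.7, 0.8, 0.9, 1.0):
            asg = assign_all(rs, toy_catalog, min_similarity=thr)
            keys_at[thr] = {a.sequence_key for a in asg if a.match_type == "standard"}
        assert keys_at[1.0] <= keys_at[0.9] <= keys_at[0.8] <= keys_at[0.7]

    def test_shm_class_attached(self, toy_by_id):
        s = toy_by_id["T1"]  # canonical class U
        r_u = _heavy(s.consensus_cdr3, sid="u", v_identity=1.0)
        r_m = _heavy(s.consensus_cdr3[:-1] + "A", sid="m", v_identity=0.90)
        asg = {a.sequence_key: a for a in assign_all([r_u, r_m], [s])}
        by_class = {a.shm_class: a for a in asg.values()}
        assert by_class["U"].concordant_shm is True
        assert by_class["M"].concordant_shm is False
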