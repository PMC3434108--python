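import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from triadcore import (
    column_conservation,
    composition_profile,
    flag_composition_outliers,
    global_align,
    map_reference_numbering,
)
from triadcore.sequence_analysis import CompositionProfile
from triadcore.structure_io import Alignment, SequenceRecord


def enumerate_global_alignments(a, b, match, mismatch, gap):
    """Independent oracle: maximum score over every global alignment,
    by exhaustive recursion (feasible for short sequences)."""
    def best(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + best(i + 1, j + 1))
        if i < len(a):
            options.append(gap + best(i + 1, j))
        if j < len(b):
            options.append(gap + best(i, j + 1))
        return max(options)

    return best(0, 0)


def _rec(seq, name="s"):
    return SequenceRecord(name, seq)


def test_identical_sequences():
    out = global_align(_rec("ACDE"), _rec("ACDE"), match=1, mismatch=-1, gap=-1)
    assert out.score == 4.0
    assert out.aligned_a == out.aligned_b == "ACDE"
    assert out.identity_pct == 100.0


def test_single_mismatch_column():
    out = global_align(_rec("A"), _rec("G"), match=1, mismatch=-1, gap=-2)
    assert out.score == -1.0
    assert (out.aligned_a, out.aligned_b) == ("A", "G")


def test_matches_exhaustive_enumeration_small_case():
    out = global_align(_rec("ACD"), _rec("AD"), match=1, mismatch=-1, gap=-1)
    assert out.score == enumerate_global_alignments("ACD", "AD", 1, -1, -1)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    a=st.text(alphabet="ACDG", min_size=1, max_size=6),
    b=st.text(alphabet="ACDG", min_size=1, max_size=6),
)
def test_optimality_property_vs_enumeration(a, b):
    out = global_align(_rec(a), _rec(b), match=2, mismatch=-1, gap=-2)
    assert out.score == enumerate_global_alignments(a, b, 2, -1, -2)
    # structural invariants
    assert out.aligned_a.replace("-", "") == a
    assert out.aligned_b.replace("-", "") == b


def test_score_matches_biopython_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score, aligner.mismatch_score = 1, -1
    aligner.open_gap_score = aligner.extend_gap_score = -2
    rng = np.random.default_rng(4)
    for _ in range(20):
        a = "".join(rng.choice(list("ACDEFGHIKL"), size=rng.integers(3, 12)))
        b = "".join(rng.choice(list("ACDEFGHIKL"), size=rng.integers(3, 12)))
        out = global_align(_rec(a), _rec(b), match=1, mismatch=-1, gap=-2)
        assert out.score == aligner.score(a, b)


def _column_alignment(columns):
    """Build an Alignment whose rows spell the given columns."""
    n_rows = len(columns[0])
    rows = [
        SequenceRecord(f"r{i}", "".join(col[i] for col in columns))
        for i in range(n_rows)
    ]
    return Alignment(rows)


def test_occupancy_16_of_21():
    col = "T" * 16 + "AGHVW"
    aln = _column_alignment([col, "A" * 21])
    stats = column_conservation(aln)[0]
    assert stats.occupancy_pct == pytest.approx(100 * 16 / 21)
    assert f"{stats.occupancy_pct:.0f}" == "76"


def test_fully_conserved_column_star():
    aln = _column_alignment(["G" * 21, "A" * 20 + "C"])
    stats = column_conservation(aln)
    assert stats[0].occupancy_pct == 100.0 and stats[0].symbol == "*"
    assert stats[1].symbol == "."  # {A,C} falls inside the weak group CSA


def test_strong_group_colon():
    aln = _column_alignment(["ILVILV", "AAAAAA"])
    assert column_conservation(aln)[0].symbol == ":"


def test_weak_group_dot():
    aln = _column_alignment(["CSACSA", "AAAAAA"])
    assert column_conservation(aln)[0].symbol == "."


def test_gap_disqualifies_star_but_not_group_symbols():
    aln = _column_alignment(["GG-G", "SS-S", "II-I", "AAAA"])
    stats = column_conservation(aln)
    assert stats[0].symbol == "."       # {G} ⊆ SAG (weak), gap blocks "*"
    assert stats[1].symbol == ":"       # {S} ⊆ STA (strong)
    assert stats[2].symbol == ":"       # {I} ⊆ MILV
    assert stats[0].occupancy_pct == pytest.approx(75.0)


def test_all_gap_column_blank():
    aln = _column_alignment(["----", "AAAA"])
    stats = column_conservation(aln)[0]
    assert stats.occupancy_pct == 0.0 and stats.symbol == " "


def test_removing_rows_never_demotes_star_columns():
    aln = _column_alignment(["GGGG", "ACAC", "TTTT"])
    full = column_conservation(aln)
    reduced = column_conservation(Alignment(aln.rows[:2]))
    for f, r in zip(full, reduced):
        if f.symbol == "*":
            assert r.symbol == "*"


def test_reference_numbering_identity():
    aln = Alignment([SequenceRecord("ref", "ACDEF"), SequenceRecord("t", "ACDEF")])
    mapping = map_reference_numbering(aln, "ref")
    assert [mapping[("t", i)] for i in range(1, 6)] == [1, 2, 3, 4, 5]
    assert [mapping[("ref", i)] for i in range(1, 6)] == [1, 2, 3, 4, 5]


def test_reference_numbering_insertion_and_resume():
    aln = Alignment([SequenceRecord("ref", "AC---D"), SequenceRecord("t", "ACXYZD")])
    mapping = map_reference_numbering(aln, "ref")
    assert mapping[("t", 1)] == 1 and mapping[("t", 2)] == 2
    assert all(mapping[("t", i)] == "insertion" for i in (3, 4, 5))
    assert mapping[("t", 6)] == 3


def test_reference_numbering_with_offset_places_catalytic_his():
    # a target His aligned to the reference's position 57 maps to 57
    ref = "A" * 56 + "H" + "A" * 3
    tgt = "G" * 56 + "H" + "G" * 3
    aln = Alignment([SequenceRecord("ref", ref), SequenceRecord("t", tgt)])
    mapping = map_reference_numbering(aln, "ref")
    assert mapping[("t", 57)] == 57


def test_reference_absent_fails():
    aln = Alignment([SequenceRecord("a", "AC"), SequenceRecord("b", "AC")])
    with pytest.raises(KeyError):
        map_reference_numbering(aln, "missing")


def test_composition_all_glycine():
    p = composition_profile(_rec("GGGG"))
    assert p["tiny"] == 100.0 and p["nonpolar"] == 100.0
    assert p["aromatic"] == 0.0 and p["polar"] == 0.0


def test_composition_aromatic_set():
    assert composition_profile(_rec("FHWY"))["aromatic"] == 100.0


def test_composition_uniform_twenty():
    p = composition_profile(_rec("ACDEFGHIKLMNPQRSTVWY"))
    assert p["aromatic"] == pytest.approx(20.0)
    assert p["acidic"] == pytest.approx(10.0)
    assert p["basic"] == pytest.approx(15.0)


def test_composition_nonpolar_polar_partition_and_permutation():
    rng = np.random.default_rng(8)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
    p = composition_profile(_rec(seq))
    assert p["nonpolar"] + p["polar"] == pytest.approx(100.0)
    shuffled = "".join(rng.permutation(list(seq)))
    assert composition_profile(_rec(shuffled)).molar_pct == p.molar_pct


def test_composition_x_excluded_from_denominator():
    assert composition_profile(_rec("GXGX"))["tiny"] == 100.0
    with pytest.raises(ValueError):
        composition_profile(_rec("XXX"))


def _profiles(values, cls="aromatic"):
    out = []
    for i, v in enumerate(values):
        pct = {k: 0.0 for k in
               ("tiny", "small", "aliphatic", "aromatic", "nonpolar",
                "polar", "charged", "basic", "acidic")}
        pct[cls] = float(v)
        out.append((f"p{i}", CompositionProfile(pct)))
    return out


def test_outlier_hand_computed_case():
    # values {10, 10, 10, 16}: mean 11.5, sample SD 3 -> only 16 > 14.5 flagged
    flags = flag_composition_outliers(_profiles([10, 10, 10, 16]))
    assert ("p3", "aromatic", "high") in flags
    assert all(label == "p3" for label, cls, _ in flags if cls == "aromatic")


def test_outlier_constructed_high_value_flagged():
    flags = flag_composition_outliers(_profiles([12, 13, 11, 12, 30]))
    assert ("p4", "aromatic", "high") in flags


def test_identical_profiles_no_flags():
    assert flag_composition_outliers(_profiles([10, 10, 10])) == []


def test_outliers_require_three_profiles():
    with pytest.raises(ValueError):
        flag_composition_outliers(_profiles([10, 12]))
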