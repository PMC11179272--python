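import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathminer.enzyme_screen import (
    KYTE_DOOLITTLE,
    DistanceMatrix,
    detect_nterm_anchor,
    filter_orthologs,
    hydropathy_profile,
    nj_tree,
    p_distance,
    truncate_nterm,
)

from conftest import random_additive_matrix


# ---------------------------------------------------------------------------
# ortholog filtering
# ---------------------------------------------------------------------------


def _row(score, similarity):
    return {"query": "q", "subject": "s", "score": score, "similarity": similarity}


@pytest.mark.parametrize(
    "score,similarity,kept",
    [
        (1031, 40, True),
        (1030, 50, False),  # strict: "over 1030"
        (2000, 39, False),  # strict: "over 39%"
        (1030.5, 39.5, True),
        (0, 0, False),
    ],
)
def test_filter_orthologs_strict_thresholds(score, similarity, kept):
    out = filter_orthologs([_row(score, similarity)])
    assert bool(out) == kept


def test_filter_orthologs_empty_and_file(tmp_path):
    assert filter_orthologs([]) == []
    path = tmp_path / "hits.tsv"
    path.write_text(
        "query\tsubject\tscore\tsimilarity\nq1\ts1\t1500\t45\nq1\ts2\t900\t70\n"
    )
    out = filter_orthologs(path)
    assert [r["subject"] for r in out] == ["s1"]


def test_filter_orthologs_malformed_row(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text("query\tsubject\tscore\tsimilarity\nq1\ts1\tnotanumber\t45\n")
    with pytest.raises(ValueError, match="line 2"):
        filter_orthologs(path)


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------


class _Rec:
    def __init__(self, id, seq):
        self.id, self.seq = id, seq


def test_p_distance_basic():
    dm = p_distance([_Rec("a", "ACDE"), _Rec("b", "ACDF"), _Rec("c", "ACDE")])
    i, j = dm.labels.index("a"), dm.labels.index("b")
    assert dm.matrix[i, j] == pytest.approx(0.25)
    assert dm.matrix[i, dm.labels.index("c")] == 0.0


def test_p_distance_gap_exclusion():
    # a vs b: column 3 has a gap in a -> compared over 3 columns, 0 mismatches
    dm = p_distance([_Rec("a", "AC-E"), _Rec("b", "ACDE"), _Rec("c", "GGDE")])
    assert dm.matrix[0, 1] == pytest.approx(0.0)
    # a vs c over 3 columns with 2 mismatches
    assert dm.matrix[0, 2] == pytest.approx(2 / 3)


def test_p_distance_length_mismatch():
    with pytest.raises(ValueError, match="length"):
        p_distance([_Rec("a", "ACDE"), _Rec("b", "ACD"), _Rec("c", "ACDE")])


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def test_nj_four_taxon_known_topology():
    """Additive matrix from ((A:2,B:3):1,(C:4,D:5)): NJ must recover the
    topology and the exact branch lengths."""
    labels = ("A", "B", "C", "D")
    M = np.array(
        [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], dtype=float
    )
    tree = nj_tree(DistanceMatrix(labels, M))
    nwk = tree.newick()
    assert "(A:2,B:3):1" in nwk
    ld = tree.leaf_distances()
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            assert ld[(a, b)] == pytest.approx(M[labels.index(a), labels.index(b)], abs=1e-9)
    assert tree.clamped_negative_branches == 0


def test_nj_three_taxa_closed_form():
    labels = ("A", "B", "C")
    M = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    tree = nj_tree(DistanceMatrix(labels, M))
    ld = tree.leaf_distances()
    assert ld[("A", "B")] == pytest.approx(3)
    assert ld[("A", "C")] == pytest.approx(4)
    assert ld[("B", "C")] == pytest.approx(5)


@pytest.mark.parametrize("n", range(4, 9))
def test_nj_exact_on_random_additive_matrices(n):
    """On additive matrices NJ reconstructs the generating tree exactly: all
    leaf-to-leaf tree distances equal the input distances to 1e-9."""
    rng = np.random.default_rng(500 + n)
    for _ in range(5):
        dm = random_additive_matrix(n, rng)
        tree = nj_tree(dm)
        assert tree.clamped_negative_branches == 0
        ld = tree.leaf_distances()
        for i, a in enumerate(dm.labels):
            for b in dm.labels[i + 1 :]:
                expected = dm.matrix[dm.labels.index(a), dm.labels.index(b)]
                assert abs(ld[(a, b)] - expected) < 1e-9


def test_nj_agrees_with_independent_implementation():
    """Tip-to-tip distances of our NJ tree match scikit-bio's NJ on the same
    additive matrix (both must reproduce the input exactly)."""
    import skbio

    rng = np.random.default_rng(77)
    dm = random_additive_matrix(6, rng)
    ours = nj_tree(dm).leaf_distances()
    sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm.matrix, ids=dm.labels))
    for i, a in enumerate(dm.labels):
        for b in dm.labels[i + 1 :]:
            sk_d = sk_tree.find(a).distance(sk_tree.find(b))
            assert ours[(a, b)] == pytest.approx(sk_d, abs=1e-9)


def test_nj_deterministic_under_ties():
    labels = ("A", "B", "C", "D")
    M = np.ones((4, 4)) - np.eye(4)  # fully tied
    t1 = nj_tree(DistanceMatrix(labels, M)).newick()
    t2 = nj_tree(DistanceMatrix(labels, M)).newick()
    assert t1 == t2


def test_nj_rejects_asymmetry():
    M = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(("A", "B", "C"), M)


def test_distance_matrix_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(3)
    dm = random_additive_matrix(5, rng)
    path = tmp_path / "d.tsv"
    dm.to_tsv(path)
    loaded = DistanceMatrix.from_tsv(path)
    assert loaded.labels == dm.labels
    assert np.allclose(loaded.matrix, dm.matrix)


# ---------------------------------------------------------------------------
# hydropathy and truncation
# ---------------------------------------------------------------------------


def test_anchor_polyisoleucine_head():
    seq = "I" * 30 + "D" * 30
    seg = detect_nterm_anchor(seq)
    assert seg is not None and seg[0] == 1


def test_anchor_absent_in_polyaspartate():
    assert detect_nterm_anchor("D" * 60) is None


def test_anchor_designed_single_stretch():
    """Mildly hydrophobic 19-mer (alanine, KD 1.8) flanked by arginine: only
    the window exactly covering residues 5..23 clears the 1.6 threshold."""
    seq = "RRRR" + "A" * 19 + "R" * 37
    prof = hydropathy_profile(seq)
    above = [i for i, v in enumerate(prof.values) if v >= 1.6]
    assert above == [4]
    assert detect_nterm_anchor(seq) == (5, 23)


def test_anchor_beyond_search_limit_ignored():
    seq = "D" * 70 + "I" * 25 + "D" * 20
    assert detect_nterm_anchor(seq) is None


def test_anchor_rejects_nonstandard_residue():
    with pytest.raises(ValueError, match="non-standard"):
        detect_nterm_anchor("ACDX" + "I" * 20)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    seq=st.text(alphabet=sorted(KYTE_DOOLITTLE), min_size=19, max_size=120),
    window=st.sampled_from([7, 11, 19]),
)
def test_hydropathy_profile_matches_naive_oracle(seq, window):
    if len(seq) < window:
        return
    prof = hydropathy_profile(seq, window=window)
    assert len(prof.values) == len(seq) - window + 1
    for i in range(len(prof.values)):
        naive = sum(KYTE_DOOLITTLE[aa] for aa in seq[i : i + window]) / window
        assert prof.values[i] == pytest.approx(naive, abs=1e-12)


def test_truncate_arithmetic():
    seq = "A" * 100
    out = truncate_nterm(seq, (1, 19))
    assert len(out) == 82 and out[0] == "M"
    assert truncate_nterm(seq, None) == seq
    with pytest.raises(ValueError, match="out of bounds"):
        truncate_nterm("ACDE", (1, 10))


def test_truncation_removes_anchor():
    seq = "RRRR" + "A" * 19 + "R" * 60
    seg = detect_nterm_anchor(seq)
    truncated = truncate_nterm(seq, seg)
    assert detect_nterm_anchor(truncated) is None
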