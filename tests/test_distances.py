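import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodelib.distances import (
    AlignmentScoring,
    DEFAULT_SCORING,
    DistanceMatrix,
    distance_matrix,
    length_summary,
    orient_sequence,
    p_distance,
    pairwise_align,
    reverse_complement,
)
from barcodelib.library_model import Library
from conftest import rec

# --- independent brute-force alignment oracle ------------------------------


def _score_alignment(a: str, b: str, sc: AlignmentScoring) -> float:
    """Score a pair of aligned strings: affine gap runs cost open + k*extend,
    runs touching either end are free when free_end_gaps is set."""
    assert len(a) == len(b)
    score = 0.0
    for seq, other in ((a, b), (b, a)):
        i = 0
        while i < len(seq):
            if seq[i] != "-":
                i += 1
                continue
            j = i
            while j < len(seq) and seq[j] == "-":
                j += 1
            is_end_run = i == 0 or j == len(seq)
            if not (sc.free_end_gaps and is_end_run):
                score += sc.gap_open + (j - i) * sc.gap_extend
            i = j
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            score += sc.match if x == y else sc.mismatch
    return score


def _enumerate_alignments(a: str, b: str):
    """All global alignments as (aligned_a, aligned_b) pairs."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in _enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in _enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in _enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def brute_force_optimum(a: str, b: str, sc: AlignmentScoring = DEFAULT_SCORING) -> float:
    return max(_score_alignment(x, y, sc) for x, y in _enumerate_alignments(a, b))


# --- pairwise_align ---------------------------------------------------------


class TestPairwiseAlign:
    def test_identity(self):
        assert pairwise_align("ACGT", "ACGT")[:2] == ("ACGT", "ACGT")

    def test_deletion_matches_brute_force(self):
        _, _, score = pairwise_align("ACGT", "AGT")
        assert score == brute_force_optimum("ACGT", "AGT")

    def test_all_mismatch_matches_brute_force(self):
        # With free end gaps the optimum staggers the sequences (score 0)
        # rather than stacking four mismatches (score -4).
        a, b, score = pairwise_align("AAAA", "TTTT")
        assert score == brute_force_optimum("AAAA", "TTTT") == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pairwise_align("", "ACGT")

    def test_gapped_input_rejected(self):
        with pytest.raises(ValueError):
            pairwise_align("AC-GT", "ACGT")

    @settings(max_examples=60, deadline=None)
    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=6),
        st.text(alphabet="ACGT", min_size=1, max_size=6),
    )
    def test_optimality_vs_brute_force(self, a, b):
        _, _, score = pairwise_align(a, b)
        assert score == pytest.approx(brute_force_optimum(a, b))

    @settings(max_examples=25, deadline=None)
    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=5),
        st.text(alphabet="ACGT", min_size=1, max_size=5),
    )
    def test_returned_alignment_scores_its_own_score(self, a, b):
        aligned_a, aligned_b, score = pairwise_align(a, b)
        assert _score_alignment(aligned_a, aligned_b, DEFAULT_SCORING) == pytest.approx(score)


# --- p_distance -------------------------------------------------------------


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected,sites",
        [
            ("ACGT", "ACGT", 0.0, 4),
            ("ACGT", "ACGA", 0.25, 4),
            ("AC-GTN", "ACCGAA", 0.25, 4),  # gap and N columns excluded
        ],
    )
    def test_examples(self, a, b, expected, sites):
        assert p_distance(a, b) == (expected, sites)

    def test_zero_comparable_sites_masked(self):
        dist, sites = p_distance("NNNN", "ACGT")
        assert dist is None and sites == 0

    def test_unequal_length_fatal(self):
        with pytest.raises(ValueError):
            p_distance("ACGT", "ACG")

    def test_oracle_equivalence_exhaustive_small(self):
        # independent oracle over every aligned pair of length 2
        alphabet = "ACGT-N"
        for a in itertools.product(alphabet, repeat=2):
            for b in itertools.product(alphabet, repeat=2):
                sa, sb = "".join(a), "".join(b)
                cols = [
                    (x, y)
                    for x, y in zip(sa, sb)
                    if x in "ACGT" and y in "ACGT"
                ]
                expected = (
                    (None, 0)
                    if not cols
                    else (sum(x != y for x, y in cols) / len(cols), len(cols))
                )
                assert p_distance(sa, sb) == expected

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGTRYN-", min_size=1, max_size=40))
    def test_self_distance_zero_over_unambiguous_sites(self, seq):
        unambiguous = sum(1 for c in seq if c in "ACGT")
        dist, sites = p_distance(seq, seq)
        assert sites == unambiguous
        assert dist == (0.0 if unambiguous else None)


# --- distance_matrix --------------------------------------------------------


class TestDistanceMatrix:
    def test_identical_sequences_all_zero(self):
        lib = Library([rec(f"S{i}", "Ptychochromis oligacanthus", seq="ACGT" * 50) for i in range(5)])
        m = distance_matrix(lib, "COI")
        off_diag = m.d[~np.eye(5, dtype=bool)]
        assert (off_diag == 0.0).all()

    def test_three_toy_consistency_with_p_distance(self):
        seqs = ["ACGTACGTAAAA", "ACGTACGTAAAT", "ACGAACGTAATT"]
        lib = Library([rec(f"S{i}", "A b", seq=s) for i, s in enumerate(seqs)])
        m = distance_matrix(lib, "COI", normalize_strand=False)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                a, b, _ = pairwise_align(seqs[i], seqs[j])
                assert m.d[i, j] == pytest.approx(p_distance(a, b)[0])

    def test_msa_mode_matches_pure_python_oracle(self, clean_sim):
        _, library, _, _ = clean_sim
        records = library.by_marker("COI")[:20]
        lib = Library(records)
        m = distance_matrix(lib, "COI", mode="msa")
        for i in range(10):  # spot-check upper triangle rows
            for j in range(i + 1, 20):
                cols = [
                    (x, y)
                    for x, y in zip(records[i].sequence, records[j].sequence)
                    if x in "ACGT" and y in "ACGT"
                ]
                expected = sum(x != y for x, y in cols) / len(cols)
                assert m.d[i, j] == pytest.approx(expected)
                assert m.sites[i, j] == len(cols)

    def test_symmetry_and_zero_diagonal(self, clean_sim):
        _, library, _, _ = clean_sim
        m = distance_matrix(library, "COI", mode="msa")
        assert np.allclose(m.d, m.d.T, equal_nan=True)
        assert (np.diag(m.d) == 0).all()

    def test_reverse_complement_invariance(self, clean_sim):
        _, library, _, _ = clean_sim
        records = library.by_marker("COI")[:8]
        lib_fwd = Library(records)
        flipped = [
            rec(r.sample_id, r.species_name, seq=reverse_complement(r.sequence))
            if i % 2
            else r
            for i, r in enumerate(records)
        ]
        lib_flip = Library(flipped)
        m1 = distance_matrix(lib_fwd, "COI", mode="pairwise_align")
        m2 = distance_matrix(lib_flip, "COI", mode="pairwise_align")
        assert np.allclose(m1.d, m2.d)

    def test_msa_unequal_lengths_fatal(self):
        lib = Library([rec("S1", "A b", seq="ACGT"), rec("S2", "A b", seq="ACGTA")])
        with pytest.raises(ValueError, match="equal-length"):
            distance_matrix(lib, "COI", mode="msa")

    def test_single_record_fatal(self):
        lib = Library([rec("S1", "A b")])
        with pytest.raises(ValueError, match=">=2"):
            distance_matrix(lib, "COI")

    def test_tsv_roundtrip_with_masked_cells(self, tmp_path):
        d = np.array([[0.0, 0.5, np.nan], [0.5, 0.0, 0.1], [np.nan, 0.1, 0.0]])
        sites = np.array([[0, 4, 0], [4, 0, 4], [0, 4, 0]])
        m = DistanceMatrix(ids=["a", "b", "c"], d=d, sites=sites, marker="COI")
        p = tmp_path / "m.tsv"
        m.write_tsv(p)
        m2 = DistanceMatrix.read_tsv(p, marker="COI")
        assert m2.ids == m.ids
        assert np.allclose(m.d, m2.d, equal_nan=True)
        assert "NA" in p.read_text()


class TestStrandNormalization:
    def test_orient_flips_reverse_complement(self, random_seq):
        seq = random_seq(200, seed=3)
        assert orient_sequence(reverse_complement(seq), seq) == seq

    def test_orient_keeps_forward(self, random_seq):
        seq = random_seq(200, seed=4)
        assert orient_sequence(seq, seq) == seq


class TestLengthSummary:
    def test_two_records(self):
        lib = Library(
            [rec("S1", "A b", seq="A" * 600), rec("S2", "A b", seq="C" * 594)]
        )
        assert length_summary(lib, "COI") == (597, 594, 600)

    def test_single_record(self):
        lib = Library([rec("S1", "A b", seq="A" * 300)])
        assert length_summary(lib, "COI") == (300, 300, 300)

    def test_gaps_excluded_from_length(self):
        lib = Library([rec("S1", "A b", seq="AAA---AAA")])
        assert length_summary(lib, "COI") == (6, 6, 6)

    def test_empty_marker_fatal(self, toy_library):
        with pytest.raises(ValueError):
            length_summary(toy_library, "ND2")


class TestStarAlignment:
    def test_equal_length_library_matches_msa_mode(self, clean_sim):
        from barcodelib.distances import star_distance_matrix

        _, library, _, _ = clean_sim
        m_star = star_distance_matrix(library, "COI")
        m_msa = distance_matrix(library, "COI", mode="msa")
        order = [m_star.ids.index(i) for i in m_msa.ids]
        assert np.allclose(m_star.d[np.ix_(order, order)], m_msa.d)

    def test_fragment_library_close_to_pairwise_mode(self):
        from barcodelib.distances import star_distance_matrix
        from barcodelib.synthetic_data import SimulationConfig, simulate_library

        config = SimulationConfig(seed=5, n_families=1, n_genera_per_family=2,
                                  n_species_per_genus=2, n_samples_per_species=3,
                                  truncate_range=(300, 600))
        library, _, _ = simulate_library(config)
        m_star = star_distance_matrix(library, "COI")
        m_pair = distance_matrix(library, "COI", mode="pairwise_align")
        order = [m_star.ids.index(i) for i in m_pair.ids]
        diff = np.abs(m_star.d[np.ix_(order, order)] - m_pair.d)
        assert np.nanmax(diff) < 0.005
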