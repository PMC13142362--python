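"""Affine-gap global alignment, shared grids and SDP identification."""

import random

import pytest
from Bio import Align

from faakit.profiling import column_profiles, extract_consensus, trim_columns
from faakit.sdp_grid import (
    build_shared_grid,
    classify_pair,
    global_align,
    identify_sdps,
    load_matrix,
    same_chemical_class,
)
from faakit.synthetic_data import FamilySpec, simulate_subtype_pair
from conftest import AA, make_alignment

MATRIX = load_matrix()
GAP_OPEN, GAP_EXTEND = 10.0, 1.0


def affine_score(cols_a, cols_b):
    """Standalone affine scorer for complete alignments (oracle component)."""
    score = 0.0
    in_a = in_b = False
    for x, y in zip(cols_a, cols_b):
        if x == "-":
            score -= GAP_EXTEND if in_a else GAP_OPEN + GAP_EXTEND
            in_a, in_b = True, False
        elif y == "-":
            score -= GAP_EXTEND if in_b else GAP_OPEN + GAP_EXTEND
            in_b, in_a = True, False
        else:
            score += MATRIX[x, y]
            in_a = in_b = False
    return score


def enumerate_alignments(a, b):
    """Every monotone global alignment of a and b (exhaustive oracle)."""
    if not a and not b:
        yield ("", "")
        return
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield (a[0] + ra, b[0] + rb)
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield (a[0] + ra, "-" + rb)
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield ("-" + ra, b[0] + rb)


class TestGlobalAlign:
    def test_identical_sequences_align_gapless(self):
        seq = "MKTAYIAKQR"
        aln = global_align(seq, seq)
        assert aln.aligned_a == aln.aligned_b == seq
        assert aln.score == sum(MATRIX[c, c] for c in seq)

    def test_single_residue_blosum_entry(self):
        assert global_align("A", "A").score == 4.0

    def test_non_canonical_rejected(self):
        with pytest.raises(ValueError, match="non-canonical"):
            global_align("AXA", "AAA")
        with pytest.raises(ValueError):
            global_align("", "A")

    def test_round_trip_degap(self, rng):
        for _ in range(50):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(1, 40)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(1, 40)))
            aln = global_align(a, b)
            assert aln.aligned_a.replace("-", "") == a
            assert aln.aligned_b.replace("-", "") == b
            assert len(aln.aligned_a) == len(aln.aligned_b)

    def test_traceback_score_consistent(self, rng):
        for _ in range(30):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(2, 30)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(2, 30)))
            aln = global_align(a, b)
            assert affine_score(aln.aligned_a, aln.aligned_b) == pytest.approx(
                aln.score
            )

    def test_matches_exhaustive_enumeration(self):
        rng = random.Random(1)
        for _ in range(12):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(1, 6)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(1, 6)))
            best = max(
                affine_score(ca, cb) for ca, cb in enumerate_alignments(a, b)
            )
            assert global_align(a, b).score == pytest.approx(best)

    def test_matches_biopython_aligner(self, rng):
        """Independent cross-check: biopython's PairwiseAligner under the
        equivalent gap parameterisation (open charged on the first gap
        column: open_gap_score = -(open + extend))."""
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = MATRIX
        aligner.mode = "global"
        aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
        aligner.extend_gap_score = -GAP_EXTEND
        for _ in range(20):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(5, 60)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(5, 60)))
            assert global_align(a, b).score == pytest.approx(aligner.score(a, b))


class TestClassification:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ("A", "A", "identical"),
            ("A", "V", "similar"),
            ("F", "Y", "similar"),
            ("D", "K", "divergent"),
            ("G", "P", "divergent"),
            ("A", "-", "unpaired"),
            ("-", "-", "unpaired"),
        ],
    )
    def test_pair_classification(self, x, y, expected):
        assert classify_pair(x, y) == expected

    def test_chemical_classes_symmetric(self):
        for x in AA:
            for y in AA:
                assert same_chemical_class(x, y) == same_chemical_class(y, x)


def build_pair(target_rows, comparison_rows):
    aln_t = make_alignment(target_rows, subtype="C_FAA")
    aln_c = make_alignment(comparison_rows, subtype="LCL")
    pt, pc = column_profiles(aln_t), column_profiles(aln_c)
    ct = extract_consensus(trim_columns(aln_t))
    cc = extract_consensus(trim_columns(aln_c))
    return build_shared_grid(ct, cc, pt, pc), aln_t, aln_c


class TestSharedGrid:
    def test_identical_consensus_all_identical(self):
        grid, *_ = build_pair(["MKLAVW"] * 4, ["MKLAVW"] * 4)
        assert all(p.classification == "identical" for p in grid.positions)
        assert all(p.profile_a and p.profile_b for p in grid.positions)

    def test_profiles_resolved_through_column_maps(self):
        grid, aln_t, _ = build_pair(["MKLAVW"] * 4, ["MKLAVW"] * 4)
        for p in grid.positions:
            assert p.profile_a.column_index == p.orig_col_a
            assert p.profile_a.n_rows == aln_t.n_rows

    def test_gapped_positions_unpaired(self):
        # target consensus is longer: extra residues must align to gaps
        grid, *_ = build_pair(["MKTAYIAKQRW"] * 4, ["MKTAYIAKQ"] * 4)
        unpaired = [p for p in grid.positions if p.classification == "unpaired"]
        assert len(unpaired) == 2
        assert all(p.profile_b is None for p in unpaired)


def sdp_fixture(target_s_count=18, comparison_s_count=2, n=20):
    """20-row families; column 3 of the target carries S at a controlled
    conservation while the comparison carries S in a controlled number of
    rows."""
    target_rows = [
        "MK" + ("S" if i < target_s_count else "A") + "LAV" for i in range(n)
    ]
    comparison_rows = [
        "MK" + ("S" if i < comparison_s_count else "T") + "LAV" for i in range(n)
    ]
    return build_pair(target_rows, comparison_rows)


class TestIdentifySdps:
    def test_sdp_called_when_both_criteria_met(self):
        grid, *_ = sdp_fixture(target_s_count=18, comparison_s_count=2)
        sdps = identify_sdps(grid)
        assert [r.orig_col_target for r in sdps] == [3]
        (rec,) = sdps
        assert rec.target_residue == "S"
        assert rec.target_conservation == pytest.approx(0.9)
        assert rec.comparison_frequency == pytest.approx(0.1)

    def test_comparison_frequency_above_ceiling_rejected(self):
        grid, *_ = sdp_fixture(comparison_s_count=6)  # 0.30 > 0.25
        assert identify_sdps(grid) == []

    def test_comparison_frequency_at_ceiling_accepted(self):
        grid, *_ = sdp_fixture(comparison_s_count=5)  # exactly 0.25
        assert [r.orig_col_target for r in identify_sdps(grid)] == [3]

    def test_low_conservation_rejected(self):
        grid, *_ = sdp_fixture(target_s_count=16)  # 0.80 < 0.85
        assert identify_sdps(grid) == []

    def test_conservation_at_threshold_accepted(self):
        grid, *_ = sdp_fixture(target_s_count=17)  # exactly 0.85
        assert [r.orig_col_target for r in identify_sdps(grid)] == [3]

    def test_entire_distribution_denominator_counts_gap_rows(self):
        # comparison column 3: 5 S, 10 T, 5 gaps -> frequency 5/20 = 0.25 over
        # all rows (SDP) but 5/15 = 0.33 over non-gap rows (rejected)
        target_rows = ["MKSLAV"] * 20
        comparison_rows = (
            ["MKSLAV"] * 5 + ["MKTLAV"] * 10 + ["MK-LAV"] * 5
        )
        grid, *_ = build_pair(target_rows, comparison_rows)
        assert [r.orig_col_target for r in identify_sdps(grid)] == [3]
        assert identify_sdps(grid, comparison_denominator="nongap") == []

    def test_monotone_in_thresholds(self):
        grid, *_ = sdp_fixture()
        base = {r.grid_index for r in identify_sdps(grid)}
        looser = {r.grid_index for r in identify_sdps(grid, comparison_max=0.5)}
        stricter = {
            r.grid_index for r in identify_sdps(grid, conservation_min=0.99)
        }
        assert base <= looser
        assert stricter <= base

    def test_sdps_lie_on_landmark_quality_columns(self):
        grid, *_ = sdp_fixture()
        for rec in identify_sdps(grid):
            assert rec.target_conservation >= 0.85
            assert rec.target_occupancy >= 0.80


class TestPlantedRecovery:
    def test_noise_free_exact_recovery(self):
        template = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSG" * 2
        planted = {10: "W", 40: "C", 75: "H"}
        target = FamilySpec(template=template, n_sequences=40, conservation=1.0,
                            subtype="C_FAA")
        comparison = FamilySpec(template=template, n_sequences=40,
                                conservation=1.0, subtype="LCL")
        aln_t, aln_c, truth = simulate_subtype_pair(
            target, comparison, planted, seed=5, comparison_ceiling=0.0
        )
        pt, pc = column_profiles(aln_t), column_profiles(aln_c)
        ct = extract_consensus(trim_columns(aln_t))
        cc = extract_consensus(trim_columns(aln_c))
        grid = build_shared_grid(ct, cc, pt, pc)
        found = sorted(r.orig_col_target for r in identify_sdps(grid))
        assert found == truth.sdp_positions

    def test_recall_under_substitution_noise(self):
        """With 5% substitution noise, recall stays >= 0.9 at defaults."""
        template = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSG" * 4
        planted = {15 + 20 * k: "W" for k in range(9)}
        planted = {
            pos: ("W" if template[pos - 1] != "W" else "C")
            for pos in planted
        }
        target = FamilySpec(template=template, n_sequences=150,
                            conservation=0.95, subtype="C_FAA")
        comparison = FamilySpec(template=template, n_sequences=150,
                                conservation=0.95, subtype="LCL")
        aln_t, aln_c, truth = simulate_subtype_pair(
            target, comparison, planted, seed=9, comparison_ceiling=0.10
        )
        pt, pc = column_profiles(aln_t), column_profiles(aln_c)
        ct = extract_consensus(trim_columns(aln_t))
        cc = extract_consensus(trim_columns(aln_c))
        grid = build_shared_grid(ct, cc, pt, pc)
        found = {r.orig_col_target for r in identify_sdps(grid)}
        recall = len(found & set(truth.sdp_positions)) / len(truth.sdp_positions)
        assert recall >= 0.9
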