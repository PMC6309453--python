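import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vnscan.motif_model import (
    SNBE,
    TERE,
    VNS,
    DegenerateMotif,
    PatternError,
    ProbabilityMatrix,
    align_matrices,
    enumerate_variants,
    information_content,
    matches,
    matrix_from_pattern,
    parse_pattern,
    pattern_subsumes,
    reverse_complement,
    trim_and_average,
)

# strategy for arbitrary degenerate motifs
allowed_sets = st.sets(st.sampled_from("ACGT"), min_size=1, max_size=4).map(frozenset)
motifs_st = st.lists(allowed_sets, min_size=1, max_size=20).map(
    lambda pos: DegenerateMotif("m", tuple(pos))
)


class TestParsePattern:
    def test_tere_is_11bp(self):
        assert len(parse_pattern(TERE)) == 11

    def test_vns_structure(self):
        m = parse_pattern(VNS)
        assert len(m) == 13
        assert m.positions[1] == frozenset("GT")
        assert m.positions[11] == frozenset("AC")
        assert m.positions[0] == frozenset("C")

    @pytest.mark.parametrize("bad", ["C(G/T", "AC)G", "C(G/X)T", "AcG", ""])
    def test_malformed_rejected(self, bad):
        with pytest.raises(PatternError):
            parse_pattern(bad)

    @given(motifs_st)
    @settings(max_examples=100, deadline=None)
    def test_render_parse_round_trip(self, motif):
        assert parse_pattern(motif.render()).positions == motif.positions


class TestMatches:
    def test_vns_examples(self, vns_motif):
        assert matches(vns_motif, "CTTAAAAAAAAAG")
        assert not matches(vns_motif, "CATAAAAAAAAAG")  # pos 2: A not in {G,T}

    def test_window_with_n_never_matches(self, tere_motif):
        assert not matches(tere_motif, "CTTNAAAGCNA")  # N is not a concrete base

    def test_length_mismatch_is_error(self, vns_motif):
        with pytest.raises(ValueError):
            matches(vns_motif, "ACGT")


class TestReverseComplement:
    def test_vns_is_self_palindromic(self, vns_motif):
        assert reverse_complement(vns_motif).positions == vns_motif.positions

    def test_hand_computed_pair(self):
        # reverse then complement by hand: CTT..ACG -> CGT..AAG
        rc = reverse_complement(parse_pattern("CTTNNNNNNNACG"))
        assert rc.render() == "CGTNNNNNNNAAG"

    @given(motifs_st)
    @settings(max_examples=100, deadline=None)
    def test_involution(self, motif):
        assert reverse_complement(reverse_complement(motif)).positions == motif.positions


class TestEnumerateVariants:
    def test_vns_four_variants(self, vns_motif):
        names = [v.name for v in enumerate_variants(vns_motif)]
        assert names == [
            "CGTNNNNNNNAAG", "CGTNNNNNNNACG", "CTTNNNNNNNAAG", "CTTNNNNNNNACG",
        ]

    def test_concrete_motif_is_its_own_variant(self):
        assert [v.name for v in enumerate_variants(parse_pattern("ACGT"))] == ["ACGT"]

    def test_snbe_expansion_size(self):
        # product of set sizes of the degenerate (non-N) positions
        assert len(enumerate_variants(parse_pattern(SNBE))) == 2 * 2 * 3 * 2 * 3 * 2

    def test_guard_on_explosion(self):
        with pytest.raises(ValueError, match="256"):
            enumerate_variants(parse_pattern("(A/C)" * 9))

    def test_vns_variant_set_closed_under_revcomp(self, vns_motif):
        names = {v.name for v in enumerate_variants(vns_motif)}
        rc_names = {
            reverse_complement(v).render() for v in enumerate_variants(vns_motif)
        }
        assert names == rc_names
        # the two asymmetric variants pair up; the other two are fixed points
        assert reverse_complement(parse_pattern("CTTNNNNNNNACG")).render() == "CGTNNNNNNNAAG"
        assert reverse_complement(parse_pattern("CTTNNNNNNNAAG")).render() == "CTTNNNNNNNAAG"
        assert reverse_complement(parse_pattern("CGTNNNNNNNACG")).render() == "CGTNNNNNNNACG"

    @given(motifs_st)
    @settings(max_examples=50, deadline=None)
    def test_count_is_product_of_set_sizes(self, motif):
        expected = 1
        for s in motif.positions:
            if 1 < len(s) < 4:
                expected *= len(s)
        if expected <= 256:
            assert len(enumerate_variants(motif)) == expected


class TestPatternSubsumes:
    def test_tere_core_within_snbe_core(self):
        # the TERE is a specialization of the relaxed core CTTNNNNNNNA
        assert pattern_subsumes(parse_pattern("CTTNNNNNNNA"), parse_pattern(TERE), 0)

    def test_not_symmetric(self):
        assert not pattern_subsumes(parse_pattern(TERE), parse_pattern("CTTNNNNNNNA"), 0)

    @given(motifs_st)
    @settings(max_examples=50, deadline=None)
    def test_reflexive(self, motif):
        assert pattern_subsumes(motif, motif, 0)


def _noisy_core(rng, core, concentration=50.0):
    return np.array([rng.dirichlet(np.maximum(concentration * c, 1e-9)) for c in core])


class TestAlignMatrices:
    def test_identical_matrices_offsets_zero(self):
        core = matrix_from_pattern(parse_pattern(VNS))
        out = align_matrices([core, ProbabilityMatrix(core.probs.copy())])
        assert [off for _, off in out] == [0, 0]

    def test_prepended_flanks_recovered(self):
        rng = np.random.default_rng(0)
        core = matrix_from_pattern(parse_pattern(VNS))
        flanked = ProbabilityMatrix(
            np.vstack([[rng.dirichlet(np.ones(4)) for _ in range(2)], core.probs])
        )
        out = align_matrices([core, flanked])
        offs = [off for _, off in out]
        # core column 0 must land two axis positions right of flanked column 0
        assert offs[0] - offs[1] == 2

    def test_planted_shifts_recovered(self):
        rng = np.random.default_rng(12)
        core = matrix_from_pattern(parse_pattern(VNS)).probs
        mats = []
        for shift in (0, 1, 3):
            flanks = [rng.dirichlet(np.ones(4)) for _ in range(shift)]
            block = _noisy_core(rng, core)
            mats.append(ProbabilityMatrix(np.vstack([*flanks, block]) if shift else block))
        out = align_matrices(mats)
        offs = [off for _, off in out]
        # all cores land on the same axis position
        assert len({offs[i] + s for i, s in enumerate((0, 1, 3))}) == 1

    def test_short_matrix_rejected(self):
        short = ProbabilityMatrix(np.full((5, 4), 0.25))
        with pytest.raises(ValueError):
            align_matrices([short, short])


class TestTrimAndAverage:
    def test_idempotent_on_identical_matrices(self):
        core = matrix_from_pattern(parse_pattern(VNS))
        aligned = [(core, 0)] * 4
        avg = trim_and_average(aligned, target_length=13)
        assert np.allclose(avg.probs, core.probs)

    def test_column_mean(self):
        a = ProbabilityMatrix(np.tile([1.0, 0, 0, 0], (13, 1)))
        b = ProbabilityMatrix(np.tile([0, 1.0, 0, 0], (13, 1)))
        avg = trim_and_average([(a, 0), (b, 0)], target_length=13)
        assert np.allclose(avg.probs, np.tile([0.5, 0.5, 0, 0], (13, 1)))

    def test_synthetic_fixture_recovery(self, meme_fixture):
        files, core, _ = meme_fixture
        aligned = align_matrices([f.matrix for f in files])
        avg = trim_and_average(aligned, target_length=13)
        assert len(avg) == 13
        assert np.abs(avg.probs - core.probs).max() <= 0.05

    def test_columns_sum_to_one(self, meme_fixture):
        files, _, _ = meme_fixture
        avg = trim_and_average(align_matrices([f.matrix for f in files]))
        assert np.allclose(avg.probs.sum(axis=1), 1.0, atol=1e-6)

    def test_error_when_no_shared_window(self):
        a = ProbabilityMatrix(np.full((13, 4), 0.25))
        with pytest.raises(ValueError):
            trim_and_average([(a, 0), (a, 40)], target_length=13)


class TestInformationContent:
    @pytest.mark.parametrize(
        "column,expected",
        [([0.25, 0.25, 0.25, 0.25], 0.0), ([1, 0, 0, 0], 2.0), ([0.5, 0.5, 0, 0], 1.0)],
    )
    def test_closed_forms(self, column, expected):
        m = ProbabilityMatrix(np.array([column], dtype=float))
        assert information_content(m)[0] == pytest.approx(expected)
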