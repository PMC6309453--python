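import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vnscan.allele_compare import (
    annotate_disruptions,
    call_snps,
    count_substitutions,
    global_align,
    tile_fragments,
)
from vnscan.motif_model import matches, parse_pattern
from vnscan.motif_scan import revcomp_seq, scan_sequence

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestGlobalAlign:
    def test_identical_sequences_no_gaps(self):
        a, b = global_align("ACGTACGT", "ACGTACGT")
        assert a == b == "ACGTACGT"

    def test_single_substitution(self):
        a, b = global_align("ACGTACGT", "ACGAACGT")
        assert "-" not in a and "-" not in b
        mismatches = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
        assert mismatches == [3]  # 1-based position 4

    def test_planted_deletion_and_substitutions(self):
        rng = np.random.default_rng(3)
        ref = _random_dna(rng, 540)
        alt = list(ref)
        sub_sites = sorted(rng.choice(500, size=5, replace=False))
        for p in sub_sites:
            alt[p] = {"A": "G", "C": "T", "G": "A", "T": "C"}[alt[p]]
        del alt[520]
        a, b = global_align(ref, "".join(alt))
        assert a.count("-") == 0 and b.count("-") == 1
        snps = call_snps(a, b)
        assert count_substitutions(snps) == 5
        assert sum(1 for s in snps if s.kind == "deletion") == 1


class TestCallSnps:
    def test_no_differences(self):
        assert call_snps("ACGT", "ACGT") == []

    def test_gap_run_collapsed(self):
        snps = call_snps("ACGGGT", "AC---T")
        assert len(snps) == 1
        assert snps[0].kind == "deletion"
        assert snps[0].ref_base == "GGG"
        assert snps[0].ref_pos == 2

    def test_insertion_recorded(self):
        snps = call_snps("AC--T", "ACGGT")
        assert [s.kind for s in snps] == ["insertion"]
        assert snps[0].alt_base == "GG"

    @given(dna)
    @settings(max_examples=50, deadline=None)
    def test_self_alignment_yields_no_snps(self, s):
        assert call_snps(*global_align(s, s)) == []

    @given(
        st.text(alphabet="ACGT", min_size=20, max_size=80),
        st.lists(st.integers(min_value=0, max_value=19), max_size=6, unique=True),
    )
    @settings(max_examples=50, deadline=None)
    def test_substitution_count_symmetric(self, a, flip_sites):
        b = list(a)
        for p in flip_sites:
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        b = "".join(b)
        fwd = count_substitutions(call_snps(*global_align(a, b)))
        rev = count_substitutions(call_snps(*global_align(b, a)))
        assert fwd == rev == len(flip_sites)

    def test_ungapped_ref_pos_equals_alt_pos(self):
        rng = np.random.default_rng(8)
        ref = _random_dna(rng, 200)
        alt = list(ref)
        for p in (10, 50, 90):
            alt[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[alt[p]]
        snps = call_snps(*global_align(ref, "".join(alt)))
        assert [s.ref_pos for s in snps] == [10, 50, 90]


class TestTileFragments:
    def test_nine_fragments_cover_promoter(self):
        frags = tile_fragments(539, 9, 0.5)
        assert [f.label for f in frags] == list("ABCDEFGHI")
        assert frags[0].start == 0 and frags[-1].end == 539
        covered = set()
        for f in frags:
            covered.update(range(f.start, f.end))
        assert covered == set(range(539))
        for a, b in zip(frags, frags[1:]):
            assert b.start < a.end  # consecutive fragments overlap

    def test_two_halves_no_overlap(self):
        frags = tile_fragments(100, 2, 0.0)
        assert [(f.start, f.end) for f in frags] == [(0, 50), (50, 100)]

    def test_infeasible_geometry(self):
        with pytest.raises(ValueError):
            tile_fragments(9, 10)

    @given(
        length=st.integers(min_value=60, max_value=2000),
        n=st.integers(min_value=2, max_value=12),
        overlap=st.sampled_from([0.0, 0.25, 0.5, 0.75]),
    )
    @settings(max_examples=100, deadline=None)
    def test_union_covers_everything(self, length, n, overlap):
        try:
            frags = tile_fragments(length, n, overlap)
        except ValueError:
            return
        covered = set()
        for f in frags:
            covered.update(range(f.start, f.end))
        assert covered == set(range(length))
        if overlap > 0:
            for a, b in zip(frags, frags[1:]):
                assert b.start < a.end


class TestAnnotateDisruptions:
    TERE = parse_pattern("CTTNAAAGCNA", "TERE")

    def _ref_with_tere(self, rng, length=200, at=80, site="CTTGAAAGCTA"):
        ref = list(_random_dna(rng, length))
        ref[at : at + 11] = site
        return "".join(ref)

    def test_substitution_at_position_two_disrupts(self):
        rng = np.random.default_rng(5)
        ref = self._ref_with_tere(rng)
        while len(scan_sequence(ref, self.TERE, "both-dedup")) != 1:
            ref = self._ref_with_tere(rng)
        alt = ref[:81] + "G" + ref[82:]  # motif position 2: T -> G
        report = annotate_disruptions(ref, alt, [self.TERE])
        rows = [r for r in report.rows if r.occurrence.start == 80]
        assert len(rows) == 1
        assert rows[0].disrupted
        assert rows[0].motif_positions_hit == [2]

    def test_substitution_at_n_position_tolerated(self):
        rng = np.random.default_rng(5)
        ref = self._ref_with_tere(rng)
        while len(scan_sequence(ref, self.TERE, "both-dedup")) != 1:
            ref = self._ref_with_tere(rng)
        # motif position 4 is N: any base is allowed
        new = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref[83]]
        alt = ref[:83] + new + ref[84:]
        report = annotate_disruptions(ref, alt, [self.TERE])
        row = next(r for r in report.rows if r.occurrence.start == 80)
        assert not row.disrupted
        assert row.motif_positions_hit == [4]

    def test_snp_outside_occurrences(self):
        rng = np.random.default_rng(6)
        ref = self._ref_with_tere(rng)
        while len(scan_sequence(ref, self.TERE, "both-dedup")) != 1:
            ref = self._ref_with_tere(rng)
        alt = ref[:5] + {"A": "C", "C": "A", "G": "T", "T": "G"}[ref[5]] + ref[6:]
        report = annotate_disruptions(ref, alt, [self.TERE])
        assert all(r.disrupting_snps == [] for r in report.rows)
        assert not any(r.disrupted for r in report.rows)

    def test_indel_overlap_flagged(self):
        rng = np.random.default_rng(9)
        ref = self._ref_with_tere(rng)
        while len(scan_sequence(ref, self.TERE, "both-dedup")) != 1:
            ref = self._ref_with_tere(rng)
        alt = ref[:85] + ref[86:]  # delete a base inside the motif window
        report = annotate_disruptions(ref, alt, [self.TERE])
        row = next(r for r in report.rows if r.occurrence.start == 80)
        assert row.disrupted and row.kind == "indel-overlap"

    def test_disruption_agrees_with_rescan_oracle(self, allele_fixture):
        """disrupted=True iff the mapped window fails the pattern on the
        alternate allele — cross-checked by independently re-scanning alt."""
        ref, alt, truth = allele_fixture
        tere = self.TERE
        report = annotate_disruptions(ref, alt, [tere])
        for row in report.rows:
            occ = row.occurrence
            if row.kind == "indel-overlap":
                assert row.disrupted
                continue
            # oracle: shift the window by upstream deletions, re-check on alt
            shift = sum(1 for d in truth.deletions if d < occ.start)
            window = alt[occ.start - shift : occ.start - shift + len(tere)]
            if occ.strand == "-":
                window = revcomp_seq(window)
            assert row.disrupted == (not matches(tere, window))

    def test_fragment_assignment(self):
        rng = np.random.default_rng(5)
        ref = self._ref_with_tere(rng)
        while len(scan_sequence(ref, self.TERE, "both-dedup")) != 1:
            ref = self._ref_with_tere(rng)
        frags = tile_fragments(len(ref), 4, 0.5)
        report = annotate_disruptions(ref, ref[:-1] + "A" if ref[-1] != "A" else ref[:-1] + "C",
                                      [self.TERE], frags)
        row = next(r for r in report.rows if r.occurrence.start == 80)
        for label in row.fragments:
            f = next(f for f in frags if f.label == label)
            assert f.start <= 80 and 91 <= f.end
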