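"""Promoter allele comparison: alignment, SNP calling, disruption annotation.

Workflow modeled on a promoter-allele binding screen: globally align two
promoter alleles, call substitutions and indels, tile the reference into
overlapping lettered fragments (the yeast one-hybrid screen geometry), and
for every binding-site occurrence on the reference ask whether the other
allele still satisfies the degenerate pattern — i.e. which SNPs disrupt
which motif position.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

from Bio import Align

from .motif_model import DegenerateMotif, matches
from .motif_scan import MotifOccurrence, revcomp_seq, scan_sequence

# Alignment scoring fixed for determinism: match +1, mismatch -1,
# gap open -4, gap extend -1 (a length-L gap costs 4 + (L-1)).
MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_OPEN = -4
GAP_EXTEND = -1


def global_align(ref: str, alt: str) -> tuple[str, str]:
    """Needleman-Wunsch global alignment; returns the two gapped strings."""
    if not ref or not alt:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=MATCH_SCORE,
        mismatch_score=MISMATCH_SCORE,
        open_gap_score=GAP_OPEN,
        extend_gap_score=GAP_EXTEND,
    )
    aln = aligner.align(ref.upper(), alt.upper())[0]
    return str(aln[0]), str(aln[1])


@dataclass(frozen=True)
class SnpRecord:
    """A called difference between two aligned alleles.

    ``ref_pos`` is the 0-based offset on the ungapped reference; for an
    insertion it is the reference offset immediately after which the run is
    inserted.  ``ref_base``/``alt_base`` hold the full run for indels.
    """

    ref_pos: int
    ref_base: str
    alt_base: str
    kind: str  # substitution | insertion | deletion

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            if self.ref_base == self.alt_base or len(self.ref_base) != 1:
                raise ValueError("substitution must change a single base")
        elif self.kind not in ("insertion", "deletion"):
            raise ValueError(f"unknown SNP kind {self.kind!r}")


def call_snps(aligned_ref: str, aligned_alt: str) -> list[SnpRecord]:
    """Call substitutions and indels from a gapped alignment.

    One substitution per mismatch column; maximal gap runs collapse into a
    single insertion/deletion record.  Substitution counts in reports always
    exclude indels.
    """
    if len(aligned_ref) != len(aligned_alt):
        raise ValueError("aligned strings differ in length")
    snps: list[SnpRecord] = []
    ref_pos = 0
    i = 0
    n = len(aligned_ref)
    while i < n:
        r, a = aligned_ref[i], aligned_alt[i]
        if r == "-" and a == "-":
            raise ValueError(f"double gap at alignment column {i}")
        if r == "-":  # insertion in alt
            j = i
            run = []
            while j < n and aligned_ref[j] == "-":
                run.append(aligned_alt[j])
                j += 1
            snps.append(
                SnpRecord(ref_pos - 1, "", "".join(run), "insertion")
            )
            i = j
        elif a == "-":  # deletion from ref
            j = i
            run = []
            while j < n and aligned_alt[j] == "-":
                run.append(aligned_ref[j])
                j += 1
            snps.append(SnpRecord(ref_pos, "".join(run), "", "deletion"))
            ref_pos += j - i
            i = j
        else:
            if r != a:
                snps.append(SnpRecord(ref_pos, r, a, "substitution"))
            ref_pos += 1
            i += 1
    return snps


def count_substitutions(snps: list[SnpRecord]) -> int:
    return sum(1 for s in snps if s.kind == "substitution")


@dataclass(frozen=True)
class FragmentSpec:
    """A lettered promoter fragment, 0-based half-open on the reference."""

    label: str
    start: int
    end: int


def tile_fragments(
    length: int, n_fragments: int = 9, overlap_fraction: float = 0.5
) -> list[FragmentSpec]:
    """Tile [0, length) into ``n_fragments`` equal overlapping fragments.

    Fragments are labeled A, B, C, ...; consecutive fragments overlap by
    round(fragment_length * overlap_fraction) and the last fragment is
    shifted to end exactly at ``length``.  Defaults give nine overlapping
    fragments over a ~540 bp promoter, the geometry of a fragment-by-fragment
    binding screen.
    """
    if n_fragments < 2:
        raise ValueError("need at least 2 fragments")
    if not (0.0 <= overlap_fraction <= 0.9):
        raise ValueError("overlap_fraction must be in [0, 0.9]")
    frag_len = -(-length // (n_fragments - (n_fragments - 1) * overlap_fraction))
    frag_len = int(frag_len)
    step = frag_len - round(frag_len * overlap_fraction)
    last_start = length - frag_len
    if frag_len < 1 or step < 1 or (n_fragments - 2) * step > last_start:
        raise ValueError(
            f"cannot tile length {length} into {n_fragments} fragments "
            f"at overlap {overlap_fraction}"
        )
    labels = string.ascii_uppercase
    if n_fragments > len(labels):
        raise ValueError("more fragments than single-letter labels")
    frags = []
    for k in range(n_fragments - 1):
        frags.append(FragmentSpec(labels[k], k * step, k * step + frag_len))
    frags.append(FragmentSpec(labels[n_fragments - 1], last_start, length))
    return frags


@dataclass
class DisruptionRow:
    """Disruption status of one reference-allele motif occurrence."""

    motif_name: str
    occurrence: MotifOccurrence
    disrupting_snps: list[SnpRecord]
    motif_positions_hit: list[int]  # 1-based from the motif 5' end
    disrupted: bool
    fragments: list[str]
    kind: str = "substitution"  # or "indel-overlap" when a gap spans the site


@dataclass
class DisruptionReport:
    rows: list[DisruptionRow] = field(default_factory=list)

    def disrupted_rows(self) -> list[DisruptionRow]:
        return [r for r in self.rows if r.disrupted]


def _ref_to_column(aligned_ref: str) -> list[int]:
    """Map each ungapped reference offset to its alignment column."""
    cols = []
    for i, c in enumerate(aligned_ref):
        if c != "-":
            cols.append(i)
    return cols


def annotate_disruptions(
    ref: str,
    alt: str,
    motifs: list[DegenerateMotif],
    fragments: list[FragmentSpec] | None = None,
) -> DisruptionReport:
    """Annotate which allele differences break which binding-site positions.

    Scans the reference allele for each motif (both strands, deduplicating
    self-palindromic loci), maps every occurrence window through the global
    alignment onto the other allele, and reports the SNPs inside the window,
    the 1-based motif positions they hit, and whether the mapped window still
    matches the degenerate pattern.  A window overlapping an alignment gap is
    flagged disrupted with kind ``indel-overlap``.  Occurrences are assigned
    to every fragment that fully contains them.
    """
    ref, alt = ref.upper(), alt.upper()
    aligned_ref, aligned_alt = global_align(ref, alt)
    snps = call_snps(aligned_ref, aligned_alt)
    ref_cols = _ref_to_column(aligned_ref)
    report = DisruptionReport()
    for motif in motifs:
        occs = scan_sequence(ref, motif, "both-dedup", sequence_id="ref")
        for occ in occs:
            lo, hi = occ.start, occ.start + len(motif)  # half-open on ref
            in_window = [
                s for s in snps
                if s.kind == "substitution" and lo <= s.ref_pos < hi
            ]
            # indels interacting with the window (an insertion between
            # ref_pos and ref_pos+1 breaks the window if strictly inside)
            indel_hit = any(
                (s.kind == "deletion" and s.ref_pos < hi and s.ref_pos + len(s.ref_base) > lo)
                or (s.kind == "insertion" and lo <= s.ref_pos < hi - 1)
                for s in snps
                if s.kind != "substitution"
            )

            def motif_position(ref_pos: int) -> int:
                if occ.strand == "+":
                    return ref_pos - lo + 1
                return hi - ref_pos  # motif read 3'->5' on the forward strand

            columns = ref_cols[lo:hi]
            alt_window = "".join(aligned_alt[c] for c in columns)
            if indel_hit or "-" in alt_window:
                disrupted = True
                kind = "indel-overlap"
                hits = sorted(motif_position(s.ref_pos) for s in in_window)
            else:
                window = alt_window if occ.strand == "+" else revcomp_seq(alt_window)
                disrupted = not matches(motif, window)
                kind = "substitution"
                hits = sorted(motif_position(s.ref_pos) for s in in_window)
            frag_labels = [
                f.label
                for f in (fragments or [])
                if f.start <= lo and hi <= f.end
            ]
            report.rows.append(
                DisruptionRow(
                    motif_name=motif.name,
                    occurrence=occ,
                    disrupting_snps=in_window,
                    motif_positions_hit=hits,
                    disrupted=disrupted,
                    fragments=frag_labels,
                    kind=kind,
                )
            )
    return report
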