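"""Degenerate-motif scanning and variant count / percentage tables.

Scanning is exact degenerate-pattern matching (no log-odds scores): every
window position must fall in the motif's allowed set, windows containing N
never match, and all overlapping occurrences are reported.  The VNS element
C(G/T)TNNNNNNNA(A/C)G expands into four concrete variants whose genome-wide
frequencies form the variant table; because the variant set is closed under
reverse complement, forward-strand scanning already represents sites on
either strand, so variant counting defaults to the forward strand only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .io_formats import SeqRecordSet, extract_peak_sequences, read_narrowpeak
from .motif_model import (
    ALPHABET,
    DegenerateMotif,
    enumerate_variants,
    matches,
    reverse_complement,
)

logger = logging.getLogger(__name__)

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def revcomp_seq(seq: str) -> str:
    """Reverse complement of a concrete sequence (N maps to N)."""
    return seq.translate(_RC_TABLE)[::-1]


@dataclass(frozen=True)
class MotifOccurrence:
    """One motif match: sequence, 0-based start, strand, concrete variant."""

    sequence_id: str
    start: int
    strand: str
    variant_name: str
    window: str


def _motif_regex(motif: DegenerateMotif) -> re.Pattern[str]:
    parts = []
    for s in motif.positions:
        if len(s) == 4:
            parts.append("[ACGT]")  # N in the subject never matches
        elif len(s) == 1:
            parts.append(next(iter(s)))
        else:
            parts.append("[" + "".join(b for b in ALPHABET if b in s) + "]")
    # lookahead so overlapping occurrences are all found
    return re.compile("(?=(" + "".join(parts) + "))")


def _classify(window: str, variants: list[DegenerateMotif]) -> str:
    for v in variants:
        if matches(v, window):
            return v.name
    raise AssertionError(f"window {window!r} matched motif but no variant")


def scan_sequence(
    seq: str,
    motif: DegenerateMotif,
    strand_mode: str = "forward",
    sequence_id: str = "seq",
) -> list[MotifOccurrence]:
    """Find all occurrences of a degenerate motif in one sequence.

    ``strand_mode='forward'`` scans the given strand only.  In
    ``'both-dedup'`` mode the reverse strand is scanned too (as forward
    matches of the reverse-complemented motif, reported with strand '-' at
    forward coordinates), except that a locus whose forward-strand window
    also matches the motif is reported once, as the forward occurrence —
    relevant for degenerate self-palindromes like the VNS.
    """
    if strand_mode not in ("forward", "both-dedup"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    seq = seq.upper()
    variants = enumerate_variants(motif)
    occs: list[MotifOccurrence] = []
    fwd_starts = set()
    for m in _motif_regex(motif).finditer(seq):
        window = m.group(1)
        occs.append(
            MotifOccurrence(
                sequence_id=sequence_id,
                start=m.start(),
                strand="+",
                variant_name=_classify(window, variants),
                window=window,
            )
        )
        fwd_starts.add(m.start())
    if strand_mode == "both-dedup":
        rc_motif = reverse_complement(motif)
        rc_variants = enumerate_variants(rc_motif)
        for m in _motif_regex(rc_motif).finditer(seq):
            if m.start() in fwd_starts:
                continue  # same locus already reported on the forward strand
            window = m.group(1)
            occs.append(
                MotifOccurrence(
                    sequence_id=sequence_id,
                    start=m.start(),
                    strand="-",
                    # variant named for how the site reads on its own strand
                    variant_name=_classify(
                        revcomp_seq(window), variants
                    ),
                    window=window,
                )
            )
        occs.sort(key=lambda o: (o.start, o.strand))
    return occs


@dataclass
class VariantCountTable:
    """Per-variant counts and percentages (the genome/peak variant table).

    Percentages are each variant's proportion of the summed count times 100;
    unrounded values sum to exactly 100 whenever ``total > 0``.  Display
    rounding to one decimal happens only at serialization.
    """

    rows: list[tuple[str, int, float]]
    total: int
    source_label: str = ""

    def percentage(self, variant_name: str) -> float:
        for name, _, pct in self.rows:
            if name == variant_name:
                return pct
        raise KeyError(variant_name)

    def count(self, variant_name: str) -> int:
        for name, cnt, _ in self.rows:
            if name == variant_name:
                return cnt
        raise KeyError(variant_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["variant", "count", "percentage"])

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df["percentage"] = df["percentage"].map(lambda p: f"{p:.1f}")
        df.to_csv(path, sep="\t", index=False)


def count_variants(
    seqs: SeqRecordSet, motif: DegenerateMotif, source_label: str = ""
) -> VariantCountTable:
    """Count each concrete variant of ``motif`` over all records (forward).

    One row per variant in enumeration order; counts are pooled across
    records.  With no matches at all, percentages are reported as 0 with a
    warning (a 0/0 proportion has no defined value).
    """
    variants = enumerate_variants(motif)
    counts = {v.name: 0 for v in variants}
    for ident, seq in seqs:
        for occ in scan_sequence(seq, motif, "forward", sequence_id=ident):
            counts[occ.variant_name] += 1
    total = sum(counts.values())
    if total == 0:
        logger.warning(
            "no occurrences of %s in %s: percentages undefined, reported as 0",
            motif.render(), source_label or "input",
        )
    rows = [
        (v.name, counts[v.name], 100.0 * counts[v.name] / total if total else 0.0)
        for v in variants
    ]
    return VariantCountTable(rows=rows, total=total, source_label=source_label)


def scan_peak_files(
    peak_paths: list[str | Path],
    genome: SeqRecordSet,
    motif: DegenerateMotif,
) -> tuple[list[VariantCountTable], VariantCountTable]:
    """Variant tables per narrowPeak file plus their mean-percentage table.

    Mirrors the DAP-seq treatment: each peak file's sequences are extracted
    from the genome and tabulated separately; the summary percentage for a
    variant is the arithmetic mean of its per-file percentages.  Files with
    zero motif sites are excluded from the mean (warned).  The mean table's
    ``count`` column holds the summed counts and ``total`` the grand total;
    its percentages are the across-file means, which need not sum to 100.
    """
    per_file: list[VariantCountTable] = []
    for path in peak_paths:
        peaks = read_narrowpeak(path)
        seqs = extract_peak_sequences(peaks, genome)
        per_file.append(count_variants(seqs, motif, source_label=str(path)))
    contributing = [t for t in per_file if t.total > 0]
    if len(contributing) < len(per_file):
        logger.warning(
            "%d of %d peak files had zero motif sites; excluded from the mean",
            len(per_file) - len(contributing), len(per_file),
        )
    variants = [name for name, _, _ in per_file[0].rows] if per_file else []
    mean_rows = []
    for name in variants:
        total_count = sum(t.count(name) for t in per_file)
        if contributing:
            mean_pct = sum(t.percentage(name) for t in contributing) / len(contributing)
        else:
            mean_pct = 0.0
        mean_rows.append((name, total_count, mean_pct))
    mean_table = VariantCountTable(
        rows=mean_rows,
        total=sum(t.total for t in per_file),
        source_label="mean across peak files",
    )
    return per_file, mean_table


def expected_match_probability(motif: DegenerateMotif, gc: float) -> float:
    """Per-window match probability under an i.i.d. background of given GC.

    p(A) = p(T) = (1-gc)/2 and p(C) = p(G) = gc/2; the window probability is
    the product over positions of the summed allowed-base probabilities.
    Closed-form null model for calibration tests (VNS at GC 0.5: 1/1024).
    """
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0, 1)")
    base_p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "C": gc / 2, "G": gc / 2}
    prob = 1.0
    for s in motif.positions:
        prob *= sum(base_p[b] for b in s)
    return prob
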