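"""Readers and writers for FASTA, MEME text v4, and ENCODE narrowPeak.

All coordinates are 0-based half-open internally (the narrowPeak/BED
convention); 1-based inclusive coordinates appear only in human-readable
report text.  Peak strand is ignored for sequence extraction — DAP-seq peaks
are effectively unstranded and strand handling belongs to the scanner.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .motif_model import ProbabilityMatrix, information_content

_VALID_CHARS = set("ACGTN")


class ParseError(ValueError):
    """Malformed input file; message names the file and line."""


class CoordinateError(ValueError):
    """Peak coordinates incompatible with the genome they reference."""


@dataclass
class SeqRecordSet:
    """Ordered named DNA sequences (uppercase over A,C,G,T,N).

    Identifiers are unique and order is preserved; this is the carrier for
    promoter alleles, synthetic genomes, and extracted peak sequences.
    """

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate identifier {dup!r}")
        for ident, seq in self.records:
            if not seq:
                raise ValueError(f"record {ident!r} has empty sequence")
            bad = set(seq) - _VALID_CHARS
            if bad:
                raise ValueError(f"record {ident!r} has illegal characters {bad}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, ident: str) -> str:
        for i, s in self.records:
            if i == ident:
                return s
        raise KeyError(ident)

    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]


def read_fasta(path: str | Path) -> SeqRecordSet:
    """Read a (possibly multi-record) FASTA file.

    Lowercase is mapped to uppercase; any character outside A,C,G,T,N
    (either case) raises :class:`ParseError` naming the line number.
    An empty file yields an empty record set.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    ident: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if ident is not None:
            records.append((ident, "".join(chunks)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                ident = line[1:].split()[0] if len(line) > 1 else ""
                if not ident:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
            else:
                if ident is None:
                    raise ParseError(
                        f"{path}:{lineno}: sequence before any '>' header"
                    )
                up = line.upper()
                bad = set(up) - _VALID_CHARS
                if bad:
                    raise ParseError(
                        f"{path}:{lineno}: illegal sequence characters {sorted(bad)}"
                    )
                chunks.append(up)
    flush()
    try:
        return SeqRecordSet(records)
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from e


def write_fasta(records: SeqRecordSet, path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w") as fh:
        for ident, seq in records:
            fh.write(f">{ident}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class MemeMotifFile:
    """One motif parsed from a MEME text v4 file."""

    motif_name: str
    matrix: ProbabilityMatrix
    source_path: str = ""


_LPM_RE = re.compile(
    r"letter-probability matrix:(?:\s+alength=\s*(\d+))?(?:\s+w=\s*(\d+))?"
)


def read_meme(path: str | Path, row_tolerance: float = 1e-3) -> list[MemeMotifFile]:
    """Parse MEME text v4 "letter-probability matrix" blocks.

    Returns one :class:`MemeMotifFile` per MOTIF block, probabilities in
    A,C,G,T order.  Requires an ``ALPHABET= ACGT`` line; a matrix row whose
    probabilities do not sum to 1 within ``row_tolerance`` is rejected.
    Blocks other than MOTIF / letter-probability are ignored.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    alphabet_seen = False
    motifs: list[MemeMotifFile] = []
    current_name: str | None = None
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("ALPHABET"):
            alpha = line.split("=", 1)[-1].strip().replace(" ", "")
            if alpha != "ACGT":
                raise ParseError(f"{path}:{i+1}: unsupported alphabet {alpha!r}")
            alphabet_seen = True
        elif line.startswith("MOTIF"):
            parts = line.split()
            current_name = parts[1] if len(parts) > 1 else f"motif_{len(motifs)+1}"
        elif _LPM_RE.match(line):
            if not alphabet_seen:
                raise ParseError(f"{path}:{i+1}: no ALPHABET line before matrix")
            if current_name is None:
                raise ParseError(f"{path}:{i+1}: matrix outside a MOTIF block")
            m = _LPM_RE.match(line)
            declared_w = int(m.group(2)) if m.group(2) else None
            rows = []
            j = i + 1
            while j < len(lines):
                row = lines[j].strip()
                fields = row.split()
                if len(fields) == 4:
                    try:
                        vals = [float(x) for x in fields]
                    except ValueError:
                        break
                    s = sum(vals)
                    if abs(s - 1.0) > row_tolerance:
                        raise ParseError(
                            f"{path}:{j+1}: matrix row sums to {s:g}, not 1"
                        )
                    rows.append(vals)
                    j += 1
                elif row == "":
                    break
                else:
                    break
            if not rows:
                raise ParseError(f"{path}:{i+1}: empty letter-probability matrix")
            if declared_w is not None and declared_w != len(rows):
                raise ParseError(
                    f"{path}:{i+1}: declared w={declared_w} but {len(rows)} rows"
                )
            probs = np.array(rows)
            probs = probs / probs.sum(axis=1, keepdims=True)
            motifs.append(
                MemeMotifFile(
                    motif_name=current_name,
                    matrix=ProbabilityMatrix(probs, name=current_name),
                    source_path=str(path),
                )
            )
            current_name = None
            i = j - 1
        i += 1
    return motifs


def write_meme(matrix: ProbabilityMatrix, path: str | Path, nsites: int = 20) -> None:
    """Write a single probability matrix as a minimal MEME text v4 file."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        fh.write(f"MOTIF {matrix.name or 'consensus'}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {len(matrix)} "
            f"nsites= {nsites} E= 0\n"
        )
        for col in matrix.probs:
            fh.write(" ".join(f"{p:.6f}" for p in col) + "\n")


def write_matrix_tsv(matrix: ProbabilityMatrix, path: str | Path) -> None:
    """Write a matrix as TSV: position (1-based), pA, pC, pG, pT, IC_bits."""
    ic = information_content(matrix)
    df = pd.DataFrame(
        {
            "position": np.arange(1, len(matrix) + 1),
            "pA": matrix.probs[:, 0],
            "pC": matrix.probs[:, 1],
            "pG": matrix.probs[:, 2],
            "pT": matrix.probs[:, 3],
            "IC_bits": ic,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass
class PeakRecord:
    """One ENCODE narrowPeak (BED6+4) interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    signal: float = 0.0
    p: float = -1.0
    q: float = -1.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.summit_offset != -1 and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak "
                f"{self.chrom}:{self.start}-{self.end}"
            )


_NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signal", "p", "q", "summit_offset",
]


def read_narrowpeak(path: str | Path) -> list[PeakRecord]:
    """Read a 10-column narrowPeak file into PeakRecords."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", header=None, names=_NARROWPEAK_COLS, comment="#",
        dtype={"chrom": str, "name": str, "strand": str},
    )
    if df.shape[1] != 10:
        raise ParseError(f"{path}: expected 10 narrowPeak columns")
    peaks = []
    for row in df.itertuples(index=False):
        try:
            peaks.append(
                PeakRecord(
                    chrom=row.chrom, start=int(row.start), end=int(row.end),
                    name=str(row.name), score=float(row.score),
                    strand=str(row.strand), signal=float(row.signal),
                    p=float(row.p), q=float(row.q),
                    summit_offset=int(row.summit_offset),
                )
            )
        except ValueError as e:
            raise ParseError(f"{path}: {e}") from e
    return peaks


def write_narrowpeak(peaks: list[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        p.chrom, p.start, p.end, p.name, p.score,
                        p.strand, p.signal, p.p, p.q, p.summit_offset,
                    )
                )
                + "\n"
            )


def extract_peak_sequences(
    peaks: list[PeakRecord], genome: SeqRecordSet
) -> SeqRecordSet:
    """Slice forward-strand peak sequences out of a genome.

    Identifiers encode ``chrom:start-end`` (half-open).  Unknown chromosomes
    or peaks running past the chromosome end raise :class:`CoordinateError`.
    """
    chrom_seqs = dict(genome.records)
    records = []
    seen: dict[str, int] = {}
    for p in peaks:
        if p.chrom not in chrom_seqs:
            raise CoordinateError(f"unknown chromosome {p.chrom!r}")
        seq = chrom_seqs[p.chrom]
        if p.end > len(seq):
            raise CoordinateError(
                f"peak {p.chrom}:{p.start}-{p.end} exceeds chromosome "
                f"length {len(seq)}"
            )
        ident = f"{p.chrom}:{p.start}-{p.end}"
        seen[ident] = seen.get(ident, 0) + 1
        if seen[ident] > 1:  # duplicate peak intervals stay addressable
            ident = f"{ident}#{seen[ident]}"
        records.append((ident, seq[p.start : p.end]))
    return SeqRecordSet(records)
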