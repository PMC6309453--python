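"""Degenerate binding-site patterns and probability-matrix consensus derivation.

Secondary-wall NAC transcription factors (VND, NST, SND clades) bind a family
of related cis-elements: the 11 bp TERE ``CTTNAAAGCNA``, the longer SNBE, and
the 13 bp VNS core ``C(G/T)TNNNNNNNA(A/C)G``.  This module provides:

* :class:`DegenerateMotif` — an ordered list of allowed-nucleotide sets with
  parsing/rendering, matching, reverse complement, variant enumeration and
  subsumption tests;
* :class:`ProbabilityMatrix` — a position probability matrix over A,C,G,T;
* the align / trim / average procedure that condenses several motif matrices
  (e.g. one per DAP-seq experiment) into a single consensus matrix, plus
  per-column information content in bits.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Canonical patterns from the secondary-wall NAC literature.
TERE = "CTTNAAAGCNA"
SNBE = "(T/A)NN(C/T)(T/C/G)TNNNNNNNA(A/C)GN(A/C/T)(A/T)"
VNS = "C(G/T)TNNNNNNNA(A/C)G"


class PatternError(ValueError):
    """Raised for malformed degenerate-pattern strings."""


@dataclass(frozen=True)
class DegenerateMotif:
    """An ordered degenerate nucleotide pattern.

    Each position is a non-empty frozenset of allowed bases.  The full set
    {A,C,G,T} renders as ``N``; multi-base subsets render as ``(X/Y)``.
    """

    name: str
    positions: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise PatternError("motif must have at least one position")
        for s in self.positions:
            if not s or not s <= set(ALPHABET):
                raise PatternError(f"illegal allowed-set {set(s)!r}")

    def __len__(self) -> int:
        return len(self.positions)

    def render(self) -> str:
        """Serialize back to the defining pattern string (lossless)."""
        out = []
        for s in self.positions:
            if len(s) == 4:
                out.append("N")
            elif len(s) == 1:
                out.append(next(iter(s)))
            else:
                out.append("(" + "/".join(b for b in ALPHABET if b in s) + ")")
        return "".join(out)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_pattern(text: str, name: str | None = None) -> DegenerateMotif:
    """Parse a degenerate-motif string such as ``C(G/T)TNNNNNNNA(A/C)G``.

    Accepts literals A/C/G/T, the wildcard N, and parenthesized slash groups.
    """
    positions: list[frozenset[str]] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c in ALPHABET:
            positions.append(frozenset(c))
            i += 1
        elif c == "N":
            positions.append(frozenset(ALPHABET))
            i += 1
        elif c == "(":
            j = text.find(")", i)
            if j < 0:
                raise PatternError(f"unbalanced parenthesis at offset {i} in {text!r}")
            bases = text[i + 1 : j].split("/")
            if not bases or any(b not in ALPHABET for b in bases):
                raise PatternError(f"illegal group {text[i:j+1]!r}")
            positions.append(frozenset(bases))
            i = j + 1
        else:
            raise PatternError(f"illegal character {c!r} at offset {i} in {text!r}")
    if not positions:
        raise PatternError("empty pattern")
    return DegenerateMotif(name or text, tuple(positions))


def matches(motif: DegenerateMotif, window: str) -> bool:
    """True iff every base of ``window`` lies in the corresponding allowed set.

    ``window`` must have the motif's length; any character outside A/C/G/T
    (including N) fails the position it occupies.
    """
    if len(window) != len(motif):
        raise ValueError(
            f"window length {len(window)} != motif length {len(motif)}"
        )
    return all(b in s for b, s in zip(window, motif.positions))


def reverse_complement(motif: DegenerateMotif) -> DegenerateMotif:
    """Set-wise reverse complement; VNS is its own reverse complement."""
    rc = tuple(
        frozenset(_COMPLEMENT[b] for b in s) for s in reversed(motif.positions)
    )
    return DegenerateMotif(motif.name + "_rc", rc)


def enumerate_variants(motif: DegenerateMotif, limit: int = 256) -> list[DegenerateMotif]:
    """Cartesian expansion of all non-N degenerate positions.

    N positions are kept as N (they are wildcards, not alternatives to be
    distinguished).  Variants come out in deterministic lexicographic order
    of the expanded positions and are pairwise disjoint as concrete patterns.
    """
    choices: list[list[frozenset[str]]] = []
    n_variants = 1
    for s in motif.positions:
        if len(s) == 4 or len(s) == 1:
            choices.append([s])
        else:
            opts = [frozenset(b) for b in ALPHABET if b in s]
            choices.append(opts)
            n_variants *= len(opts)
    if n_variants > limit:
        raise ValueError(f"expansion would produce {n_variants} variants (> {limit})")
    out = []
    for combo in itertools.product(*choices):
        v = DegenerateMotif("tmp", tuple(combo))
        out.append(DegenerateMotif(v.render(), tuple(combo)))
    return out


def pattern_subsumes(
    general: DegenerateMotif, specific: DegenerateMotif, offset: int = 0
) -> bool:
    """True iff ``specific`` is position-wise contained in ``general``.

    ``specific`` is aligned against ``general`` starting at ``offset``; the
    comparison runs over the overlap window and requires every allowed set of
    ``specific`` in that window to be a subset of the aligned set of
    ``general``.  E.g. the TERE's core is subsumed by the SNBE's internal
    CTTNNNNNNNA stretch.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    for i, s in enumerate(specific.positions):
        j = offset + i
        if j >= len(general):
            break
        if not s <= general.positions[j]:
            return False
    return True


@dataclass
class ProbabilityMatrix:
    """Position probability matrix: L columns of A,C,G,T probabilities."""

    probs: np.ndarray  # shape (L, 4), rows sum to 1
    name: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("matrix must have shape (L, 4)")
        if self.probs.shape[0] < 1:
            raise ValueError("matrix must have at least one column")
        if (self.probs < 0).any():
            raise ValueError("negative probability")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"column {bad} sums to {sums[bad]:.6f}, not 1")

    def __len__(self) -> int:
        return self.probs.shape[0]


def information_content(matrix: ProbabilityMatrix) -> list[float]:
    """Per-column information content, 2 + sum p*log2(p) bits, in [0, 2]."""
    out = []
    for col in matrix.probs:
        h = sum(p * math.log2(p) for p in col if p > 0)
        out.append(2.0 + h)
    return out


def _total_ic(probs: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, probs * np.log2(np.where(probs > 0, probs, 1)), 0.0)
    return float((2.0 + terms.sum(axis=1)).sum())


def _column_covariance_sum(a: np.ndarray, b: np.ndarray) -> float:
    """Summed per-column covariance between two (k, 4) probability blocks.

    Covariance rather than Pearson correlation, and the sum rather than a
    mean over columns: normalizing each 4-entry column pair to unit variance
    lets near-uniform noise columns contribute correlations of +/-1 and lets
    a short lucky overlap outscore the true alignment, whereas covariance is
    tiny for uninformative columns and large only where two informative
    columns agree.  Summing makes long consistent overlaps beat short
    spurious ones.
    """
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    return float((ac * bc).sum())


MIN_OVERLAP = 8


def align_matrices(
    matrices: list[ProbabilityMatrix], min_overlap: int = MIN_OVERLAP
) -> list[tuple[ProbabilityMatrix, int]]:
    """Place motif matrices on a common coordinate axis.

    A deterministic surrogate for manual alignment by nucleotide similarity:
    the matrix with the highest total information content seeds the axis at
    offset 0; every other matrix (in decreasing-IC order) is slid across all
    offsets that leave at least ``min_overlap`` overlapping columns with the
    running average, taking the offset with the highest summed per-column
    covariance (ties toward the smallest offset).  The returned offset of a
    matrix is the axis coordinate of its first column.

    Results are returned in the original input order.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices to align")
    for m in matrices:
        if len(m) < min_overlap:
            raise ValueError(
                f"matrix {m.name!r} has {len(m)} columns (< {min_overlap})"
            )
    order = sorted(range(len(matrices)), key=lambda i: -_total_ic(matrices[i].probs))
    seed_idx = order[0]
    offsets: dict[int, int] = {seed_idx: 0}
    # running average tracked as (sum, count) per axis coordinate
    axis: dict[int, tuple[np.ndarray, int]] = {
        j: (matrices[seed_idx].probs[j].copy(), 1) for j in range(len(matrices[seed_idx]))
    }
    for idx in order[1:]:
        probs = matrices[idx].probs
        lo, hi = min(axis), max(axis)
        best_offset, best_score = None, -np.inf
        for off in range(lo - len(probs) + min_overlap, hi - min_overlap + 2):
            coords = [off + j for j in range(len(probs)) if off + j in axis]
            if len(coords) < min_overlap:
                continue
            avg = np.array([axis[c][0] / axis[c][1] for c in coords])
            block = np.array([probs[c - off] for c in coords])
            score = _column_covariance_sum(block, avg)
            if score > best_score + 1e-12:
                best_score, best_offset = score, off
        assert best_offset is not None
        offsets[idx] = best_offset
        for j in range(len(probs)):
            c = best_offset + j
            if c in axis:
                s, n = axis[c]
                axis[c] = (s + probs[j], n + 1)
            else:
                axis[c] = (probs[j].copy(), 1)
    return [(matrices[i], offsets[i]) for i in range(len(matrices))]


def trim_and_average(
    aligned: list[tuple[ProbabilityMatrix, int]],
    target_length: int = 13,
    min_contributors: int = 2,
    name: str = "consensus",
) -> ProbabilityMatrix:
    """Average aligned matrices column-wise and trim to ``target_length``.

    Each axis position is the unweighted arithmetic mean of the columns of
    the matrices covering it, renormalized to sum 1.  Among all windows of
    ``target_length`` consecutive positions in which every column has at
    least ``min_contributors`` contributing matrices, the one maximizing the
    total information content of the averaged matrix is kept (leftmost on
    ties).
    """
    cover: dict[int, tuple[np.ndarray, int]] = {}
    for matrix, off in aligned:
        for j in range(len(matrix)):
            c = off + j
            if c in cover:
                s, n = cover[c]
                cover[c] = (s + matrix.probs[j], n + 1)
            else:
                cover[c] = (matrix.probs[j].copy(), 1)
    coords = sorted(cover)
    eligible = [c for c in coords if cover[c][1] >= min_contributors]
    best: tuple[float, int] | None = None
    for start in eligible:
        window = list(range(start, start + target_length))
        if not all(c in cover and cover[c][1] >= min_contributors for c in window):
            continue
        avg = np.array([cover[c][0] / cover[c][1] for c in window])
        avg = avg / avg.sum(axis=1, keepdims=True)
        ic = _total_ic(avg)
        if best is None or ic > best[0] + 1e-12:
            best = (ic, start)
    if best is None:
        raise ValueError(
            f"no {target_length}-column window with >= {min_contributors} "
            "contributing matrices per column"
        )
    start = best[1]
    avg = np.array([cover[c][0] / cover[c][1] for c in range(start, start + target_length)])
    avg = avg / avg.sum(axis=1, keepdims=True)
    return ProbabilityMatrix(avg, name=name)


def matrix_from_pattern(
    motif: DegenerateMotif, dominance: float = 0.91, name: str | None = None
) -> ProbabilityMatrix:
    """Build a probability matrix that concentrates mass on a pattern.

    Single-base positions receive ``dominance`` on the base and the
    remainder spread uniformly; multi-base positions split ``dominance``
    among the allowed bases; N positions are uniform.  Used as the default
    generating core for synthetic motif-file sets.
    """
    cols = []
    for s in motif.positions:
        if len(s) == 4:
            cols.append([0.25] * 4)
        else:
            inside = dominance / len(s)
            outside = (1.0 - dominance) / (4 - len(s))
            cols.append([inside if b in s else outside for b in ALPHABET])
    return ProbabilityMatrix(np.array(cols), name=name or motif.render())
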