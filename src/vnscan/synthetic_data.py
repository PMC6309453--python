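"""Deterministic synthetic fixtures for every pipeline stage.

Each generator emulates one of the study's external inputs so the whole
pipeline is testable without downloads:

* i.i.d. genomes of stated GC content with planted motif instances
  (stand-in for a reference assembly and DAP-seq peak sequences);
* MEME motif-file sets sharing a noisy 13-column core with random flanks
  (stand-in for per-TF DAP-seq motif files);
* promoter allele pairs with planted SNPs inside and outside binding sites
  (stand-in for sequenced promoter alleles, default preset: 540 bp
  reference, 16 substitutions, 1 single-base deletion, two planted TEREs of
  which one is disrupted at motif position 2);
* RIL genotype/expression tables with one planted cis-acting expression
  effect plus Gaussian noise (stand-in for a two-parent RIL mapping
  population).

One integer seed drives everything; each generator draws from its own
fixed substream (``default_rng([seed, stream_id])``) so adding a generator
never perturbs existing fixtures.  Identical configs give byte-identical
artifacts.  Planted windows replace background bases, keeping lengths
exact; every truth table is verified against the corresponding analysis
stage before being returned (generate -> analyze -> compare, closed loop).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .allele_compare import call_snps, global_align
from .eqtl_coexpr import RilDataset
from .io_formats import MemeMotifFile, SeqRecordSet
from .motif_model import (
    ALPHABET,
    TERE,
    VNS,
    DegenerateMotif,
    ProbabilityMatrix,
    matches,
    matrix_from_pattern,
    parse_pattern,
)
from .motif_scan import scan_sequence

_STREAM_GENOME = 1
_STREAM_MEME = 2
_STREAM_ALLELE = 3
_STREAM_RIL = 4


class PackingError(ValueError):
    """Planted features cannot be placed under the requested geometry."""


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list("ACGT")), size=length, p=p)


def _place_nonoverlapping(
    rng: np.random.Generator, genome_length: int, widths: list[int], tries: int = 200
) -> list[int]:
    if sum(widths) > genome_length:
        raise PackingError("planted instances exceed the genome length")
    for _ in range(tries):
        starts = [int(rng.integers(0, genome_length - w + 1)) for w in widths]
        intervals = sorted(zip(starts, widths))
        if all(
            intervals[i][0] + intervals[i][1] <= intervals[i + 1][0]
            for i in range(len(intervals) - 1)
        ):
            return starts
    raise PackingError(
        f"could not place {len(widths)} non-overlapping instances in "
        f"{genome_length} bp after {tries} attempts"
    )


def _concrete_instance(rng: np.random.Generator, motif: DegenerateMotif) -> str:
    return "".join(
        next(iter(s)) if len(s) == 1 else str(rng.choice(sorted(s)))
        for s in motif.positions
    )


@dataclass
class GenomeConfig:
    seed: int
    length: int = 100_000
    gc: float = 0.5
    planted_motifs: list[tuple[str, int]] = field(default_factory=list)
    chrom_name: str = "chr1"


def gen_genome(config: GenomeConfig) -> tuple[SeqRecordSet, pd.DataFrame]:
    """I.i.d. genome with planted motif instances and a verified truth table.

    The truth table lists every occurrence of each planted pattern found by
    the scanner — planted ones flagged ``planted=True``, incidental
    background matches ``planted=False``.
    """
    rng = _rng(config.seed, _STREAM_GENOME)
    seq = _random_seq(rng, config.length, config.gc)
    planted: list[tuple[int, str]] = []
    patterns = [
        (parse_pattern(p), count) for p, count in config.planted_motifs
    ]
    widths = [len(m) for m, count in patterns for _ in range(count)]
    flat = [m for m, count in patterns for _ in range(count)]
    starts = _place_nonoverlapping(rng, config.length, widths) if widths else []
    for motif, start in zip(flat, starts):
        inst = _concrete_instance(rng, motif)
        seq[start : start + len(motif)] = list(inst)
        planted.append((start, motif.render()))
    genome = SeqRecordSet([(config.chrom_name, "".join(seq))])
    planted_set = {(pos, pat) for pos, pat in planted}
    rows = []
    for motif, _ in patterns:
        for occ in scan_sequence(genome.records[0][1], motif, "forward"):
            rows.append(
                {
                    "chrom": config.chrom_name,
                    "position": occ.start,
                    "pattern": motif.render(),
                    "variant": occ.variant_name,
                    "planted": (occ.start, motif.render()) in planted_set,
                }
            )
    truth = pd.DataFrame(
        rows, columns=["chrom", "position", "pattern", "variant", "planted"]
    ).sort_values(["position", "pattern"], ignore_index=True)
    n_planted_found = int(truth["planted"].sum()) if len(truth) else 0
    assert n_planted_found == len(planted), "planted instance lost during generation"
    return genome, truth


#: DAP-seq experiment labels used to name synthetic motif files.
NAC_NAMES = ["VND1", "VND2", "VND3", "VND4", "VND6", "SND2", "SND3", "NST1"]


@dataclass
class MemeSetConfig:
    seed: int
    k_motifs: int = 8
    core: ProbabilityMatrix | None = None  # default: VNS-shaped 13-column core
    flank_max: int = 3
    dirichlet_concentration: float = 200.0

    def resolved_core(self) -> ProbabilityMatrix:
        return self.core if self.core is not None else matrix_from_pattern(
            parse_pattern(VNS), name="VNS-core"
        )


def gen_meme_set(
    config: MemeSetConfig,
) -> tuple[list[MemeMotifFile], ProbabilityMatrix, list[int]]:
    """Noisy copies of a shared core matrix with random uniform flanks.

    Each synthetic motif file perturbs the core column-wise with Dirichlet
    noise (column ~ Dirichlet(concentration * core_column)) and prepends /
    appends 0..flank_max columns drawn uniformly from the simplex.  Returns
    the motif files, the generating core, and the truth left-flank offsets.
    """
    core = config.resolved_core()
    if len(core) != 13:
        raise ValueError("core matrix must have 13 columns")
    rng = _rng(config.seed, _STREAM_MEME)
    files: list[MemeMotifFile] = []
    offsets: list[int] = []
    for k in range(config.k_motifs):
        name = NAC_NAMES[k] if k < len(NAC_NAMES) else f"TF{k+1}"
        left = int(rng.integers(0, config.flank_max + 1))
        right = int(rng.integers(0, config.flank_max + 1))
        cols = []
        for _ in range(left):
            cols.append(rng.dirichlet(np.ones(4)))
        for col in core.probs:
            alpha = np.maximum(config.dirichlet_concentration * col, 1e-9)
            cols.append(rng.dirichlet(alpha))
        for _ in range(right):
            cols.append(rng.dirichlet(np.ones(4)))
        files.append(
            MemeMotifFile(
                motif_name=name,
                matrix=ProbabilityMatrix(np.array(cols), name=name),
            )
        )
        offsets.append(left)
    return files, core, offsets


@dataclass
class AlleleConfig:
    seed: int
    length: int = 540
    n_substitutions: int = 16
    n_indels: int = 1
    n_planted_motifs: int = 2
    fraction_disrupting: float = 0.5
    motif: str = TERE
    disrupting_position: int = 2  # 1-based motif position hit by each disruptor
    gc: float = 0.4


@dataclass
class AlleleTruth:
    substitutions: list[int]  # ref offsets
    deletions: list[int]  # ref offsets of deleted bases
    planted_occurrences: list[tuple[int, str]]  # (ref start, window)
    disrupted: list[bool]  # parallel to planted_occurrences


def gen_allele_pair(
    config: AlleleConfig, max_tries: int = 200
) -> tuple[str, str, AlleleTruth]:
    """A promoter allele pair with planted, verifiable differences.

    The default preset reproduces the promoter-screen topology: a 540 bp
    reference, 16 substitutions, one single-base deletion (so the other
    allele is 539 bp), and two planted TERE instances of which one carries a
    substitution at motif position 2 that breaks the pattern.  The returned
    truth is verified internally: SNP calling on the pair recovers exactly
    the planted edits, and re-scanning the alternate allele confirms the
    disruption flags.
    """
    motif = parse_pattern(config.motif)
    L = len(motif)
    pos1 = config.disrupting_position
    if not (1 <= pos1 <= L) or len(motif.positions[pos1 - 1]) == 4:
        raise ValueError("disrupting_position must index a non-N motif position")
    # disrupting SNPs come out of the substitution budget
    n_disrupt = min(
        round(config.fraction_disrupting * config.n_planted_motifs),
        config.n_substitutions,
    )
    rng = _rng(config.seed, _STREAM_ALLELE)
    for _ in range(max_tries):
        out = _try_allele_pair(rng, config, motif, n_disrupt)
        if out is not None:
            return out
    raise PackingError(f"no valid allele pair after {max_tries} attempts")


def _try_allele_pair(rng, config: AlleleConfig, motif, n_disrupt):
    L = len(motif)
    seq = _random_seq(rng, config.length, config.gc)
    starts = _place_nonoverlapping(
        rng, config.length, [L] * config.n_planted_motifs
    )
    starts.sort()
    for s in starts:
        seq[s : s + L] = list(_concrete_instance(rng, motif))
    ref = "".join(seq)
    occs = scan_sequence(ref, motif, "both-dedup")
    if {(o.start, o.strand) for o in occs} != {(s, "+") for s in starts}:
        return None  # incidental occurrence or planted site destroyed
    in_motif = set()
    for s in starts:
        in_motif.update(range(s, s + L))
    alt = list(ref)
    sub_positions: list[int] = []
    disrupted_flags = [False] * config.n_planted_motifs
    for k in range(n_disrupt):
        s = starts[k]
        p = s + config.disrupting_position - 1
        allowed = motif.positions[config.disrupting_position - 1]
        choices = [b for b in ALPHABET if b not in allowed and b != ref[p]]
        if not choices:
            choices = [b for b in ALPHABET if b not in allowed]
        alt[p] = str(rng.choice(choices))
        sub_positions.append(p)
        disrupted_flags[k] = True
    n_free = config.n_substitutions - n_disrupt
    free = [i for i in range(config.length) if i not in in_motif]
    if len(free) < n_free + config.n_indels:
        raise PackingError("allele too short for the requested edits")
    picks = rng.choice(len(free), size=n_free + config.n_indels, replace=False)
    edit_sites = sorted(free[int(i)] for i in picks)
    sub_sites, del_sites = edit_sites[: n_free], edit_sites[n_free:]
    for p in sub_sites:
        alt[p] = str(rng.choice([b for b in ALPHABET if b != ref[p]]))
        sub_positions.append(p)
    for p in sorted(del_sites, reverse=True):
        del alt[p]
    alt_seq = "".join(alt)
    # closed-loop verification against the analysis stages
    aligned = global_align(ref, alt_seq)
    called = call_snps(*aligned)
    subs = sorted(s.ref_pos for s in called if s.kind == "substitution")
    dels = sorted(s.ref_pos for s in called if s.kind == "deletion")
    n_del_bases = sum(
        len(s.ref_base) for s in called if s.kind == "deletion"
    )
    if subs != sorted(sub_positions) or len(dels) != config.n_indels:
        return None
    if n_del_bases != config.n_indels:
        return None
    # surviving (non-disrupted) occurrences must still match on alt
    alt_occs = {
        (o.start, o.strand) for o in scan_sequence(alt_seq, motif, "both-dedup")
    }
    expected_surviving = sum(1 for f in disrupted_flags if not f)
    survivors = 0
    for idx, s in enumerate(starts):
        shift = sum(1 for d in del_sites if d < s)
        present = (s - shift, "+") in alt_occs
        if disrupted_flags[idx] and present:
            return None
        if not disrupted_flags[idx]:
            if not present:
                return None
            survivors += 1
    if survivors != expected_surviving or len(alt_occs) != expected_surviving:
        return None
    truth = AlleleTruth(
        substitutions=sorted(sub_positions),
        deletions=sorted(del_sites),
        planted_occurrences=[(s, ref[s : s + L]) for s in starts],
        disrupted=disrupted_flags,
    )
    return ref, alt_seq, truth


@dataclass
class RilConfig:
    seed: int
    n_lines: int = 160
    n_chromosomes: int = 5
    n_markers_per_chrom: int = 8
    cm_spacing: float = 10.0
    effect_size: float = 1.0  # in units of noise SD
    noise_sd: float = 1.0
    cis_marker_index: int = 20  # global marker index carrying the effect
    gene_name: str = "GOI"
    n_null_genes: int = 2
    bp_per_cm: int = 250_000


def gen_ril_population(config: RilConfig) -> tuple[RilDataset, dict]:
    """Two-parent RIL genotypes plus expression with one planted cis effect.

    Genotypes follow a Markov chain along each chromosome with switch
    probability given by the Haldane map function for the marker spacing,
    then are (by construction) fully homozygous 0/1.  Expression of the
    focal gene is intercept + effect * genotype(cis marker) + N(0, noise);
    the focal gene's annotated position is the cis marker's position, and
    ``n_null_genes`` pure-noise genes are annotated elsewhere.
    """
    if config.n_lines < 20:
        raise ValueError("need at least 20 lines")
    rng = _rng(config.seed, _STREAM_RIL)
    n_markers = config.n_chromosomes * config.n_markers_per_chrom
    if not (0 <= config.cis_marker_index < n_markers):
        raise ValueError("cis_marker_index out of range")
    r = 0.5 * (1.0 - np.exp(-2.0 * config.cm_spacing / 100.0))
    geno = np.empty((config.n_lines, n_markers), dtype=int)
    col = 0
    for _ in range(config.n_chromosomes):
        g = rng.random(config.n_lines) < 0.5
        geno[:, col] = g
        for _ in range(config.n_markers_per_chrom - 1):
            col += 1
            switch = rng.random(config.n_lines) < r
            g = np.logical_xor(g, switch)
            geno[:, col] = g
        col += 1
    markers = [f"m{k:03d}" for k in range(n_markers)]
    chroms, cms, bps = [], [], []
    for c in range(config.n_chromosomes):
        for j in range(config.n_markers_per_chrom):
            chroms.append(f"chr{c+1}")
            cms.append(j * config.cm_spacing)
            bps.append(int(j * config.cm_spacing * config.bp_per_cm) + 1)
    marker_positions = pd.DataFrame(
        {"chrom": chroms, "cM": cms, "bp": bps}, index=pd.Index(markers, name="marker")
    )
    lines = [f"RIL{i+1:03d}" for i in range(config.n_lines)]
    cis = config.cis_marker_index
    focal = (
        10.0
        + config.effect_size * config.noise_sd * geno[:, cis]
        + rng.normal(0.0, config.noise_sd, config.n_lines)
    )
    expr = {config.gene_name: focal}
    gene_rows = {
        config.gene_name: {
            "chrom": marker_positions.iloc[cis]["chrom"],
            "bp": int(marker_positions.iloc[cis]["bp"]),
        }
    }
    for g in range(config.n_null_genes):
        name = f"null{g+1}"
        expr[name] = 10.0 + rng.normal(0.0, config.noise_sd, config.n_lines)
        other_chrom = (int(marker_positions.iloc[cis]["chrom"][3:]) % config.n_chromosomes) + 1
        gene_rows[name] = {"chrom": f"chr{other_chrom}", "bp": 1000 + g}
    dataset = RilDataset(
        genotypes=pd.DataFrame(geno, index=lines, columns=markers),
        marker_positions=marker_positions,
        expression=pd.DataFrame(expr, index=lines),
        gene_positions=pd.DataFrame.from_dict(gene_rows, orient="index").rename_axis("gene"),
    )
    truth = {
        "cis_marker": markers[cis],
        "effect_size": config.effect_size * config.noise_sd,
        "gene": config.gene_name,
    }
    return dataset, truth
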