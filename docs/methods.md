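# Methods

This note records the models behind each `vnscan` stage, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical decisions taken where the design was genuinely open.

## Degenerate patterns and scanning

A degenerate motif is an ordered list of allowed-nucleotide sets: `N` is
{A,C,G,T}, a slash group like `(G/T)` is the listed pair, and a literal is a
singleton.  Matching is exact set membership per position — no log-odds
scores or p-value thresholds; a binding site either satisfies the pattern
or it does not.  Subject windows containing `N` never match (no ambiguity
expansion on the subject side), and every start offset is tested, so
overlapping occurrences are all reported.

The scanner compiles a pattern to a regular expression inside a lookahead
(to capture overlaps) and classifies each match into one of the pattern's
concrete variants (the Cartesian expansion of its non-`N` degenerate
positions; `N`s stay `N`).  A brute-force per-window oracle — independent
set-membership checks at every offset — backs the scanner in the test
suite.

**Strand convention.**  Variant counting is forward-strand-only by default.
The VNS element's variant set is closed under reverse complement
(`CTT..ACG` ↔ `CGT..AAG`; the other two variants are fixed points), so a
forward scan already represents sites on either strand, and scanning both
strands would double-count the self-palindromic variants.  For motifs
without this closure (e.g. the TERE), disruption annotation scans both
strands and deduplicates loci whose forward window also matches
(`both-dedup` mode).

**Percentages.**  A variant's percentage is its count divided by the summed
count across variants, × 100; unrounded percentages therefore always sum to
100.  Display rounding is one decimal, applied only at serialization.  For
sets of peak files, the summary percentage is the unweighted arithmetic
mean of per-file percentages (files with zero sites are excluded from the
mean with a warning), so the summary column need not sum to 100.

**Null model.**  Under an i.i.d. background with GC content *g*, the
per-window match probability is the product over positions of the summed
allowed-base probabilities with p(C)=p(G)=g/2.  For the VNS at g=0.5 this
is 1/1024, giving ≈977 expected sites per megabase — the calibration used
in the tests.

## Consensus derivation (align – trim – average)

Input is a set of position probability matrices (one per TF experiment)
believed to share a common core with uninformative flanks.  The procedure:

1. **Seed**: the matrix with the highest total information content anchors
   the common axis at offset 0.
2. **Align**: remaining matrices, in decreasing-IC order, are slid across
   every offset leaving ≥ 8 overlapping columns with the running
   columnwise average; the offset maximizing the **summed per-column
   covariance** between the matrix and the average is taken (ties to the
   smallest offset), and the matrix joins the running average.
3. **Trim + average**: every axis window of 13 consecutive columns in which
   each column is covered by ≥ 2 matrices is scored by the total IC of its
   renormalized columnwise mean; the best window (leftmost on ties) is the
   consensus.

The covariance score deserves a note.  A per-column Pearson correlation on
4-entry probability vectors is maximally noisy exactly where the data are
uninformative: two near-uniform columns (spacer positions, random flanks)
can correlate at ±1, so a short lucky overlap can outscore the true
alignment, and averaging per-column correlations dilutes the signal of the
few informative columns.  Covariance is near zero for uninformative columns
and large only where two informative columns agree, and summing (rather
than averaging) lets long consistent overlaps dominate short spurious ones.
On the standard synthetic fixture the covariance score recovers every
planted offset across 40 seeds, where the mean-correlation score misaligned
about half the seeds.

Averaging is unweighted across motif files (no weighting by peak counts),
and information content per column is 2 + Σ p·log₂p bits with 0·log₂0 = 0
and no small-sample correction.

## Allele comparison

Global alignment is Needleman–Wunsch with match +1, mismatch −1, gap open
−4, gap extend −1 (a length-L gap costs 4 + (L−1)), delegated to
Biopython's `PairwiseAligner`; the first optimal alignment is taken, which
is deterministic for a fixed Biopython version, and near-identical promoter
alleles have an essentially unique optimum.  SNP calling emits one
substitution per mismatch column and collapses maximal gap runs into single
indel records; reported "SNP counts" are substitutions only.

Fragment tiling divides [0, L) into n equal-length fragments labeled A, B,
C, … whose consecutive overlap is round(fragment_length × overlap_fraction),
with the last fragment shifted to end at L.  Defaults (n = 9, overlap 0.5)
emit nine overlapping fragments over a ~540 bp promoter — the geometry of a
fragment-by-fragment promoter binding screen, parameterized because real
screens derive their boundaries from primer positions.

Disruption annotation scans the reference allele, maps each occurrence
window through the alignment, and re-tests the degenerate pattern on the
mapped window (reverse-complemented first for minus-strand occurrences).
Windows overlapping an alignment gap are flagged disrupted with kind
`indel-overlap`.  Motif positions are reported 1-based from the motif's 5'
end on the occurrence's own strand.

## CAPS assay

The default enzyme follows the assay notation `CGTTAC|NN`: recognition
`CGTTACNN` including the two `N`s, cut offset 8 (after the `NN`), which
reproduces the 401 + 142 bp digest of a 543 bp amplicon carrying one site
at offset 393.  This notation differs from the canonical catalog definition
of BsrDI, so the enzyme is named `BsrDI-paper` and any
`name:RECOGNITION:offset` spec can be substituted.  Sites are found on both
strands; a reverse-strand site at forward interval [s, s+L) cuts the top
strand at s + L − offset.  Only top-strand cut positions define fragment
boundaries (agarose gels do not resolve 2-nt overhangs), cuts landing
exactly on an amplicon boundary are dropped with a warning, and fragment
lengths always sum to the amplicon length.  Primer matching is exact with
IUPAC degeneracy allowed in the primer; zero or multiple binding sites are
errors naming the primer.

Genotype calls: `cut` when the test allele yields strictly more fragments
than the reference; `uncut` when both run as a single indistinguishable
band; `ambiguous` otherwise, including both-digested patterns
indistinguishable within the gel tolerance (default 5 bp).

## eQTL machinery

The scan is single-marker least-squares regression at the markers (no
interval imputation): per marker, LOD = (n/2)·log₁₀(RSS₀/RSS₁) with RSS₀
from the intercept-only model, computed through the algebraically identical
−(n/2)·log₁₀(1−r²).  Missing genotypes are dropped pairwise (≤ 10% per
marker enforced); monomorphic markers score 0 with a warning.  The peak is
the leftmost argmax; the support interval is the contiguous same-chromosome
run around the peak with LOD ≥ peak − 1.5.  A peak is **cis** when the gene
lies on the peak chromosome within 1 Mb of the peak marker or inside the
support interval, **trans** otherwise; the 1.5-LOD drop and 1 Mb window are
conventional defaults, both configurable, since no principled value is
forced by the design.  Co-expression is pairwise Pearson r with the exact
two-sided t-transform p-value (n−2 df), pairwise-complete observations,
and an `ns` flag at α = 0.05 (configurable); zero-variance genes yield
missing correlations.

## Synthetic data: what it emulates, what it does not

All generators draw from numpy substreams keyed `[seed, stream_id]` with a
fixed id per generator, so fixtures are byte-stable under a seed and adding
a generator never shifts existing ones.

* **Genomes** are i.i.d. at a stated GC with motif instances planted at
  uniformly drawn non-overlapping positions (windows replaced, not
  inserted, keeping coordinates exact).  The truth table lists planted and
  incidental occurrences, verified by re-scanning.  Real genomes have
  repeats, isochores, and GC heterogeneity; a test passing here shows
  scanner correctness, not genomic realism.
* **Motif-file sets** perturb a fixed 13-column core column-wise with
  Dirichlet noise (column ~ Dir(c·p), concentration c = 200 by default —
  per-entry SD ≈ 0.035, so an 8-file average recovers the core within
  0.05) and add 0–3 uniform-simplex flank columns per side.  The default
  core concentrates 0.91 probability on each constrained pattern position.
  Real DAP-seq matrices differ in depth, width, and systematic bias;
  recovery here validates the align-trim-average machinery only.
* **Allele pairs** default to the promoter-screen topology: 540 bp
  reference, 16 substitutions, 1 single-base deletion, two planted TEREs
  with one disrupted at motif position 2.  Disrupting SNPs come out of the
  substitution budget.  Generation is rejection-sampled until the truth
  verifies end-to-end: SNP calling recovers exactly the planted edits and
  re-scanning confirms every disruption flag.
* **RIL populations** simulate two-parent genotypes as a Markov chain per
  chromosome with switch probability from the Haldane map function at the
  marker spacing (default 5 chromosomes × 8 markers, 10 cM, 1 cM ≈ 250 kb),
  fully homozygous; expression is intercept + effect·genotype(cis marker)
  + Gaussian noise (default effect 1 SD, noise SD 1, n = 160).  Residual
  heterozygosity, segregation distortion, and polygenic trans effects are
  not modeled, so these fixtures test the scan machinery, not mapping-study
  realism.  With these defaults a planted 1-SD effect is recovered at the
  true marker and classified cis in ≥95% of replicates, and null max-LOD
  exceeds 3 in well under 10% of runs.

## Numerical choices and degenerate inputs

Probability-matrix columns must sum to 1 within 1e-6 (MEME rows within
1e-3 at parse time, then renormalized).  Variant enumeration refuses
expansions beyond 256 variants.  Empty sequence sets produce a zero-count
table with percentages reported as 0 and a warning (0/0 is undefined).
Zero-length digest fragments are dropped with a warning.  Coordinates are
0-based half-open everywhere internally; 1-based positions appear only in
human-readable report fields (motif positions, TSV position columns).

## Known limitations

* Exact-match scanning cannot rank partial sites; there is no PWM-score
  scanning with thresholds.
* The alignment-based consensus derivation assumes one shared core; sets
  of matrices with genuinely different motifs will still be forced onto a
  common axis.
* Sequence-logo rendering is not included; the consensus TSV carries the
  per-column probabilities and information content from which a logo is a
  direct plot.
* The eQTL stage is deliberately minimal: no composite-interval mapping,
  permutation thresholds, or multi-trait models.
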