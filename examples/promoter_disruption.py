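"""Call SNPs between two promoter alleles and find broken binding sites.

A synthetic allele pair mimics a sequenced promoter comparison: 540 bp
reference, 16 substitutions, one single-base deletion, and two perfect TERE
elements (CTTNAAAGCNA) of which one carries a substitution at motif
position 2.  The pipeline aligns the alleles, calls the differences, tiles
the promoter into nine overlapping lettered fragments, and reports which
SNP breaks which motif position.
"""

from vnscan import (
    AlleleConfig,
    TERE,
    annotate_disruptions,
    call_snps,
    count_substitutions,
    gen_allele_pair,
    global_align,
    parse_pattern,
    tile_fragments,
)

ref, alt, truth = gen_allele_pair(AlleleConfig(seed=4))
snps = call_snps(*global_align(ref, alt))
print(f"alleles: {len(ref)} bp vs {len(alt)} bp")
print(f"called: {count_substitutions(snps)} substitutions, "
      f"{sum(1 for s in snps if s.kind != 'substitution')} indel(s)")

fragments = tile_fragments(len(ref), n_fragments=9, overlap_fraction=0.5)
report = annotate_disruptions(ref, alt, [parse_pattern(TERE, "TERE")], fragments)
for row in report.rows:
    status = "DISRUPTED" if row.disrupted else "intact"
    print(f"  TERE at {row.occurrence.start} ({row.occurrence.strand}) in "
          f"fragment(s) {','.join(row.fragments)}: {status}"
          + (f", SNP hits motif position(s) {row.motif_positions_hit}"
             if row.motif_positions_hit else ""))

print("\nA substitution at a constrained motif position (here position 2)")
print("abolishes the match — the in-silico analogue of a promoter allele")
print("losing transcription-factor binding — while SNPs at the motif's N")
print("positions or outside any occurrence leave binding sites intact.")
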