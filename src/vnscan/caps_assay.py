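"""In-silico CAPS genotyping: PCR amplicon location and restriction digest.

A CAPS (cleaved amplified polymorphic sequence) marker genotypes an allele
by PCR followed by allele-specific restriction digestion: one allele carries
a recognition site inside the amplicon and is cleaved into shorter
fragments, the other remains undigested.  The default enzyme here follows
the assay description CGTTAC|NN — recognition CGTTACNN with the cut placed
after the two N bases (offset 8) — which on a 543 bp promoter amplicon with
one site yields 401 + 142 bp fragments for the cut allele.  Only top-strand
cut positions determine fragment boundaries (a gel cannot resolve 2 nt
overhangs).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .motif_model import DegenerateMotif, parse_pattern
from .motif_scan import revcomp_seq

logger = logging.getLogger(__name__)

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: degenerate recognition site plus cut offset.

    ``cut_offset`` counts bases 3' of the recognition-site start on the
    strand carrying the site; the cut falls between offset-1 and offset.
    """

    name: str
    recognition: DegenerateMotif
    cut_offset: int

    def __post_init__(self) -> None:
        if not (0 <= self.cut_offset <= len(self.recognition) + 10):
            raise ValueError(f"cut_offset {self.cut_offset} out of range")

    @classmethod
    def from_string(cls, text: str) -> "EnzymeSpec":
        """Parse ``name:RECOGNITION:offset``, e.g. ``BsrDI-paper:CGTTACNN:8``."""
        parts = text.split(":")
        if len(parts) != 3:
            raise ValueError(f"enzyme spec {text!r} is not name:site:offset")
        return cls(parts[0], parse_pattern(parts[1], name=parts[0]), int(parts[2]))


#: The assay's enzyme as printed: recognition CGTTACNN, cut after the NN.
BSRDI_PAPER = EnzymeSpec("BsrDI-paper", parse_pattern("CGTTACNN", "BsrDI-paper"), 8)


class PrimerError(ValueError):
    """Primer missing from, or ambiguous on, the template."""


def _primer_regex(primer: str) -> re.Pattern[str]:
    parts = []
    for c in primer.upper():
        if c not in IUPAC:
            raise ValueError(f"illegal primer base {c!r}")
        opts = IUPAC[c]
        parts.append(c if len(opts) == 1 else "[" + opts + "]")
    return re.compile("(?=(" + "".join(parts) + "))")


def _sole_match(template: str, primer: str, label: str) -> int:
    hits = [m.start() for m in _primer_regex(primer).finditer(template)]
    if not hits:
        raise PrimerError(f"{label} primer {primer!r} not found on template")
    if len(hits) > 1:
        raise PrimerError(
            f"{label} primer {primer!r} binds {len(hits)} times (ambiguous)"
        )
    return hits[0]


def find_amplicon(
    template: str, fwd_primer: str, rev_primer: str
) -> tuple[int, int, str]:
    """Locate the PCR product defined by a primer pair on a template.

    The forward primer must match the forward strand exactly once; the
    reverse primer's reverse complement must match once, downstream of the
    forward site.  Returns (start, end, amplicon) with the amplicon spanning
    both primers inclusive (0-based half-open on the template).  IUPAC
    degenerate bases are allowed in primers; matching is otherwise exact.
    """
    template = template.upper()
    if len(fwd_primer) < 15 or len(rev_primer) < 15:
        raise ValueError("primers must be at least 15 bp")
    f = _sole_match(template, fwd_primer, "forward")
    rev_rc = rev_primer.upper().translate(_IUPAC_COMP)[::-1]
    r = _sole_match(template, rev_rc, "reverse")
    end = r + len(rev_rc)
    if end <= f:
        raise PrimerError("reverse primer binds upstream of the forward primer")
    return f, end, template[f:end]


@dataclass
class DigestResult:
    """Predicted digestion: cut positions and fragment lengths."""

    amplicon_length: int
    cut_positions: list[int]  # sorted, 0-based, strictly inside the amplicon
    fragment_lengths: list[int]  # sorted descending; sums to amplicon_length


def digest(amplicon: str, enzyme: EnzymeSpec = BSRDI_PAPER) -> DigestResult:
    """Cut an amplicon at every recognition site on either strand.

    Reverse-strand sites are mapped to top-strand coordinates
    (cut = site_start + site_length - cut_offset).  Cuts landing exactly at
    the amplicon boundary would create zero-length fragments; they are
    dropped with a warning.
    """
    amplicon = amplicon.upper()
    L = len(enzyme.recognition)
    site_re = _primer_regex(_motif_to_iupac(enzyme.recognition))
    cuts = set()
    for m in site_re.finditer(amplicon):
        cuts.add(m.start() + enzyme.cut_offset)
    rc_site = _motif_to_iupac(enzyme.recognition).translate(_IUPAC_COMP)[::-1]
    for m in _primer_regex(rc_site).finditer(amplicon):
        cuts.add(m.start() + L - enzyme.cut_offset)
    kept = sorted(c for c in cuts if 0 < c < len(amplicon))
    if len(kept) < len(cuts):
        logger.warning(
            "%d cut position(s) at the amplicon boundary dropped "
            "(zero-length fragment)", len(cuts) - len(kept),
        )
    bounds = [0] + kept + [len(amplicon)]
    fragments = sorted(
        (b - a for a, b in zip(bounds, bounds[1:])), reverse=True
    )
    return DigestResult(len(amplicon), kept, fragments)


def _motif_to_iupac(motif: DegenerateMotif) -> str:
    rev = {frozenset(v): k for k, v in IUPAC.items()}
    return "".join(rev[frozenset(s)] for s in motif.positions)


def genotype_call(
    digest_ref: DigestResult, digest_alt: DigestResult, tolerance_bp: int = 5
) -> str:
    """Call the alternate allele cut / uncut / ambiguous against a reference.

    "cut" when the alternate allele shows strictly more fragments than the
    reference; "uncut" when both alleles run as a single undigested band of
    indistinguishable length; "ambiguous" otherwise (including both alleles
    digested into fragment sets indistinguishable at gel resolution,
    ``tolerance_bp``).
    """
    ref_frags, alt_frags = digest_ref.fragment_lengths, digest_alt.fragment_lengths
    if len(alt_frags) > len(ref_frags):
        return "cut"
    same_sets = len(ref_frags) == len(alt_frags) and all(
        abs(a - b) <= tolerance_bp for a, b in zip(ref_frags, alt_frags)
    )
    if same_sets and len(ref_frags) == 1:
        return "uncut"
    return "ambiguous"
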