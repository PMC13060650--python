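"""Methylation-sensitive restriction enzymes and IUPAC site scanning.

MSREs cut their recognition site only when the contained CpG is unmethylated,
so a CpG is assayable by MSRE digestion only if some enzyme's recognition
site overlaps the CpG dinucleotide. Recognition sequences use the IUPAC
ambiguity alphabet and are scanned on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass

from .containers import CpGContext, ValidationError

# standard IUPAC nucleotide ambiguity codes
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def expand_iupac(pattern: str) -> set[str]:
    """All concrete ACGT sequences matching an IUPAC pattern."""
    seqs = [""]
    for ch in pattern:
        seqs = [s + b for s in seqs for b in IUPAC[ch]]
    return set(seqs)


@dataclass(frozen=True)
class Enzyme:
    name: str
    recognition: str

    def __post_init__(self) -> None:
        site = self.recognition.upper().replace("^", "")
        if not site:
            raise ValidationError(f"{self.name}: empty recognition sequence")
        if set(site) - set(IUPAC):
            raise ValidationError(f"{self.name}: non-IUPAC recognition sequence")
        if not any("CG" in s for s in expand_iupac(site)):
            raise ValidationError(f"{self.name}: recognition site contains no CpG")
        object.__setattr__(self, "recognition", site)


@dataclass(frozen=True)
class EnzymeSet:
    enzymes: tuple[Enzyme, ...]

    def __post_init__(self) -> None:
        if not self.enzymes:
            raise ValidationError("enzyme set is empty")

    def __iter__(self):
        return iter(self.enzymes)

    @classmethod
    def from_pairs(cls, pairs) -> "EnzymeSet":
        return cls(tuple(Enzyme(n, s) for n, s in pairs))


#: Four MSREs commonly combined for CpG-dense digestion assays. The set is a
#: default only; analyses can supply their own via configuration.
DEFAULT_ENZYMES = EnzymeSet.from_pairs(
    [
        ("AciI", "CCGC"),
        ("HinP1I", "GCGC"),
        ("Hpy99I", "CGWCG"),
        ("HpyCH4IV", "ACGT"),
    ]
)


def _matches_at(window: str, start: int, pattern: str) -> bool:
    """IUPAC match of pattern at window[start:]; N in the window never matches."""
    for i, ch in enumerate(pattern):
        base = window[start + i]
        if base == "N" or base not in IUPAC[ch]:
            return False
    return True


def find_site_hits(sequence: str, enzymes: EnzymeSet) -> list[tuple[str, int, int]]:
    """All (enzyme name, start, end) half-open spans where a recognition site
    occurs on either strand of ``sequence`` (coordinates on the given strand).
    """
    seq = sequence.upper()
    hits = []
    for enz in enzymes:
        for pat in (enz.recognition, reverse_complement(enz.recognition)):
            L = len(pat)
            for s in range(len(seq) - L + 1):
                if _matches_at(seq, s, pat):
                    hits.append((enz.name, s, s + L))
    return hits


def msre_site_overlap(ctx: CpGContext, enzymes: EnzymeSet = DEFAULT_ENZYMES) -> bool:
    """True iff some enzyme recognition site overlaps the CpG dinucleotide.

    Overlap means the site span intersects the two bases at
    ``[ctx.offset, ctx.offset + 2)``.
    """
    lo, hi = ctx.offset, ctx.offset + 2
    for _, s, e in find_site_hits(ctx.sequence, enzymes):
        if s < hi and e > lo:
            return True
    return False
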