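"""DNA helpers: reverse complement, Hamming distance, IUPAC codes.

N (and any IUPAC ambiguity code in the *subject* sequence) counts as a
mismatch against a concrete base — wildcard matching of ambiguous subject
bases is deliberately disallowed so that degenerate sequence can never
silently satisfy a consensus.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# IUPAC code -> set of concrete bases it stands for (pattern side only)
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC ambiguity codes are complemented too."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Positionwise mismatch count between equal-length concrete sequences.

    Any position where either base is not one of ACGT counts as a mismatch.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    acgt = frozenset("ACGT")
    return sum(
        1
        for x, y in zip(a.upper(), b.upper())
        if x != y or x not in acgt
    )


def iupac_match(base: str, code: str) -> bool:
    """Does concrete ``base`` satisfy IUPAC ``code``?  Non-ACGT subject
    bases never match."""
    if code not in IUPAC:
        raise ValueError(f"invalid IUPAC code {code!r}")
    return base in IUPAC[code] and base in "ACGT"


def validate_iupac(pattern: str) -> None:
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}")
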