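"""Small RNA-sequence helpers shared across modules.

Internal alphabet is RNA {A, C, G, U}; DNA input is converted on read
(see :mod:`cernapipe.io_formats`).
"""

from __future__ import annotations

RNA_ALPHABET = frozenset("ACGU")

# IUPAC nucleotide codes accepted on input (before T->U canonicalization).
IUPAC_CODES = frozenset("ACGTUNRYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")

#: Watson-Crick pairs over the RNA alphabet.
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})

#: G:U wobble pairs (allowed in duplex energetics, never in seed-class calls).
GU_PAIRS = frozenset({("G", "U"), ("U", "G")})


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_wc(a: str, b: str) -> bool:
    return (a, b) in WC_PAIRS


def pairs(a: str, b: str) -> bool:
    """True for Watson-Crick or G:U wobble."""
    return (a, b) in WC_PAIRS or (a, b) in GU_PAIRS


def canonicalize_rna(seq: str) -> str:
    """Uppercase and convert T->U."""
    return seq.upper().replace("T", "U")


def validate_rna(seq: str, *, name: str = "sequence") -> None:
    """Raise ValueError with the offending position for non-ACGU characters."""
    for i, ch in enumerate(seq):
        if ch not in RNA_ALPHABET:
            raise ValueError(
                f"invalid character {ch!r} at position {i} in {name}: "
                "expected RNA over {A,C,G,U}"
            )
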