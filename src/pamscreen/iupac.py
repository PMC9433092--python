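"""Standard IUPAC degenerate nucleotide codes.

The 15 symbols map to nonempty subsets of {A, C, G, T}; ``N`` is any base,
``R`` purines, ``Y`` pyrimidines, ``V`` = A/C/G, and so on. Consensus PAMs
such as N4CC or N4GATT are strings over this alphabet.
"""

from __future__ import annotations

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_BASES_TO_SYMBOL: dict[frozenset[str], str] = {v: k for k, v in IUPAC_CODES.items()}

DNA_BASES = "ACGT"


def iupac_match(symbol: str, base: str) -> bool:
    """Return True iff ``base`` is one of the bases denoted by ``symbol``."""
    if symbol not in IUPAC_CODES:
        raise ValueError(f"unknown IUPAC symbol: {symbol!r}")
    if base not in IUPAC_CODES or len(IUPAC_CODES[base]) != 1:
        raise ValueError(f"not a concrete DNA base: {base!r}")
    return base in IUPAC_CODES[symbol]


def symbol_for_bases(bases) -> str:
    """Return the IUPAC symbol whose base set is exactly ``bases``."""
    key = frozenset(bases)
    try:
        return _BASES_TO_SYMBOL[key]
    except KeyError:
        raise ValueError(f"no IUPAC symbol for base set {sorted(key)}") from None


def pam_matches(consensus: str, pam: str) -> bool:
    """Positionwise match of a concrete PAM against a degenerate consensus."""
    if len(consensus) != len(pam):
        raise ValueError(
            f"length mismatch: consensus {len(consensus)} vs PAM {len(pam)}"
        )
    return all(iupac_match(s, b) for s, b in zip(consensus, pam))
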