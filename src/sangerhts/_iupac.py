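"""IUPAC nucleotide ambiguity-code tables shared by base calling and alignment."""

from __future__ import annotations

from Bio.Data.IUPACData import ambiguous_dna_values

#: IUPAC code (upper case) -> frozenset of plain bases it denotes, e.g. "M" -> {A, C}.
CODE_TO_BASES: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items()
}

#: frozenset of plain bases -> IUPAC code, e.g. {A, C} -> "M".
BASES_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in CODE_TO_BASES.items()}

PLAIN_BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(PLAIN_BASES)}


def is_plain(seq: str) -> bool:
    """True if *seq* contains only A/C/G/T."""
    return all(c in BASE_INDEX for c in seq)


def bases_of(code: str) -> frozenset[str]:
    """Base set denoted by a single IUPAC character (case-insensitive)."""
    try:
        return CODE_TO_BASES[code.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def code_for(bases: frozenset[str] | set[str]) -> str:
    """IUPAC character for a nonempty set of plain bases."""
    try:
        return BASES_TO_CODE[frozenset(bases)]
    except KeyError:
        raise ValueError(f"no IUPAC code for base set {sorted(bases)}") from None
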