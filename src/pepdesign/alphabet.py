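"""The canonical 20-letter amino-acid alphabet and residue-code normalization.

The index order is frozen: alanine, cysteine, aspartate, glutamate,
phenylalanine, glycine, histidine, isoleucine, lysine, leucine, methionine,
asparagine, proline, glutamine, arginine, serine, threonine, valine,
tryptophan, tyrosine — i.e. alphabetical in one-letter codes.  Every array in
the package that is indexed by residue type uses this order.
"""
from __future__ import annotations

from .errors import InputError

#: Frozen canonical ordering of the 20 natural amino acids (one-letter codes).
AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}

ONE_TO_THREE = {one: three for three, one in THREE_TO_ONE.items()}

_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


def normalize_residue(code: str) -> str:
    """Return the one-letter code for a 1- or 3-letter residue code.

    Raises :class:`InputError` for anything outside the canonical 20.
    """
    c = str(code).strip().upper()
    if len(c) == 1 and c in _INDEX:
        return c
    if len(c) == 3 and c in THREE_TO_ONE:
        return THREE_TO_ONE[c]
    raise InputError(f"unknown residue code: {code!r}")


def aa_index(code: str) -> int:
    """Canonical row index (0-19) of a residue given in 1- or 3-letter code."""
    return _INDEX[normalize_residue(code)]


def validate_alphabet(alphabet: str) -> str:
    """Validate a (possibly reduced) alphabet: unique letters drawn from AA_ORDER.

    Reduced alphabets are used to make exhaustive-enumeration tests cheap; the
    production default is the full 20 letters.
    """
    letters = [normalize_residue(a) for a in alphabet]
    if len(set(letters)) != len(letters):
        raise InputError(f"alphabet has repeated letters: {alphabet!r}")
    if len(letters) < 1:
        raise InputError("alphabet must contain at least one letter")
    return "".join(letters)
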