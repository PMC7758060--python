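"""Residue alphabet shared across the package.

Sequences are strings over the 20 standard amino acids plus 'X' (unknown).
Internally residues are encoded as small integers indexing this alphabet.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
ALPHABET_SIZE = len(ALPHABET)

_CODE = {c: i for i, c in enumerate(ALPHABET)}


def encode(seq: str) -> np.ndarray:
    """Encode a residue-string as an int8 array; raise on foreign symbols."""
    try:
        return np.array([_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(
            f"symbol {exc.args[0]!r} not in alphabet {ALPHABET!r}"
        ) from None


def decode(codes) -> str:
    return "".join(ALPHABET[int(c)] for c in codes)


def is_valid(seq: str) -> bool:
    return all(c in _CODE for c in seq)
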