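"""The 20-letter amino-acid alphabet and fast string <-> integer encoding."""

from __future__ import annotations

import numpy as np

from .errors import AlphabetError

#: Canonical residues in alphabetical one-letter order. Column order of every PSSM.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
N_RESIDUES = len(AMINO_ACIDS)

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# byte-value -> residue index lookup (255 marks a non-canonical byte)
_BYTE_TO_INDEX = np.full(256, 255, dtype=np.uint8)
for _aa, _i in AA_INDEX.items():
    _BYTE_TO_INDEX[ord(_aa)] = _i

_INDEX_TO_BYTE = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


def encode(peptide: str) -> np.ndarray:
    """Encode a peptide string as an array of residue indices (0..19)."""
    raw = np.frombuffer(peptide.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _BYTE_TO_INDEX[raw]
    if (codes == 255).any():
        bad = sorted({c for c in peptide if c not in AA_INDEX})
        raise AlphabetError(f"non-canonical residue(s) {bad!r} in peptide {peptide!r}")
    return codes


def encode_many(peptides, length: int) -> np.ndarray:
    """Encode equal-length peptides into an (n, length) index matrix."""
    joined = "".join(peptides)
    codes = encode(joined)
    if codes.size != length * len(list(peptides)):
        raise ValueError("peptides do not all have the stated length")
    return codes.reshape(-1, length)


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _INDEX_TO_BYTE[np.asarray(codes, dtype=np.intp)].tobytes().decode("ascii")
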