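"""The 20-letter amino-acid alphabet and substitution-matrix helpers.

Every encoding in this package indexes amino acids by their position in
:data:`AMINO_ACIDS` (alphabetical one-letter order). Vectors carry a 21st
dimension reserved for the placeholder/unknown symbol used when a short
peptide leaves a core slot empty.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

#: Fixed alphabetical ordering of the 20 standard amino acids.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: index of each one-letter code in :data:`AMINO_ACIDS`
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

N_AMINO_ACIDS = 20

#: number of core positions a peptide is aligned to
N_CORE = 9

#: vector width per residue in flat encodings: 20 amino acids + placeholder
VECTOR_DIM = 21


def validate_peptide(peptide: str, min_len: int = 8, max_len: int = 11) -> str:
    """Uppercase and validate a peptide string.

    Raises ``ValueError`` naming the first offending character or the
    offending length.
    """
    pep = peptide.strip().upper()
    if not (min_len <= len(pep) <= max_len):
        raise ValueError(
            f"peptide {pep!r} has length {len(pep)}, expected {min_len}-{max_len}"
        )
    for pos, ch in enumerate(pep):
        if ch not in AA_INDEX:
            raise ValueError(f"invalid amino-acid letter {ch!r} at position {pos + 1} in {pep!r}")
    return pep


def _blosum62_rows() -> np.ndarray:
    """BLOSUM62 scores as a (20, 21) float array in AMINO_ACIDS order.

    Column 21 (the placeholder symbol) is zero.
    """
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((N_AMINO_ACIDS, VECTOR_DIM), dtype=float)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = mat[a, b]
    return out


BLOSUM62_ROWS: np.ndarray = _blosum62_rows()
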