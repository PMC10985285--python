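"""Degenerate encoding: the 20 x 9 x 21 image-like array (ILA).

The ILA interlocks an allele's structural contact information with the
peptide's identity in one tensor:

* axis 0 (height 20): the 20 amino-acid types, alphabetical order;
* axis 1 (width 9): the 9 core positions a peptide is aligned to;
* axis 2 (depth 21): channel 0 is the binary *contact channel* — entry
  (h, j) is 1 iff the allele's pseudo sequence has a residue of type h
  structurally contacting core position j — and channels 1-20 are *peptide
  channels*: channel c carries ``hit`` (0.90) in column j when the core
  residue at j is amino acid c, else ``miss`` (0.05), broadcast over the
  height axis.

Peptides of length 8-11 are aligned to the 9 core slots by middle
insertion/deletion (:func:`map_to_core`). Flat baseline encodings
(one-hot / BLOSUM62 per-residue vectors over pseudo + core residues) are
provided for ablation comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .alphabet import (
    AA_INDEX,
    AMINO_ACIDS,
    BLOSUM62_ROWS,
    N_AMINO_ACIDS,
    N_CORE,
    VECTOR_DIM,
    validate_peptide,
)
from .pseudoseq import PseudoSequence

HIT_VALUE = 0.90
MISS_VALUE = 0.05

ILA_SHAPE = (N_AMINO_ACIDS, N_CORE, VECTOR_DIM)  # (20, 9, 21)

BASELINE_SCHEMES = ("blosum62", "onehot")


@dataclass(frozen=True)
class CoreAlignment:
    """Alignment of a peptide onto the 9 core slots.

    ``slots[j]`` is the 0-based peptide index aligned to core position
    j+1, or ``None`` for a placeholder slot (8-mers only).
    """

    peptide: str
    slots: tuple[Optional[int], ...]

    def __post_init__(self) -> None:
        if len(self.slots) != N_CORE:
            raise ValueError(f"core alignment needs exactly {N_CORE} slots")
        used = [s for s in self.slots if s is not None]
        if any(b <= a for a, b in zip(used, used[1:])):
            raise ValueError("peptide indices must be strictly increasing")


def map_to_core(peptide: str) -> CoreAlignment:
    """Deterministic middle insertion/deletion alignment to 9 core slots.

    9-mers map by identity. An 8-mer gets a placeholder at slot 5. 10- and
    11-mers drop the middle residue(s) (peptide positions 5, resp. 5-6)
    from the core window; the anchor-bearing termini are preserved.
    """
    pep = validate_peptide(peptide)
    n = len(pep)
    idx = list(range(n))
    if n == 9:
        slots: list[Optional[int]] = idx
    elif n == 8:
        slots = idx[:4] + [None] + idx[4:]
    elif n == 10:
        slots = idx[:4] + idx[5:]
    else:  # 11
        slots = idx[:4] + idx[6:]
    return CoreAlignment(peptide=pep, slots=tuple(slots))


def build_allele_contact_matrix(
    pseudo: PseudoSequence,
    position_to_core: Mapping[int, frozenset[int] | set[int]],
    spec_positions: tuple[int, ...],
) -> np.ndarray:
    """Binary 20 x 9 contact-channel matrix for one allele.

    Entry (h, j) is 1 iff some spec position p whose pseudo residue has
    amino-acid type h contacts core position j+1 under the consensus map.
    """
    if len(pseudo.residues) != len(spec_positions):
        raise ValueError(
            f"pseudo sequence length {len(pseudo.residues)} != spec length {len(spec_positions)}"
        )
    missing = [p for p in spec_positions if p not in position_to_core]
    if missing:
        raise ValueError(f"spec positions {missing} absent from position_to_core map")
    mat = np.zeros((N_AMINO_ACIDS, N_CORE), dtype=float)
    for letter, pos in zip(pseudo.residues, spec_positions):
        h = AA_INDEX[letter]
        for j in position_to_core[pos]:
            mat[h, j - 1] = 1.0
    if not mat.any():
        raise ValueError(f"allele {pseudo.allele_name} has no contacts")
    return mat


def encode_peptide_channels(
    core: CoreAlignment, hit: float = HIT_VALUE, miss: float = MISS_VALUE
) -> np.ndarray:
    """The 20 peptide channels as a (20, 9, 20) stack.

    Channel c holds ``hit`` at every (row, column j) entry where core slot
    j carries a residue of type c; everything else — including every
    channel of a placeholder slot — holds ``miss``.
    """
    out = np.full((N_AMINO_ACIDS, N_CORE, N_AMINO_ACIDS), miss, dtype=float)
    for j, s in enumerate(core.slots):
        if s is None:
            continue
        c = AA_INDEX[core.peptide[s]]
        out[:, j, c] = hit
    return out


def encode(
    peptide: str,
    allele_matrix: np.ndarray,
    hit: float = HIT_VALUE,
    miss: float = MISS_VALUE,
) -> np.ndarray:
    """Build the full 20 x 9 x 21 ILA for one peptide-allele pair."""
    if allele_matrix.shape != (N_AMINO_ACIDS, N_CORE):
        raise ValueError(f"allele matrix must be {(N_AMINO_ACIDS, N_CORE)}, got {allele_matrix.shape}")
    ila = np.empty(ILA_SHAPE, dtype=float)
    ila[:, :, 0] = allele_matrix
    ila[:, :, 1:] = encode_peptide_channels(map_to_core(peptide), hit=hit, miss=miss)
    return ila


def decode_peptide(ila: np.ndarray, hit: float = HIT_VALUE) -> str:
    """Recover a 9-mer peptide from the peptide channels of an ILA.

    Placeholder columns (no channel at ``hit``) decode to ``-`` so 8-mers
    round-trip through their alignment.
    """
    letters = []
    for j in range(N_CORE):
        col = ila[0, j, 1:]
        c = int(np.argmax(col))
        letters.append(AMINO_ACIDS[c] if np.isclose(col[c], hit) else "-")
    return "".join(letters)


def encode_baseline(peptide: str, pseudo: PseudoSequence, scheme: str = "blosum62") -> np.ndarray:
    """Flat baseline encoding: per-residue 21-dim vectors, pseudo then core.

    ``onehot`` puts a 1 in the residue's alphabet column; ``blosum62`` uses
    the residue's BLOSUM62 row (placeholder column zero). Placeholder core
    slots encode as zero vectors. Output length is 21 * (len(pseudo) + 9).
    """
    if scheme not in BASELINE_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; valid schemes: {BASELINE_SCHEMES}")
    core = map_to_core(peptide)
    residues: list[Optional[str]] = list(pseudo.residues)
    residues += [None if s is None else core.peptide[s] for s in core.slots]
    rows = np.zeros((len(residues), VECTOR_DIM), dtype=float)
    for i, r in enumerate(residues):
        if r is None:
            continue
        if scheme == "onehot":
            rows[i, AA_INDEX[r]] = 1.0
        else:
            rows[i] = BLOSUM62_ROWS[AA_INDEX[r]]
    return rows.ravel()


def encode_batch(
    peptides: list[str],
    allele_matrices: list[np.ndarray],
    hit: float = HIT_VALUE,
    miss: float = MISS_VALUE,
) -> np.ndarray:
    """Stack ILAs for aligned lists of peptides and allele matrices."""
    if len(peptides) != len(allele_matrices):
        raise ValueError("peptides and allele matrices must align")
    return np.stack([encode(p, m, hit=hit, miss=miss) for p, m in zip(peptides, allele_matrices)])
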