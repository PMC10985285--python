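"""MHC-I pseudo-sequence derivation from peptide-MHC structures.

A *pseudo sequence* is the ordered subset of MHC alpha-chain residues
observed to contact bound peptides in crystal structures (any atom pair
within a distance cutoff, 4.0 angstrom by default). Conditioning a
pan-specific predictor on this compact allele representation lets one model
cover many alleles.

This module derives contact assignments from PDB files, aggregates them
into a :class:`PseudoSequenceSpec` with a consensus position-to-core map,
and ships the published preset position lists used by NetMHCpan-style and
MHCflurry-style encoders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .alphabet import AA_INDEX, N_CORE

logger = logging.getLogger(__name__)

#: Published 34-residue peptide-contacting position list (mature-chain,
#: 1-based numbering) used by NetMHCpan-style pseudo sequences.
NETMHCPAN_34_POSITIONS: tuple[int, ...] = (
    7, 9, 24, 45, 59, 62, 63, 66, 67, 69, 70, 73, 74, 76, 77, 80, 81, 84,
    95, 97, 99, 114, 116, 118, 143, 147, 150, 152, 156, 158, 159, 163, 167, 171,
)

#: MHCflurry-style variant: the same 34 positions plus three extras.
MHCFLURRY_EXTRA_POSITIONS: tuple[int, ...] = (91, 102, 199)

DEFAULT_CONTACT_CUTOFF = 4.0  # angstrom, over any atom pair


@dataclass(frozen=True)
class PseudoSequenceSpec:
    """Named, strictly ascending list of 1-based MHC residue positions."""

    name: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("a pseudo-sequence spec needs at least one position")
        if any(p < 1 for p in self.positions):
            raise ValueError("residue positions are 1-based and must be >= 1")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("spec positions must be strictly ascending with no duplicates")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class ContactAssignment:
    """Map from MHC residue position to the set of contacted core positions.

    Keys are 1-based mature-chain positions; values are nonempty frozensets
    of core positions in 1..9. Residues with no contact are absent.
    """

    contacts: Mapping[int, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, cores in self.contacts.items():
            if pos < 1:
                raise ValueError(f"residue position {pos} must be >= 1")
            if not cores:
                raise ValueError(f"residue {pos} maps to an empty core set")
            bad = [j for j in cores if not 1 <= j <= N_CORE]
            if bad:
                raise ValueError(f"core positions {bad} outside 1..{N_CORE}")

    def positions(self) -> tuple[int, ...]:
        return tuple(sorted(self.contacts))

    def __len__(self) -> int:
        return len(self.contacts)


@dataclass(frozen=True)
class AlleleSequenceRecord:
    allele_name: str
    sequence: str

    def __post_init__(self) -> None:
        bad = [c for c in self.sequence if c not in AA_INDEX]
        if bad:
            raise ValueError(f"allele {self.allele_name}: invalid letters {sorted(set(bad))}")


@dataclass(frozen=True)
class PseudoSequence:
    """One letter per spec position, extracted from an allele sequence."""

    allele_name: str
    residues: str
    spec_name: str


class StructureError(ValueError):
    """A structure violates the parsing/filtering rules."""


@dataclass
class ChainResidues:
    """Residues of one polymer chain with their atom coordinates.

    Residues are renumbered sequentially 1..N from the first observed
    residue (mature-chain convention); author PDB numbering is discarded.
    """

    chain_id: str
    letters: str
    coords: list[np.ndarray]  # one (n_atoms, 3) array per residue

    def __len__(self) -> int:
        return len(self.letters)


def _extract_chain(chain) -> ChainResidues:
    letters: list[str] = []
    coords: list[np.ndarray] = []
    for res in chain:
        if res.id[0] != " ":  # heteroatoms / waters
            continue
        name = res.get_resname().strip()
        one = protein_letters_3to1.get(name)
        if one is None or one not in AA_INDEX:
            raise StructureError(f"undefined amino acid {name!r} in chain {chain.id}")
        letters.append(one)
        xyz = np.array([a.coord for a in res.get_atoms()], dtype=float)
        coords.append(xyz)
    return ChainResidues(chain_id=chain.id, letters="".join(letters), coords=coords)


def parse_structure(
    path: str | Path, require_9mer: bool = True
) -> tuple[ChainResidues, ChainResidues]:
    """Split a peptide-MHC PDB file into (mhc_chain, peptide_chain).

    Only the first model is read; heteroatoms and waters are excluded. The
    peptide is the unique polymer chain of length 8-11 (ties broken by chain
    id); the MHC chain is the longest remaining chain. Complexes whose
    peptide is not a 9-mer are rejected when ``require_9mer`` is set, since
    only 9-mer complexes contribute to spec derivation.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("pmhc", str(path))
    model = next(iter(structure))
    chains = sorted((_extract_chain(c) for c in model), key=lambda c: c.chain_id)
    chains = [c for c in chains if len(c) > 0]
    if len(chains) < 2:
        raise StructureError(f"{path}: need at least two polymer chains")

    candidates = [c for c in chains if 8 <= len(c) <= 11]
    if not candidates:
        raise StructureError(f"{path}: no peptide chain (no chain of length 8-11)")
    peptide = candidates[0]
    if require_9mer and len(peptide) != 9:
        raise StructureError(f"{path}: non-9-mer peptide (length {len(peptide)})")
    rest = [c for c in chains if c.chain_id != peptide.chain_id]
    mhc = max(rest, key=len)
    return mhc, peptide


def compute_contact_assignment(
    mhc_chain: ChainResidues,
    peptide_chain: ChainResidues,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ContactAssignment:
    """Contacts between MHC residues and peptide core positions.

    MHC residue ``r`` contacts core position ``j`` iff the minimum
    Euclidean distance over all atom pairs (any atom of ``r``, any atom of
    peptide residue ``j``) is at most ``cutoff``. Residues without
    coordinates are skipped with a warning.
    """
    if len(mhc_chain) == 0 or len(peptide_chain) == 0:
        raise ValueError("both chains must be nonempty")
    contacts: dict[int, frozenset[int]] = {}
    for ridx, ratoms in enumerate(mhc_chain.coords, start=1):
        if ratoms.size == 0:
            logger.warning("MHC residue %d has no coordinates; skipped", ridx)
            continue
        hit: set[int] = set()
        for j, patoms in enumerate(peptide_chain.coords, start=1):
            if patoms.size == 0:
                logger.warning("peptide residue %d has no coordinates; skipped", j)
                continue
            d2 = np.sum((ratoms[:, None, :] - patoms[None, :, :]) ** 2, axis=-1)
            if d2.min() <= cutoff * cutoff:
                hit.add(j)
        if hit:
            contacts[ridx] = frozenset(hit)
    return ContactAssignment(contacts)


def aggregate_spec(
    assignments: Sequence[ContactAssignment],
    min_support: int = 1,
    name: str = "derived",
) -> tuple[PseudoSequenceSpec, dict[int, frozenset[int]]]:
    """Aggregate per-structure contacts into a spec and a consensus map.

    A position enters the spec if it contacts *any* core position in at
    least ``min_support`` structures; the consensus map retains, for each
    such position, the core positions individually supported in at least
    ``min_support`` structures (falling back to the position's best-supported
    core when none reaches the threshold on its own).
    """
    if not assignments:
        raise ValueError("cannot aggregate an empty collection of assignments")
    pos_support: dict[int, int] = {}
    core_support: dict[int, dict[int, int]] = {}
    for a in assignments:
        for pos, cores in a.contacts.items():
            pos_support[pos] = pos_support.get(pos, 0) + 1
            per = core_support.setdefault(pos, {})
            for j in cores:
                per[j] = per.get(j, 0) + 1
    kept = sorted(p for p, n in pos_support.items() if n >= min_support)
    if not kept:
        raise ValueError(f"no supported positions at min_support={min_support}")
    consensus: dict[int, frozenset[int]] = {}
    for p in kept:
        per = core_support[p]
        strong = frozenset(j for j, n in per.items() if n >= min_support)
        if not strong:
            best = max(per.values())
            strong = frozenset(j for j, n in per.items() if n == best)
        consensus[p] = strong
    return PseudoSequenceSpec(name=name, positions=tuple(kept)), consensus


def builtin_spec(name: str) -> PseudoSequenceSpec:
    """Return a published preset position list by name.

    ``netmhcpan34`` is the 34-residue peptide-contacting list;
    ``mhcflurry37`` adds positions 91, 102 and 199.
    """
    presets = {
        "netmhcpan34": NETMHCPAN_34_POSITIONS,
        "mhcflurry37": tuple(sorted(NETMHCPAN_34_POSITIONS + MHCFLURRY_EXTRA_POSITIONS)),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; valid presets: {sorted(presets)}")
    return PseudoSequenceSpec(name=name, positions=presets[name])


def extract_pseudo_sequence(
    allele: AlleleSequenceRecord, spec: PseudoSequenceSpec
) -> PseudoSequence:
    """Pick the spec's positions (1-based) out of the allele sequence."""
    for p in spec.positions:
        if p > len(allele.sequence):
            raise ValueError(
                f"allele {allele.allele_name}: sequence length {len(allele.sequence)} "
                f"does not cover spec position {p}"
            )
    residues = "".join(allele.sequence[p - 1] for p in spec.positions)
    return PseudoSequence(allele_name=allele.allele_name, residues=residues, spec_name=spec.name)


# ---------------------------------------------------------------------------
# io

def write_spec(spec: PseudoSequenceSpec, path: str | Path) -> None:
    """Two-column text: name, comma-separated positions."""
    Path(path).write_text(f"{spec.name}\t{','.join(map(str, spec.positions))}\n")


def read_spec(path: str | Path) -> PseudoSequenceSpec:
    line = Path(path).read_text().strip().splitlines()[0]
    name, positions = line.split("\t")
    return PseudoSequenceSpec(name=name, positions=tuple(int(p) for p in positions.split(",")))


def read_allele_fasta(path: str | Path) -> list[AlleleSequenceRecord]:
    """Read MHC alpha-chain sequences from FASTA; record id is the allele name."""
    return [
        AlleleSequenceRecord(allele_name=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
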