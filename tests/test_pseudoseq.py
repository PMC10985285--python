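"""Pseudo-sequence derivation: structures, contacts, aggregation, presets."""

import numpy as np
import pytest

from degenmhc.pseudoseq import (
    AlleleSequenceRecord,
    ChainResidues,
    ContactAssignment,
    PseudoSequenceSpec,
    StructureError,
    aggregate_spec,
    builtin_spec,
    compute_contact_assignment,
    extract_pseudo_sequence,
    parse_structure,
    read_spec,
    write_spec,
)
from degenmhc.synthetic import write_structure_fixture

from conftest import random_assignment


def chain_from_points(letters, points):
    """One residue per letter; each residue's atoms given as a list of xyz."""
    return ChainResidues(chain_id="X", letters=letters,
                         coords=[np.asarray(p, dtype=float).reshape(-1, 3) for p in points])


class TestParseStructure:
    def test_toy_fixture_assigns_chains_by_length(self, tmp_path, toy_assignment):
        path = tmp_path / "toy.pdb"
        write_structure_fixture(toy_assignment, path, mhc_length=30)
        mhc, pep = parse_structure(path)
        assert len(pep) == 9
        assert len(mhc) == 30

    def test_non_9mer_peptide_rejected(self, tmp_path):
        path = tmp_path / "bad.pdb"
        text = write_structure_fixture(ContactAssignment({}), path)
        # extend the peptide chain to 10 residues
        extra = text.replace("END", "").rstrip().splitlines()
        tenth = [l for l in extra if " CA " in l and " B " in l][-1]
        bumped = tenth.replace("B   9", "B  10").replace("180.000   0.000",
                                                         "200.000   0.000")
        lines = [l for l in extra if l != "TER"] + [bumped, "TER", "END"]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(StructureError, match="non-9-mer"):
            parse_structure(path)
        # ... but acceptable when the 9-mer filter is relaxed
        mhc, pep = parse_structure(path, require_9mer=False)
        assert len(pep) == 10

    def test_undefined_amino_acid_rejected(self, tmp_path, toy_assignment):
        path = tmp_path / "unk.pdb"
        text = write_structure_fixture(toy_assignment, path)
        path.write_text(text.replace("GLY B   5", "UNK B   5"))
        with pytest.raises(StructureError, match="undefined amino acid"):
            parse_structure(path)

    def test_no_peptide_chain(self, tmp_path):
        path = tmp_path / "nopep.pdb"
        text = write_structure_fixture(ContactAssignment({}), path)
        # drop the whole B chain
        lines = [l for l in text.splitlines() if " B " not in l]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(StructureError, match="no peptide chain|two polymer"):
            parse_structure(path)


class TestContactAssignmentComputation:
    def test_single_atom_below_cutoff(self):
        mhc = chain_from_points("A", [[(0.0, 0.0, 0.0)]])
        pep = chain_from_points("GGGGGGGGG",
                                [[(100.0 + 10 * j, 0, 0)] for j in range(4)]
                                + [[(3.0, 0.0, 0.0)]]
                                + [[(200.0 + 10 * j, 0, 0)] for j in range(4)])
        got = compute_contact_assignment(mhc, pep, cutoff=4.0)
        assert dict(got.contacts) == {1: frozenset({5})}

    def test_same_geometry_above_cutoff_is_empty(self):
        mhc = chain_from_points("A", [[(0.0, 0.0, 0.0)]])
        pep = chain_from_points("GGGGGGGGG", [[(10.0 + 100 * j, 0, 0)] for j in range(9)])
        got = compute_contact_assignment(mhc, pep, cutoff=4.0)
        assert dict(got.contacts) == {}

    def test_matches_brute_force_all_pairs_scan(self, rng):
        n_mhc, n_pep = 8, 9
        mhc_pts = [rng.normal(scale=6.0, size=(int(rng.integers(1, 5)), 3)) for _ in range(n_mhc)]
        pep_pts = [rng.normal(scale=6.0, size=(int(rng.integers(1, 5)), 3)) for _ in range(n_pep)]
        mhc = chain_from_points("A" * n_mhc, mhc_pts)
        pep = chain_from_points("G" * n_pep, pep_pts)
        cutoff = 5.0
        expected = {}
        for r, ra in enumerate(mhc_pts, start=1):
            cores = set()
            for j, pa in enumerate(pep_pts, start=1):
                hit = False
                for a in ra:
                    for b in pa:
                        if np.sqrt(((a - b) ** 2).sum()) <= cutoff:
                            hit = True
                if hit:
                    cores.add(j)
            if cores:
                expected[r] = frozenset(cores)
        got = compute_contact_assignment(mhc, pep, cutoff=cutoff)
        assert dict(got.contacts) == expected

    def test_rigid_motion_invariance_and_cutoff_monotonicity(self, rng):
        pts_m = [rng.normal(scale=4.0, size=(3, 3)) for _ in range(5)]
        pts_p = [rng.normal(scale=4.0, size=(2, 3)) for _ in range(9)]
        mhc = chain_from_points("AAAAA", pts_m)
        pep = chain_from_points("G" * 9, pts_p)
        base = compute_contact_assignment(mhc, pep, cutoff=4.0)
        # joint rigid rotation + translation preserves all pairwise distances
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        t = np.array([5.0, -3.0, 2.0])
        mhc2 = chain_from_points("AAAAA", [p @ R.T + t for p in pts_m])
        pep2 = chain_from_points("G" * 9, [p @ R.T + t for p in pts_p])
        moved = compute_contact_assignment(mhc2, pep2, cutoff=4.0)
        assert dict(moved.contacts) == dict(base.contacts)
        wider = compute_contact_assignment(mhc, pep, cutoff=7.0)
        for pos, cores in base.contacts.items():
            assert cores <= wider.contacts.get(pos, frozenset())


class TestAggregateSpec:
    def test_single_assignment_union(self):
        spec, consensus = aggregate_spec(
            [ContactAssignment({7: frozenset({2}), 9: frozenset({2, 3})})]
        )
        assert spec.positions == (7, 9)
        assert consensus == {7: frozenset({2}), 9: frozenset({2, 3})}

    def test_min_support_two_with_disjoint_assignments_errors(self):
        a = ContactAssignment({7: frozenset({2})})
        b = ContactAssignment({9: frozenset({3})})
        with pytest.raises(ValueError, match="no supported positions"):
            aggregate_spec([a, b], min_support=2)

    def test_empty_collection_errors(self):
        with pytest.raises(ValueError):
            aggregate_spec([])

    def test_matches_counting_oracle(self, rng):
        assignments = [random_assignment(rng) for _ in range(10)]
        min_support = 3
        support = {}
        for a in assignments:
            for p in a.contacts:
                support[p] = support.get(p, 0) + 1
        expected_positions = tuple(sorted(p for p, n in support.items() if n >= min_support))
        if expected_positions:
            spec, _ = aggregate_spec(assignments, min_support=min_support)
            assert spec.positions == expected_positions
        else:
            with pytest.raises(ValueError):
                aggregate_spec(assignments, min_support=min_support)

    def test_min_support_one_equals_union(self, rng):
        assignments = [random_assignment(rng) for _ in range(6)]
        spec, _ = aggregate_spec(assignments, min_support=1)
        union = sorted({p for a in assignments for p in a.contacts})
        assert list(spec.positions) == union


class TestBuiltinSpecs:
    def test_netmhcpan34_positions(self):
        spec = builtin_spec("netmhcpan34")
        assert len(spec.positions) == 34
        assert spec.positions[:3] == (7, 9, 24)
        assert spec.positions[-1] == 171

    def test_mhcflurry37_adds_three_positions(self):
        extra = set(builtin_spec("mhcflurry37").positions) - set(builtin_spec("netmhcpan34").positions)
        assert extra == {91, 102, 199}

    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(ValueError, match="netmhcpan34"):
            builtin_spec("mixmhcpred")


class TestExtractPseudoSequence:
    def test_direct_indexing(self):
        allele = AlleleSequenceRecord("X", "ACDEFGHIK")
        spec = PseudoSequenceSpec("s", (1, 3, 5))
        assert extract_pseudo_sequence(allele, spec).residues == "ADF"

    def test_too_short_sequence_names_position(self):
        allele = AlleleSequenceRecord("X", "A" * 100)
        spec = PseudoSequenceSpec("s", (1, 171))
        with pytest.raises(ValueError, match="171"):
            extract_pseudo_sequence(allele, spec)

    def test_matches_character_pick_oracle_and_length(self, rng):
        from degenmhc.alphabet import AMINO_ACIDS

        letters = np.array(list(AMINO_ACIDS))
        seq = "".join(letters[rng.integers(0, 20, size=200)])
        positions = tuple(sorted(rng.choice(np.arange(1, 201), size=15, replace=False).tolist()))
        spec = PseudoSequenceSpec("r", positions)
        ps = extract_pseudo_sequence(AlleleSequenceRecord("X", seq), spec)
        assert ps.residues == "".join(seq[p - 1] for p in positions)
        assert len(ps.residues) == len(spec.positions)


def test_spec_text_round_trip(tmp_path):
    spec = builtin_spec("mhcflurry37")
    path = tmp_path / "spec.txt"
    write_spec(spec, path)
    assert read_spec(path) == spec
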