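import pytest

from protacdec import (
    Candidate,
    apply_filters,
    bidirectional_decompose,
    categorize_failure,
    decompose_pass,
    find_matches,
    library_from_smiles,
    standardize_molecule,
    subtract_fragment,
)
from protacdec.decompose import MatchSite, PassTrace
from protacdec.errors import ContractError, DegenerateSubtractionError, InputError


class TestFindMatches:
    def test_pyridine_in_p1(self, p1_smiles, p1_libs):
        parent = standardize_molecule(p1_smiles)
        sites = find_matches(parent, p1_libs[0].fragments[0])
        assert len(sites) == 1
        assert len(sites[0].atom_indices) == 6
        assert len(sites[0].cut_bonds) == 1

    def test_piperidine_in_p1(self, p1_smiles, p1_libs):
        parent = standardize_molecule(p1_smiles)
        sites = find_matches(parent, p1_libs[1].fragments[0])
        assert len(sites) == 1
        assert len(sites[0].cut_bonds) == 1

    def test_no_embedding(self, p1_libs):
        benzene = standardize_molecule("c1ccccc1")
        assert find_matches(benzene, p1_libs[0].fragments[0]) == []

    def test_fragment_equal_to_parent_rejected(self):
        parent = standardize_molecule("c1ccncc1")
        frag = library_from_smiles(["c1ccncc1"], "warhead").fragments[0]
        assert find_matches(parent, frag) == []

    def test_symmetric_embeddings_collapse_to_atom_sets(self):
        # benzene embeds into toluene's ring with 12 automorphic maps, one atom set
        parent = standardize_molecule("Cc1ccccc1")
        frag = library_from_smiles(["c1ccccc1"], "warhead").fragments[0]
        assert len(find_matches(parent, frag)) == 1

    def test_cut_bonds_cross_the_match_boundary(self, p1_smiles, p1_libs):
        parent = standardize_molecule(p1_smiles)
        (site,) = find_matches(parent, p1_libs[0].fragments[0])
        inside = set(site.atom_indices)
        for a, b in site.cut_bonds:
            assert a in inside and b not in inside


class TestSubtract:
    def test_pyridine_subtraction_leaves_chain_piperidine(self, p1_smiles, p1_libs):
        parent = standardize_molecule(p1_smiles)
        (site,) = find_matches(parent, p1_libs[0].fragments[0])
        remainders = subtract_fragment(parent, site)
        assert len(remainders) == 1
        assert remainders[0].smiles_canonical == standardize_molecule("CCCN1CCCCC1").smiles_canonical
        assert remainders[0].n_heavy == 9

    def test_internal_atom_subtraction_disconnects(self, p1_smiles):
        parent = standardize_molecule(p1_smiles)
        # atom 7 is the middle chain carbon of the canonical P1 numbering
        chain = [
            a.GetIdx()
            for a in parent.mol.GetAtoms()
            if a.GetAtomicNum() == 6 and not a.GetIsAromatic() and not a.IsInRing()
        ]
        mid = chain[1]
        site = MatchSite(fragment_id="x", atom_indices=(mid,), cut_bonds=())
        assert len(subtract_fragment(parent, site)) == 2

    def test_degenerate_subtraction(self, p1_smiles):
        parent = standardize_molecule(p1_smiles)
        site = MatchSite(
            fragment_id="x", atom_indices=tuple(range(parent.n_heavy)), cut_bonds=()
        )
        with pytest.raises(DegenerateSubtractionError):
            subtract_fragment(parent, site)


class TestPass:
    def test_single_candidate(self, p1_smiles, p1_libs):
        parent = standardize_molecule(p1_smiles)
        cands, trace = decompose_pass(parent, *p1_libs)
        assert len(cands) == 1
        assert cands[0].linker_components == ("CCC",)
        assert trace.first_matched and trace.second_matched

    def test_no_first_match_stage(self, p1_smiles, p1_libs):
        parent = standardize_molecule(p1_smiles)
        naphthalene = library_from_smiles(["c1ccc2ccccc2c1"], "warhead")
        cands, trace = decompose_pass(parent, naphthalene, p1_libs[1])
        assert cands == [] and not trace.first_matched

    def test_boundary_ambiguity_gives_two_candidates(self, p1_smiles, p1_libs):
        parent = standardize_molecule(p1_smiles)
        warheads = library_from_smiles(["c1ccncc1", "Cc1ccccn1"], "warhead")
        cands, _ = decompose_pass(parent, warheads, p1_libs[1])
        assert sorted(c.linker_smiles for c in cands) == ["CC", "CCC"]

    def test_empty_library_rejected(self, p1_smiles, p1_libs):
        from protacdec.library import FragmentLibrary

        parent = standardize_molecule(p1_smiles)
        empty = FragmentLibrary(role="warhead", fragments=())
        with pytest.raises(InputError):
            decompose_pass(parent, empty, p1_libs[1])


class TestBidirectional:
    def test_p1_solved(self, p1_smiles, p1_libs):
        report = bidirectional_decompose(p1_smiles, *p1_libs)
        assert report.solved
        assert [s.triple for s in report.solutions] == [
            ("c1ccncc1", "CCC", "C1CCNCC1")
        ]
        sol = report.solutions[0]
        assert sol.found_in_pass_a and sol.found_in_pass_b

    def test_missing_warhead(self, p1_smiles, p1_libs):
        warheads = library_from_smiles(["c1ccc2ccccc2c1"], "warhead")
        report = bidirectional_decompose(p1_smiles, warheads, p1_libs[1])
        assert report.status == "failed"
        assert report.failure_category == "warhead_not_found"
        assert report.solutions == ()

    def test_two_solutions_atom_conserving(self, p1_smiles, p1_libs):
        parent = standardize_molecule(p1_smiles)
        warheads = library_from_smiles(["c1ccncc1", "Cc1ccccn1"], "warhead")
        report = bidirectional_decompose(p1_smiles, warheads, p1_libs[1])
        assert report.solved and len(report.solutions) == 2
        for s in report.solutions:
            assert s.warhead.n_heavy + s.n_heavy_linker + s.e3_ligand.n_heavy == parent.n_heavy
            assert s.warhead.n_rings + s.n_rings_linker + s.e3_ligand.n_rings == parent.n_rings
        # stable ordering: larger warhead (methylpyridine) first
        assert report.solutions[0].warhead.n_heavy == 7

    def test_directional_symmetry(self, p1_smiles):
        fwd = bidirectional_decompose(
            p1_smiles,
            library_from_smiles(["c1ccncc1"], "warhead"),
            library_from_smiles(["C1CCNCC1"], "e3_ligand"),
        )
        swapped = bidirectional_decompose(
            p1_smiles,
            library_from_smiles(["C1CCNCC1"], "warhead"),
            library_from_smiles(["c1ccncc1"], "e3_ligand"),
        )
        assert fwd.solved and swapped.solved
        f, s = fwd.solutions[0], swapped.solutions[0]
        assert f.warhead.smiles_canonical == s.e3_ligand.smiles_canonical
        assert f.e3_ligand.smiles_canonical == s.warhead.smiles_canonical
        assert f.linker_smiles == s.linker_smiles

    def test_determinism(self, p1_smiles, p1_libs):
        a = bidirectional_decompose(p1_smiles, *p1_libs)
        b = bidirectional_decompose(p1_smiles, *p1_libs)
        assert a == b

    def test_library_growth_is_monotone(self, p1_smiles, p1_libs):
        base = bidirectional_decompose(p1_smiles, *p1_libs)
        grown = library_from_smiles(["c1ccncc1", "c1ccc2ccccc2c1"], "warhead")
        after = bidirectional_decompose(p1_smiles, grown, p1_libs[1])
        assert {s.triple for s in base.solutions} <= {s.triple for s in after.solutions}

    def test_unparseable_parent_reported_not_skipped(self, p1_libs):
        report = bidirectional_decompose("not_a_smiles", *p1_libs)
        assert report.status == "input_error"
        assert report.failure_category == "input_error"


class TestFilters:
    def _candidate(self, p1_smiles, p1_libs):
        parent = standardize_molecule(p1_smiles)
        cands, _ = decompose_pass(parent, *p1_libs)
        return parent, cands[0]

    def test_valid_candidate_passes(self, p1_smiles, p1_libs):
        parent, cand = self._candidate(p1_smiles, p1_libs)
        res = apply_filters(cand, parent)
        assert res.passed and res.violations == ()

    def test_disconnected_linker_violation(self, p1_smiles, p1_libs):
        parent, cand = self._candidate(p1_smiles, p1_libs)
        broken = Candidate(
            warhead=cand.warhead,
            e3_ligand=cand.e3_ligand,
            warhead_atoms=cand.warhead_atoms,
            e3_atoms=cand.e3_atoms,
            linker_atoms=cand.linker_atoms,
            linker_components=("C", "CC"),
        )
        res = apply_filters(broken, parent)
        assert not res.passed and "multiple_linker_fragments" in res.violations

    def test_double_counted_atom_breaks_conservation(self, p1_smiles, p1_libs):
        # shrink the linker by one atom as if warhead and E3 overlapped on it
        parent, cand = self._candidate(p1_smiles, p1_libs)
        overlapping = Candidate(
            warhead=cand.warhead,
            e3_ligand=cand.e3_ligand,
            warhead_atoms=cand.warhead_atoms,
            e3_atoms=cand.e3_atoms,
            linker_atoms=cand.linker_atoms[:-1],
            linker_components=("CC",),
        )
        res = apply_filters(overlapping, parent)
        assert not res.passed and "heavy_atom_discrepancy" in res.violations


class TestCategorize:
    def test_priority_warhead_first(self):
        a = PassTrace(first_role="warhead", first_matched=False, second_matched=False)
        b = PassTrace(first_role="e3_ligand", first_matched=False, second_matched=False)
        assert categorize_failure(a, b, []) == "warhead_not_found"

    def test_e3_after_warhead(self):
        a = PassTrace(first_role="warhead", first_matched=True, second_matched=False)
        b = PassTrace(first_role="e3_ligand", first_matched=False, second_matched=False)
        assert categorize_failure(a, b, []) == "e3_not_found"

    def test_contract_violation_when_solutions_exist(self, p1_smiles, p1_libs):
        parent = standardize_molecule(p1_smiles)
        cands, trace = decompose_pass(parent, *p1_libs)
        good = [(cands[0], apply_filters(cands[0], parent))]
        with pytest.raises(ContractError):
            categorize_failure(trace, trace, good)
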