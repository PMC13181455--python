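import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from protacdec import (
    adversarial_cases,
    assemble_protac,
    bidirectional_decompose,
    library_from_smiles,
    linker_series,
    random_corpus,
    standardize_molecule,
)
from protacdec.errors import AssemblyError
from protacdec.synthetic import DEFAULT_E3_LIGANDS, DEFAULT_LINKERS, DEFAULT_WARHEADS, attachment_sites


def _site_adjacent_to_nitrogen(smiles):
    mol = standardize_molecule(smiles).mol
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 6 and atom.GetTotalNumHs() >= 1 and any(
            n.GetAtomicNum() == 7 for n in atom.GetNeighbors()
        ):
            return atom.GetIdx()
    raise AssertionError("no such site")


def test_hand_assembled_p1(p1_smiles):
    pyridine, propane, piperidine = "c1ccncc1", "CCC", "C1CCNCC1"
    wh_site = _site_adjacent_to_nitrogen(pyridine)
    n_idx = next(
        a.GetIdx()
        for a in standardize_molecule(piperidine).mol.GetAtoms()
        if a.GetAtomicNum() == 7
    )
    syn = assemble_protac(pyridine, propane, piperidine, wh_site, (0, 2), n_idx)
    assert syn.protac_smiles == standardize_molecule(p1_smiles).smiles_canonical


def test_one_atom_linker_boundary_case():
    syn = assemble_protac("c1ccccc1", "C", "C1CCNCC1", 0, (0, 0), 0)
    parts = sum(
        standardize_molecule(s).n_heavy for s in syn.truth
    )
    assert parts == standardize_molecule(syn.protac_smiles).n_heavy


def test_site_without_hydrogen_rejected():
    with pytest.raises(AssemblyError):
        assemble_protac("CC(C)(C)C", "CCC", "C1CCNCC1", 1, (0, 2), 0)


def test_distinct_linker_sites_required():
    with pytest.raises(AssemblyError):
        assemble_protac("c1ccccc1", "CCC", "C1CCNCC1", 0, (1, 1), 0)


def test_corpus_reproducible():
    assert random_corpus(n=10, seed=7) == random_corpus(n=10, seed=7)
    assert random_corpus(n=10, seed=7) != random_corpus(n=10, seed=8)


def test_single_member_pools_share_truth():
    corpus = random_corpus(["c1ccncc1"], ["CCCC"], ["C1CCNCC1"], n=10, seed=1)
    assert len({p.truth for p in corpus}) == 1


def test_corpus_invariants_sweep():
    for p in random_corpus(n=50, seed=3):
        std = standardize_molecule(p.protac_smiles)
        assert "." not in std.smiles_canonical
        parts = [standardize_molecule(s) for s in p.truth]
        assert sum(x.n_heavy for x in parts) == std.n_heavy
        assert sum(x.n_rings for x in parts) == std.n_rings


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    w=st.sampled_from(DEFAULT_WARHEADS),
    l=st.sampled_from(DEFAULT_LINKERS),
    e=st.sampled_from(DEFAULT_E3_LIGANDS),
    pick=st.integers(min_value=0, max_value=10_000),
)
def test_assembly_conserves_counts_property(w, l, e, pick):
    wm, lm, em = (standardize_molecule(s).mol for s in (w, l, e))
    ws, ls, es = attachment_sites(wm), attachment_sites(lm), attachment_sites(em)
    if len(ls) < 2:
        return
    syn = assemble_protac(
        w, l, e,
        ws[pick % len(ws)],
        (ls[pick % len(ls)], ls[(pick + 1) % len(ls)])
        if ls[pick % len(ls)] != ls[(pick + 1) % len(ls)]
        else (ls[0], ls[1]),
        es[pick % len(es)],
    )
    std = standardize_molecule(syn.protac_smiles)
    assert Chem.MolFromSmiles(syn.protac_smiles) is not None
    assert sum(standardize_molecule(s).n_heavy for s in syn.truth) == std.n_heavy


@pytest.mark.parametrize("case", adversarial_cases(), ids=lambda c: c.name)
def test_adversarial_case_outcomes(case):
    warheads = library_from_smiles(case.warhead_lib, "warhead")
    e3s = library_from_smiles(case.e3_lib, "e3_ligand")
    report = bidirectional_decompose(case.protac_smiles, warheads, e3s)
    if case.expected_category is None:
        assert report.solved
        assert len(report.solutions) == case.expected_n_solutions
    else:
        assert report.status == "failed"
        assert report.failure_category == case.expected_category


def test_linker_series_shares_moieties_and_varies_linker():
    series, labels = linker_series()
    assert len(series) == 25 and len(labels) == 25
    assert len({p.warhead_smiles for p in series}) == 1
    assert len({p.e3_smiles for p in series}) == 1
    assert len({p.linker_smiles for p in series}) == 25
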