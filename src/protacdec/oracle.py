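"""Brute-force two-cut enumeration — an independent reference for small molecules.

A valid, fully conserving decomposition of a degrader corresponds to cutting
exactly two bridge bonds of the parent graph: ring conservation forbids
cutting through rings, and heavy-atom conservation forces the three pieces to
partition the parent. This module therefore enumerates *every* pair of bond
deletions that splits the parent into three connected pieces, keeps the
assignments whose two terminal pieces are canonical-SMILES-equal to library
members, and applies the same conservation arithmetic.

The enumeration is deliberately independent of the match-and-subtract
decomposer: no substructure matching, no directional passes. It is quadratic
in bond count, so it is only practical for small parents (≲ 30 heavy atoms),
where it serves as ground truth in tests.
"""

from __future__ import annotations

from itertools import combinations, permutations
from typing import Iterable

from rdkit import Chem

from .standardize import StereoMode, ring_count, standardize_molecule


def _piece_smiles(kek_parent: Chem.Mol, atoms: tuple[int, ...]) -> str | None:
    """Canonical SMILES of the induced submolecule, or None if unsanitizable."""
    keep = set(atoms)
    rw = Chem.RWMol(kek_parent)
    for idx in sorted(
        (i for i in range(kek_parent.GetNumAtoms()) if i not in keep), reverse=True
    ):
        rw.RemoveAtom(idx)
    piece = rw.GetMol()
    try:
        Chem.SanitizeMol(piece)
    except Exception:
        return None
    return Chem.MolToSmiles(piece)


def enumerate_two_cut_solutions(
    protac_smiles: str,
    warhead_smiles: Iterable[str],
    e3_smiles: Iterable[str],
    stereo: StereoMode = "ignore",
) -> set[tuple[str, str, str]]:
    """All (warhead, linker, E3) canonical triples reachable by two bond cuts.

    A triple is emitted when deleting some pair of bonds yields exactly three
    connected pieces, one piece equals a warhead-library member, another
    equals an E3-library member, the remaining piece (the linker) is nonempty,
    and the pieces' heavy-atom and SSSR ring counts sum to the parent's.
    """
    parent = standardize_molecule(protac_smiles, stereo=stereo)
    wh_set = {standardize_molecule(s, stereo=stereo).smiles_canonical for s in warhead_smiles}
    e3_set = {standardize_molecule(s, stereo=stereo).smiles_canonical for s in e3_smiles}

    kek = Chem.Mol(parent.mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in kek.GetBonds()]

    solutions: set[tuple[str, str, str]] = set()
    for (a1, a2), (b1, b2) in combinations(bonds, 2):
        rw = Chem.RWMol(kek)
        rw.RemoveBond(a1, a2)
        rw.RemoveBond(b1, b2)
        frags = Chem.GetMolFrags(rw.GetMol())
        if len(frags) != 3:
            continue
        smiles = [_piece_smiles(kek, f) for f in frags]
        if any(s is None for s in smiles):
            continue
        counts = []
        for s in smiles:
            m = Chem.MolFromSmiles(s)
            counts.append((m.GetNumHeavyAtoms(), ring_count(m)))
        for i, j, k in permutations(range(3)):
            w, l, e = smiles[i], smiles[j], smiles[k]
            if w not in wh_set or e not in e3_set:
                continue
            n_sum = counts[i][0] + counts[j][0] + counts[k][0]
            r_sum = counts[i][1] + counts[j][1] + counts[k][1]
            if n_sum == parent.n_heavy and r_sum == parent.n_rings:
                solutions.add((w, l, e))
    return solutions
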