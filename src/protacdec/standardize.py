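"""Molecule standardization.

Every structure that enters the decomposition pipeline — parent degraders,
library fragments, linkers — goes through the same normalization so that
canonical-SMILES equality can serve as the identity relation throughout:

* parse the SMILES,
* keep the largest covalently bonded component (salt/solvate stripping),
* optionally discard stereochemistry (the default: reference libraries are
  frequently drawn without it, and matching is 2-D),
* emit the RDKit canonical SMILES together with heavy-atom and SSSR ring
  counts computed on that component.

Standardization is idempotent: re-standardizing the canonical output is a
no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .errors import InputError, SmilesParseError

StereoMode = Literal["ignore", "strict"]


@dataclass(frozen=True)
class Standardized:
    """A canonicalized, single-component molecule record.

    ``mol`` carries the parsed RDKit molecule for downstream graph work; it is
    excluded from equality so two records with the same canonical SMILES
    compare equal.
    """

    smiles_canonical: str
    n_heavy: int
    n_rings: int
    mol: Chem.Mol = field(compare=False, repr=False)


def ring_count(mol: Chem.Mol) -> int:
    """Number of SSSR rings — the single ring-counting convention used everywhere."""
    return rdMolDescriptors.CalcNumRings(mol)


def standardize_molecule(smiles: str, stereo: StereoMode = "ignore") -> Standardized:
    """Canonicalize ``smiles`` to its largest connected component.

    Parameters
    ----------
    smiles:
        Input SMILES. Multi-component inputs (salts) are reduced to the
        largest component by heavy-atom count (ties broken by canonical
        SMILES so the choice is deterministic).
    stereo:
        ``"ignore"`` (default) removes stereochemistry before
        canonicalization; ``"strict"`` preserves it.

    Raises
    ------
    InputError
        If ``smiles`` is empty or not a string.
    SmilesParseError
        If RDKit cannot parse the input.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise InputError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    mol = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))
    if stereo == "ignore":
        Chem.RemoveStereochemistry(mol)
    canonical = Chem.MolToSmiles(mol)
    # Re-parse so the carried mol is exactly the molecule the SMILES denotes.
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:  # pragma: no cover - canonical output always re-parses
        raise SmilesParseError(canonical, "canonical form failed to re-parse")
    return Standardized(
        smiles_canonical=canonical,
        n_heavy=mol.GetNumHeavyAtoms(),
        n_rings=ring_count(mol),
        mol=mol,
    )
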