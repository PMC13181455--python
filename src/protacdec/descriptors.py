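"""Physicochemical descriptors for linkerology profiling.

Six 2-D descriptors summarize what matters about a linker (or any moiety):

* size — average molecular weight (MW, Da, implicit hydrogens included);
* hydrophobicity — number of carbon atoms (nC);
* polarity — topological polar surface area (TPSA, Å²), hydrogen-bond donors
  (HBD) and acceptors (HBA);
* flexibility — the Kier molecular flexibility index
  Φ = (¹κα · ²κα) / A, where A is the heavy-atom count and ¹κα, ²κα are the
  alpha-modified Hall–Kier kappa shape indices.

Donor/acceptor counts use RDKit's ``CalcNumHBD``/``CalcNumHBA`` (N/O-based)
definitions; these are the pinned convention for the whole package, so group
comparisons are internally consistent. Φ is computed from RDKit's Kappa1 and
Kappa2, which implement the alpha-modified kappa formulas; on unbranched
sp³ alkanes of A atoms this reduces to the closed form Φ = A − 1.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, GraphDescriptors, rdMolDescriptors

from .errors import InputError
from .standardize import Standardized, ring_count, standardize_molecule

DESCRIPTOR_COLUMNS = ("mw", "nC", "tpsa", "hbd", "hba", "phi", "n_heavy", "n_rings")


@dataclass(frozen=True)
class DescriptorRecord:
    """The six linkerology descriptors plus bookkeeping counts."""

    mw: float
    nC: int
    tpsa: float
    hbd: int
    hba: int
    phi: float
    n_heavy: int
    n_rings: int


def kier_flexibility(mol: Chem.Mol) -> float:
    """Kier flexibility index Φ = κ1·κ2 / A (alpha-modified kappas).

    For molecules with fewer than three heavy atoms the second-order path
    count vanishes and the index is undefined; 0.0 is returned by convention
    (such fragments carry no conformational flexibility to speak of).
    """
    n_heavy = mol.GetNumHeavyAtoms()
    if n_heavy < 3:
        return 0.0
    return GraphDescriptors.Kappa1(mol) * GraphDescriptors.Kappa2(mol) / n_heavy


def compute_descriptors(molecule: str | Standardized | Chem.Mol) -> DescriptorRecord:
    """Compute the descriptor record for one molecule.

    Accepts a SMILES string, a :class:`Standardized` record, or an RDKit mol.
    Pure function: identical canonical SMILES yield identical records.
    """
    if isinstance(molecule, Standardized):
        mol = molecule.mol
    elif isinstance(molecule, Chem.Mol):
        mol = molecule
    else:
        mol = standardize_molecule(molecule).mol
    if mol.GetNumHeavyAtoms() < 1:
        raise InputError("cannot compute descriptors of an empty molecule")
    return DescriptorRecord(
        mw=Descriptors.MolWt(mol),
        nC=sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6),
        tpsa=rdMolDescriptors.CalcTPSA(mol),
        hbd=rdMolDescriptors.CalcNumHBD(mol),
        hba=rdMolDescriptors.CalcNumHBA(mol),
        phi=kier_flexibility(mol),
        n_heavy=mol.GetNumHeavyAtoms(),
        n_rings=ring_count(mol),
    )


def profile_set(
    molecules: Sequence[str | Standardized],
    ids: Optional[Sequence[str]] = None,
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Descriptor table for a set of molecules, plus per-label group means.

    ``labels`` are opaque user-supplied strings (e.g. degradation-efficacy
    classes determined experimentally); with no labels a single overall mean
    row is appended. Rows are tagged ``kind = "molecule"`` or
    ``kind = "group_mean"``.
    """
    if not molecules:
        raise InputError("profile_set needs at least one molecule")
    if labels is not None and len(labels) != len(molecules):
        raise InputError(
            f"got {len(labels)} labels for {len(molecules)} molecules"
        )
    if ids is not None and len(ids) != len(molecules):
        raise InputError(f"got {len(ids)} ids for {len(molecules)} molecules")

    rows = []
    for i, m in enumerate(molecules):
        std = m if isinstance(m, Standardized) else standardize_molecule(m)
        rec = asdict(compute_descriptors(std))
        rows.append(
            {
                "id": ids[i] if ids is not None else f"mol{i + 1}",
                "smiles": std.smiles_canonical,
                "label": labels[i] if labels is not None else "all",
                "kind": "molecule",
                **rec,
            }
        )
    df = pd.DataFrame(rows)
    means = (
        df.groupby("label", sort=True)[list(DESCRIPTOR_COLUMNS)]
        .mean()
        .reset_index()
    )
    means.insert(0, "id", "mean[" + means["label"] + "]")
    means.insert(1, "smiles", "")
    means["kind"] = "group_mean"
    return pd.concat([df, means[df.columns]], ignore_index=True)
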