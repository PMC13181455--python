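"""Synthetic degrader assembly with known ground truth.

Real validation sets for decomposition tools are curated by hand; this module
replaces them with molecules whose true (warhead, linker, E3 ligand) triple
is known *by construction*: two single bonds join three standardized parts at
hydrogen-bearing attachment atoms, so heavy-atom and ring conservation hold
automatically and every assembled molecule is a fully specified test case.

The default pools use small drug-like ring systems — indole, quinazoline and
sulfonamide warhead stand-ins, thalidomide-type glutarimide and VHL-like
amide E3 ligands, alkyl/PEG/amide/piperazine linkers — so that corpus tests
run in seconds while still exercising fused rings, heteroatoms and flexible
chains. ``adversarial_cases`` adds hand-built molecules engineered to hit
each failure category of the decomposer's taxonomy.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from typing import Optional, Sequence

from rdkit import Chem, rdBase

from .errors import AssemblyError
from .standardize import ring_count, standardize_molecule

logger = logging.getLogger(__name__)

#: Warhead stand-ins: drug-like POI-binding cores.
DEFAULT_WARHEADS = (
    "NC(=O)c1cc2ccccc2[nH]1",            # indole-2-carboxamide
    "c1ccc2ncncc2c1",                     # quinazoline
    "Cc1ccc(S(N)(=O)=O)cc1",              # toluenesulfonamide
    "c1ccc(-n2cccn2)cc1",                 # phenylpyrazole
    "COc1ccc2nccc(N)c2c1",                # aminoquinoline ether
)

#: Linker stand-ins: flexible chains, PEG, amide and ring-containing linkers.
DEFAULT_LINKERS = (
    "CCCC",                               # butylene
    "CCCCCC",                             # hexylene
    "OCCOCCO",                            # di(ethylene glycol)
    "NCCOCCN",                            # PEG diamine
    "NCC(=O)NCC",                         # glycinamide chain
    "C1CNCCN1",                           # piperazine
    "CC(=O)NCCC",                         # acetamide chain
)

#: E3 ligase ligand stand-ins: cereblon- and VHL-type binders.
DEFAULT_E3_LIGANDS = (
    "O=C1CCC(N2C(=O)c3ccccc3C2=O)C(=O)N1",   # thalidomide (glutarimide-phthalimide)
    "CC(C)C(=O)N1CCCC1C(=O)NCc1ccccc1",      # VHL-like prolinamide
    "O=C1CCCN1c1ccc2ncccc2c1",               # pyrrolidinone-quinoline binder
)


@dataclass(frozen=True)
class SyntheticProtac:
    """An assembled degrader carrying its ground-truth decomposition."""

    protac_smiles: str
    warhead_smiles: str
    linker_smiles: str
    e3_smiles: str
    seed: int = 0

    @property
    def truth(self) -> tuple[str, str, str]:
        return (self.warhead_smiles, self.linker_smiles, self.e3_smiles)


@dataclass(frozen=True)
class AdversarialCase:
    """A fixed molecule/library pairing engineered for one decomposer outcome."""

    name: str
    protac_smiles: str
    warhead_lib: tuple[str, ...]
    e3_lib: tuple[str, ...]
    expected_category: Optional[str]  # None for solvable cases
    expected_n_solutions: int = 0


def attachment_sites(mol: Chem.Mol, min_hydrogens: int = 1) -> list[int]:
    """Atom indices able to accept one more single bond (≥ min_hydrogens H)."""
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= min_hydrogens]


def assemble_protac(
    warhead: str,
    linker: str,
    e3: str,
    wh_site: int,
    linker_sites: tuple[int, int],
    e3_site: int,
    seed: int = 0,
) -> SyntheticProtac:
    """Join warhead–linker–E3 with two single bonds at the given atom indices.

    The truth triple is recorded as the standardized input parts; conservation
    of heavy atoms and rings holds by construction. Raises
    :class:`AssemblyError` when a chosen atom cannot accept the new bond(s).
    """
    w = standardize_molecule(warhead)
    l = standardize_molecule(linker)
    e = standardize_molecule(e3)
    ls1, ls2 = linker_sites
    if l.n_heavy > 1 and ls1 == ls2:
        raise AssemblyError("linker attachment sites must be distinct atoms")
    for mol, site, needed, part in (
        (w.mol, wh_site, 1, "warhead"),
        (l.mol, ls1, 2 if ls1 == ls2 else 1, "linker"),
        (l.mol, ls2, 2 if ls1 == ls2 else 1, "linker"),
        (e.mol, e3_site, 1, "e3"),
    ):
        if not (0 <= site < mol.GetNumAtoms()):
            raise AssemblyError(f"{part} site {site} out of range")
        if mol.GetAtomWithIdx(site).GetTotalNumHs() < needed:
            raise AssemblyError(
                f"{part} atom {site} has no available hydrogen for a new bond"
            )
    combo = Chem.CombineMols(Chem.CombineMols(w.mol, l.mol), e.mol)
    rw = Chem.RWMol(combo)
    off_l = w.mol.GetNumAtoms()
    off_e = off_l + l.mol.GetNumAtoms()
    rw.AddBond(wh_site, off_l + ls1, Chem.BondType.SINGLE)
    rw.AddBond(off_l + ls2, off_e + e3_site, Chem.BondType.SINGLE)
    # atoms whose hydrogens are explicit (e.g. aromatic [nH]) must give one
    # up per new bond; implicit hydrogens recompute on sanitization
    for idx in (wh_site, off_l + ls1, off_l + ls2, off_e + e3_site):
        atom = rw.GetAtomWithIdx(idx)
        explicit = atom.GetNumExplicitHs()
        if explicit > 0:
            atom.SetNumExplicitHs(explicit - 1)
    assembled = rw.GetMol()
    try:
        with rdBase.BlockLogs():
            Chem.SanitizeMol(assembled)
    except Exception as exc:  # valence violations etc.
        raise AssemblyError(f"assembly produced an invalid molecule: {exc}") from exc
    protac = standardize_molecule(Chem.MolToSmiles(assembled))
    # conservation sanity, by construction
    assert protac.n_heavy == w.n_heavy + l.n_heavy + e.n_heavy
    assert protac.n_rings == w.n_rings + l.n_rings + e.n_rings
    return SyntheticProtac(
        protac_smiles=protac.smiles_canonical,
        warhead_smiles=w.smiles_canonical,
        linker_smiles=l.smiles_canonical,
        e3_smiles=e.smiles_canonical,
        seed=seed,
    )


def random_corpus(
    warhead_pool: Optional[Sequence[str]] = None,
    linker_pool: Optional[Sequence[str]] = None,
    e3_pool: Optional[Sequence[str]] = None,
    n: int = 200,
    seed: int = 0,
    max_retries: int = 20,
) -> list[SyntheticProtac]:
    """Seeded, reproducible corpus of assembled degraders.

    Triples and attachment sites are sampled uniformly; a triple whose sampled
    sites violate valence is resampled up to ``max_retries`` times, then
    skipped with a warning. The same seed always yields the identical corpus.
    """
    warhead_pool = tuple(warhead_pool or DEFAULT_WARHEADS)
    linker_pool = tuple(linker_pool or DEFAULT_LINKERS)
    e3_pool = tuple(e3_pool or DEFAULT_E3_LIGANDS)
    if n < 1:
        raise AssemblyError("corpus size must be >= 1")
    rng = random.Random(seed)
    corpus: list[SyntheticProtac] = []
    for i in range(n):
        assembled = None
        for _ in range(max_retries):
            w = rng.choice(warhead_pool)
            l = rng.choice(linker_pool)
            e = rng.choice(e3_pool)
            wm = standardize_molecule(w).mol
            lm = standardize_molecule(l).mol
            em = standardize_molecule(e).mol
            w_sites = attachment_sites(wm)
            e_sites = attachment_sites(em)
            l_sites = attachment_sites(lm)
            if not w_sites or not e_sites or not l_sites:
                continue
            if lm.GetNumAtoms() == 1:
                ls = (l_sites[0], l_sites[0])
                if lm.GetAtomWithIdx(l_sites[0]).GetTotalNumHs() < 2:
                    continue
            else:
                if len(l_sites) < 2:
                    continue
                ls = tuple(rng.sample(l_sites, 2))
            try:
                assembled = assemble_protac(
                    w, l, e, rng.choice(w_sites), ls, rng.choice(e_sites), seed=seed
                )
                break
            except AssemblyError:
                continue
        if assembled is None:
            logger.warning("skipping corpus entry %d: no valid attachment found", i)
            continue
        corpus.append(assembled)
    return corpus


# A pyridine-C3-piperidine toy degrader used across the adversarial cases.
_P1 = "c1ccc(nc1)CCCN1CCCCC1"


def adversarial_cases() -> list[AdversarialCase]:
    """Fixed molecule/library pairings triggering each failure category.

    * ``warhead_not_found`` / ``e3_not_found`` — the matching moiety is simply
      absent from the corresponding library;
    * ``linker_inconsistent`` — extended library fragments (2-ethylpyridine /
      N-ethylpiperidine) both match the parent but claim an overlapping
      methylene, so neither directional pass can complete a consistent triple;
    * ``multiple_linker_fragments`` — the warhead ring sits in the middle of
      the chain, so its subtraction disconnects the candidate linker;
    * ``count_discrepancy`` — benzene matches into the fused ring of a
      quinoline-based degrader; the consistent triple loses one SSSR ring;
    * ``boundary_ambiguity`` — a second, larger warhead shifting the boundary
      by one methylene yields exactly two valid solutions.
    """
    return [
        AdversarialCase(
            name="warhead_not_found",
            protac_smiles=_P1,
            warhead_lib=("c1ccc2ccccc2c1",),
            e3_lib=("C1CCNCC1",),
            expected_category="warhead_not_found",
        ),
        AdversarialCase(
            name="e3_not_found",
            protac_smiles=_P1,
            warhead_lib=("c1ccncc1",),
            e3_lib=("c1ccc2ccccc2c1",),
            expected_category="e3_not_found",
        ),
        AdversarialCase(
            name="linker_inconsistent",
            protac_smiles=_P1,
            warhead_lib=("CCc1ccccn1",),
            e3_lib=("CCN1CCCCC1",),
            expected_category="linker_inconsistent",
        ),
        AdversarialCase(
            name="multiple_linker_fragments",
            protac_smiles="c1ccc(cc1)CCc1ccc(CCN2CCCCC2)cn1",
            warhead_lib=("c1ccncc1",),
            e3_lib=("C1CCNCC1",),
            expected_category="multiple_linker_fragments",
        ),
        AdversarialCase(
            name="count_discrepancy",
            protac_smiles="c1ccc2nc(CCCN3CCCCC3)ccc2c1",
            warhead_lib=("c1ccccc1",),
            e3_lib=("C1CCNCC1",),
            expected_category="count_discrepancy",
        ),
        AdversarialCase(
            name="boundary_ambiguity",
            protac_smiles=_P1,
            warhead_lib=("c1ccncc1", "Cc1ccccn1"),
            e3_lib=("C1CCNCC1",),
            expected_category=None,
            expected_n_solutions=2,
        ),
    ]


#: Shared moieties of the linker-variation series.
SERIES_WARHEAD = "NC(=O)c1cc2ccccc2[nH]1"
SERIES_E3 = "O=C1CCC(N2C(=O)c3ccccc3C2=O)C(=O)N1"

_SERIES_LINKERS = (
    "CC", "CCC", "CCCC", "CCCCC", "CCCCCC", "CCCCCCC", "CCCCCCCC", "CCCCCCCCC",
    "OCCO", "OCCOCCO", "OCCOCCOCCO", "COCCOC", "CCOCCOCC",
    "NCC(=O)C", "NCCC(=O)CC", "CC(=O)NCC", "CCNC(=O)CC",
    "C1CCCCC1", "C1CCNCC1", "C1CNCCN1", "c1ccccc1",
    "CC1CCC(C)CC1", "OCCNCCO", "NCCCCN", "CCSCC",
)


def linker_series(seed: int = 0) -> tuple[list[SyntheticProtac], list[str]]:
    """A 25-member series sharing one warhead and one thalidomide-type E3 ligand.

    Mirrors the shape of a lead-optimization campaign in which only the linker
    varies: each member is assembled from the shared moieties and one of 25
    distinct linkers. Returns the series together with deterministic
    poor/moderate/strong efficacy labels (opaque stand-ins for experimental
    classes).
    """
    rng = random.Random(seed)
    series: list[SyntheticProtac] = []
    wm = standardize_molecule(SERIES_WARHEAD).mol
    em = standardize_molecule(SERIES_E3).mol
    w_sites = attachment_sites(wm)
    e_sites = attachment_sites(em)
    for smi in _SERIES_LINKERS:
        lm = standardize_molecule(smi).mol
        l_sites = attachment_sites(lm)
        assembled = None
        for _ in range(20):
            ls = tuple(rng.sample(l_sites, 2)) if len(l_sites) > 1 else (l_sites[0], l_sites[0])
            try:
                assembled = assemble_protac(
                    SERIES_WARHEAD, smi, SERIES_E3,
                    rng.choice(w_sites), ls, rng.choice(e_sites), seed=seed,
                )
                break
            except AssemblyError:
                continue
        if assembled is None:  # pragma: no cover - pools chosen to always assemble
            raise AssemblyError(f"could not assemble series member with linker {smi}")
        series.append(assembled)
    labels = [("poor", "moderate", "strong")[i % 3] for i in range(len(series))]
    return series, labels
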