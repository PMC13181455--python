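"""Bidirectional match-and-subtract decomposition of heterobifunctional degraders.

The algorithm mirrors how a medicinal chemist annotates a PROTAC:

* **Pass A** — match every warhead-library fragment against the parent,
  subtract each match, then match every E3-ligand-library fragment against
  what remains; the leftover atoms are a candidate linker.
* **Pass B** — the same procedure starting from the E3 ligand.
* **Consistency** — a candidate triple (warhead, linker, E3) is retained only
  if the *identical* triple — same canonical warhead, same canonical E3, and
  the same canonical linker SMILES — arises in both directions.
* **Filters** — surviving candidates must have a single connected linker with
  at least one heavy atom, and the three parts must conserve the parent's
  heavy-atom and SSSR ring counts exactly. Nothing is invented and nothing is
  lost: a solution accounts for the entire parent molecule.

Matching the second fragment is performed against the remainder molecule
(re-sanitized after subtraction), not against the parent. This matters: when
the first subtraction cuts into a fused ring system the remainder's
aromaticity is re-perceived, so the two directions can genuinely disagree —
which is exactly the pass-A/pass-B linker inconsistency the failure taxonomy
reports.

All valid solutions are enumerated, deduplicated by canonical triple, and
returned in a stable order; the final choice between chemically plausible
alternative boundaries is left to the user.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from rdkit import Chem

from .errors import ContractError, DegenerateSubtractionError, InputError, ProtacDecError
from .library import Fragment, FragmentLibrary
from .standardize import Standardized, StereoMode, ring_count, standardize_molecule

logger = logging.getLogger(__name__)

# Failure taxonomy, in priority order (earliest-stage cause wins).
WARHEAD_NOT_FOUND = "warhead_not_found"
E3_NOT_FOUND = "e3_not_found"
LINKER_INCONSISTENT = "linker_inconsistent"
MULTIPLE_LINKER_FRAGMENTS = "multiple_linker_fragments"
COUNT_DISCREPANCY = "count_discrepancy"
INPUT_ERROR = "input_error"  # artifact-level extension for unparseable input rows

FAILURE_CATEGORIES = (
    WARHEAD_NOT_FOUND,
    E3_NOT_FOUND,
    LINKER_INCONSISTENT,
    MULTIPLE_LINKER_FRAGMENTS,
    COUNT_DISCREPANCY,
)


# ---------------------------------------------------------------------------
# graph helpers
# ---------------------------------------------------------------------------

def _kekulized_copy(mol: Chem.Mol) -> Chem.Mol:
    m = Chem.Mol(mol)
    Chem.Kekulize(m, clearAromaticFlags=True)
    return m


def _delete_atoms(mol: Chem.Mol, atoms: Sequence[int]) -> tuple[Chem.Mol, list[int]]:
    """Remove ``atoms`` (indices of ``mol``) and re-sanitize.

    Works on a kekulized copy so that partially removed aromatic systems
    leave well-defined alternating bonds; sanitization then re-perceives
    aromaticity on whatever rings survived intact.

    Returns the remainder molecule and ``old_of_new`` mapping each remainder
    atom index back to its index in ``mol``. Raises
    ``DegenerateSubtractionError`` if nothing remains and ``ValueError`` if
    the remainder cannot be sanitized.
    """
    doomed = set(atoms)
    if len(doomed) >= mol.GetNumAtoms():
        raise DegenerateSubtractionError("subtraction would remove every atom")
    rw = Chem.RWMol(_kekulized_copy(mol))
    for idx in sorted(doomed, reverse=True):
        rw.RemoveAtom(idx)
    remainder = rw.GetMol()
    Chem.SanitizeMol(remainder)  # raises on broken valence etc.
    old_of_new = [i for i in range(mol.GetNumAtoms()) if i not in doomed]
    return remainder, old_of_new


def _component_smiles(mol: Chem.Mol) -> list[str]:
    """Canonical SMILES of each connected component, sorted."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    return sorted(Chem.MolToSmiles(f) for f in frags)


def extract_fragment(parent: Chem.Mol, atoms: Sequence[int]) -> Standardized:
    """Standardized record for the induced submolecule on ``atoms`` of ``parent``."""
    keep = set(atoms)
    drop = [i for i in range(parent.GetNumAtoms()) if i not in keep]
    sub, _ = _delete_atoms(parent, drop)
    return standardize_molecule(Chem.MolToSmiles(sub))


# ---------------------------------------------------------------------------
# matching and subtraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchSite:
    """One symmetry-distinct embedding of a library fragment in a parent."""

    fragment_id: str
    atom_indices: tuple[int, ...]  # sorted parent atom indices
    cut_bonds: tuple[tuple[int, int], ...]  # (inside atom, outside atom) pairs


def find_matches(
    parent: Standardized,
    fragment: Fragment,
    stereo: StereoMode = "ignore",
) -> list[MatchSite]:
    """All symmetry-distinct substructure embeddings of ``fragment`` in ``parent``.

    Embeddings covering the same atom set (automorphic images) are reported
    once. A fragment as large as the whole parent is rejected: all three
    moieties of a degrader must be nonempty. Results are ordered by sorted
    atom-index tuple, so the enumeration is deterministic.
    """
    if fragment.n_heavy >= parent.n_heavy:
        return []
    raw = parent.mol.GetSubstructMatches(
        fragment.mol,
        uniquify=True,
        useChirality=(stereo == "strict"),
        maxMatches=10_000,
    )
    atom_sets = sorted({tuple(sorted(m)) for m in raw})
    sites = []
    for atoms in atom_sets:
        inside = set(atoms)
        cuts = []
        for bond in parent.mol.GetBonds():
            a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if (a in inside) != (b in inside):
                cuts.append((a, b) if a in inside else (b, a))
        sites.append(
            MatchSite(
                fragment_id=fragment.id,
                atom_indices=atoms,
                cut_bonds=tuple(sorted(cuts)),
            )
        )
    return sites


def subtract_fragment(parent: Standardized, site: MatchSite) -> list[Standardized]:
    """Remove a match site from the parent; return its connected remainders.

    Each remainder is returned as a standardized record (canonical SMILES and
    counts). Attachment positions are tracked internally by the pass driver;
    the emitted SMILES carry no dummy atoms.
    """
    remainder, _ = _delete_atoms(parent.mol, site.atom_indices)
    return [standardize_molecule(s) for s in _component_smiles(remainder)]


# ---------------------------------------------------------------------------
# directional passes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    """An unfiltered (warhead, linker, E3) candidate from one directional pass."""

    warhead: Fragment
    e3_ligand: Fragment
    warhead_atoms: tuple[int, ...]  # parent atom indices
    e3_atoms: tuple[int, ...]
    linker_atoms: tuple[int, ...]
    linker_components: tuple[str, ...]  # sorted canonical SMILES, one per component

    @property
    def linker_smiles(self) -> str:
        return ".".join(self.linker_components)

    @property
    def triple(self) -> tuple[str, str, str]:
        return (
            self.warhead.smiles_canonical,
            self.linker_smiles,
            self.e3_ligand.smiles_canonical,
        )


@dataclass
class PassTrace:
    """How far one directional pass got — used for failure categorization."""

    first_role: str
    first_matched: bool = False
    second_matched: bool = False
    n_candidates: int = 0


def decompose_pass(
    parent: Standardized,
    first_lib: FragmentLibrary,
    second_lib: FragmentLibrary,
    stereo: StereoMode = "ignore",
) -> tuple[list[Candidate], PassTrace]:
    """One directional match-and-subtract pass.

    For every first-library match the matched atoms are subtracted and the
    second library is matched against the remainder; the atoms left over form
    the candidate linker. Branches whose first subtraction disconnects the
    remainder are carried forward (their linkers end up multi-component and
    are rejected later by the single-linker filter rather than prevented
    here). Enumeration is exhaustive and deterministically ordered.
    """
    if len(first_lib) == 0 or len(second_lib) == 0:
        raise InputError("fragment libraries must be nonempty")
    trace = PassTrace(first_role=first_lib.role)
    candidates: list[Candidate] = []
    for f1 in first_lib:
        sites1 = find_matches(parent, f1, stereo=stereo)
        if sites1:
            trace.first_matched = True
        for s1 in sites1:
            try:
                remainder, old_of_new = _delete_atoms(parent.mol, s1.atom_indices)
            except (DegenerateSubtractionError, ValueError, Chem.rdchem.KekulizeException):
                continue
            rem_std = Standardized(
                smiles_canonical=Chem.MolToSmiles(remainder),
                n_heavy=remainder.GetNumHeavyAtoms(),
                n_rings=ring_count(remainder),
                mol=remainder,
            )
            for f2 in second_lib:
                sites2 = find_matches(rem_std, f2, stereo=stereo)
                if sites2:
                    trace.second_matched = True
                for s2 in sites2:
                    try:
                        linker_mol, _ = _delete_atoms(remainder, s2.atom_indices)
                    except (DegenerateSubtractionError, ValueError, Chem.rdchem.KekulizeException):
                        continue
                    s2_parent = tuple(sorted(old_of_new[i] for i in s2.atom_indices))
                    linker_parent = tuple(
                        sorted(
                            old_of_new[i]
                            for i in range(remainder.GetNumAtoms())
                            if i not in set(s2.atom_indices)
                        )
                    )
                    wh, e3 = (f1, f2) if first_lib.role == "warhead" else (f2, f1)
                    wh_atoms, e3_atoms = (
                        (s1.atom_indices, s2_parent)
                        if first_lib.role == "warhead"
                        else (s2_parent, s1.atom_indices)
                    )
                    candidates.append(
                        Candidate(
                            warhead=wh,
                            e3_ligand=e3,
                            warhead_atoms=wh_atoms,
                            e3_atoms=e3_atoms,
                            linker_atoms=linker_parent,
                            linker_components=tuple(_component_smiles(linker_mol)),
                        )
                    )
    trace.n_candidates = len(candidates)
    return candidates, trace


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterResult:
    passed: bool
    violations: tuple[str, ...]


def apply_filters(candidate: Candidate, parent: Standardized) -> FilterResult:
    """Structural conservation filters on a consistent candidate.

    Checks, in order: (1) the linker is exactly one connected component with
    at least one heavy atom; (2) heavy-atom conservation against the parent;
    (3) SSSR ring-count conservation. All violations are reported, not just
    the first.
    """
    violations: list[str] = []
    linker_mol = Chem.MolFromSmiles(candidate.linker_smiles) if candidate.linker_smiles else None
    if len(candidate.linker_components) != 1 or linker_mol is None or linker_mol.GetNumHeavyAtoms() < 1:
        violations.append(MULTIPLE_LINKER_FRAGMENTS)
    n_linker = linker_mol.GetNumHeavyAtoms() if linker_mol is not None else 0
    r_linker = ring_count(linker_mol) if linker_mol is not None else 0
    if candidate.warhead.n_heavy + n_linker + candidate.e3_ligand.n_heavy != parent.n_heavy:
        violations.append("heavy_atom_discrepancy")
    if candidate.warhead.n_rings + r_linker + candidate.e3_ligand.n_rings != parent.n_rings:
        violations.append("ring_count_discrepancy")
    return FilterResult(passed=not violations, violations=tuple(violations))


def categorize_failure(
    trace_a: PassTrace,
    trace_b: PassTrace,
    consistent: Sequence[tuple[Candidate, FilterResult]],
) -> str:
    """Assign the single failure category for a molecule with no valid solution.

    Priority order (earliest-stage cause wins):

    1. ``warhead_not_found`` — no warhead-library match in either pass;
    2. ``e3_not_found`` — a warhead matched, but no E3-library match;
    3. ``linker_inconsistent`` — both moieties were found, yet the two
       directional passes yielded no identical (warhead, linker, E3) triple
       (including the overlapping-match case where one or both passes produce
       no candidate at all);
    4. ``multiple_linker_fragments`` — consistent candidates existed but every
       one had a disconnected linker;
    5. ``count_discrepancy`` — the remaining candidates violated heavy-atom or
       ring-count conservation.
    """
    if any(res.passed for _, res in consistent):
        raise ContractError("categorize_failure called although valid solutions exist")
    warhead_seen = trace_a.first_matched or trace_b.second_matched
    e3_seen = trace_a.second_matched or trace_b.first_matched
    if not warhead_seen:
        return WARHEAD_NOT_FOUND
    if not e3_seen:
        return E3_NOT_FOUND
    if not consistent:
        return LINKER_INCONSISTENT
    if all(len(c.linker_components) != 1 for c, _ in consistent):
        return MULTIPLE_LINKER_FRAGMENTS
    return COUNT_DISCREPANCY


# ---------------------------------------------------------------------------
# the bidirectional driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecompositionSolution:
    """One validated (warhead, linker, E3) triple with conservation bookkeeping."""

    warhead: Fragment
    e3_ligand: Fragment
    warhead_atoms: tuple[int, ...]
    e3_atoms: tuple[int, ...]
    linker_atoms: tuple[int, ...]
    linker_smiles: str
    n_heavy_linker: int
    n_rings_linker: int
    found_in_pass_a: bool = True
    found_in_pass_b: bool = True

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.warhead.smiles_canonical, self.linker_smiles, self.e3_ligand.smiles_canonical)


@dataclass(frozen=True)
class DecompositionReport:
    """Per-degrader outcome: all valid solutions, or a single failure category."""

    protac_id: str
    protac_smiles_canonical: str
    status: Literal["solved", "failed", "input_error"]
    solutions: tuple[DecompositionSolution, ...] = ()
    failure_category: Optional[str] = None

    @property
    def solved(self) -> bool:
        return self.status == "solved"


def bidirectional_decompose(
    protac: str | Standardized,
    warhead_lib: FragmentLibrary,
    e3_lib: FragmentLibrary,
    stereo: StereoMode = "ignore",
    protac_id: str = "",
) -> DecompositionReport:
    """Decompose one degrader with the full bidirectional procedure.

    Runs the warhead-first and E3-first passes, keeps only triples appearing
    identically in both, applies the conservation filters, and returns either
    all valid solutions (deduplicated, stably sorted by descending warhead
    size, then descending E3 size, then linker SMILES) or a single failure
    category. Unparseable input yields a distinct ``input_error`` report, not
    a silent skip.
    """
    if len(warhead_lib) == 0 or len(e3_lib) == 0:
        raise InputError("fragment libraries must be nonempty")
    if isinstance(protac, Standardized):
        parent = protac
    else:
        try:
            parent = standardize_molecule(protac, stereo=stereo)
        except ProtacDecError:
            return DecompositionReport(
                protac_id=protac_id,
                protac_smiles_canonical=str(protac),
                status="input_error",
                failure_category=INPUT_ERROR,
            )

    cands_a, trace_a = decompose_pass(parent, warhead_lib, e3_lib, stereo=stereo)
    cands_b, trace_b = decompose_pass(parent, e3_lib, warhead_lib, stereo=stereo)

    by_triple_a: dict[tuple[str, str, str], Candidate] = {}
    for c in cands_a:
        by_triple_a.setdefault(c.triple, c)
    triples_b = {c.triple for c in cands_b}

    consistent: list[tuple[Candidate, FilterResult]] = []
    for triple, cand in by_triple_a.items():
        if triple in triples_b:
            consistent.append((cand, apply_filters(cand, parent)))

    solutions: dict[tuple[str, str, str], DecompositionSolution] = {}
    for cand, res in consistent:
        if not res.passed:
            continue
        linker_mol = Chem.MolFromSmiles(cand.linker_smiles)
        solutions.setdefault(
            cand.triple,
            DecompositionSolution(
                warhead=cand.warhead,
                e3_ligand=cand.e3_ligand,
                warhead_atoms=cand.warhead_atoms,
                e3_atoms=cand.e3_atoms,
                linker_atoms=cand.linker_atoms,
                linker_smiles=cand.linker_smiles,
                n_heavy_linker=linker_mol.GetNumHeavyAtoms(),
                n_rings_linker=ring_count(linker_mol),
            ),
        )
    if solutions:
        ordered = tuple(
            sorted(
                solutions.values(),
                key=lambda s: (-s.warhead.n_heavy, -s.e3_ligand.n_heavy, s.linker_smiles),
            )
        )
        return DecompositionReport(
            protac_id=protac_id,
            protac_smiles_canonical=parent.smiles_canonical,
            status="solved",
            solutions=ordered,
        )
    category = categorize_failure(trace_a, trace_b, consistent)
    return DecompositionReport(
        protac_id=protac_id,
        protac_smiles_canonical=parent.smiles_canonical,
        status="failed",
        failure_category=category,
    )
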