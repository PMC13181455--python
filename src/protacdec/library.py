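"""Warhead and E3-ligand reference libraries.

A library is an ordered collection of standardized fragments of one role.
Entries are plain molecules (no attachment-point annotation); attachment
positions are discovered at match time by the decomposer. Ordering is
deterministic — descending heavy-atom count, ties broken lexicographically by
canonical SMILES — so that larger, more specific fragments are tried first
and repeated runs produce identical output.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional, Sequence

import pandas as pd
from rdkit import Chem

from .errors import LibraryError, ProtacDecError
from .standardize import StereoMode, standardize_molecule

logger = logging.getLogger(__name__)

Role = Literal["warhead", "e3_ligand"]
ROLES: tuple[Role, ...] = ("warhead", "e3_ligand")

#: Fragments below this heavy-atom count are flagged by validate_library and
#: excluded from batch runs by default: tiny fragments produce degenerate,
#: chemically meaningless matches.
MIN_FRAGMENT_HEAVY_ATOMS = 3


@dataclass(frozen=True)
class Fragment:
    """One library entry: a standardized warhead or E3 ligase ligand."""

    id: str
    smiles_input: str
    smiles_canonical: str
    role: Role
    n_heavy: int
    n_rings: int
    mol: Chem.Mol = field(compare=False, repr=False)


@dataclass(frozen=True)
class FragmentLibrary:
    """An ordered, deduplicated collection of fragments sharing one role."""

    role: Role
    fragments: tuple[Fragment, ...]
    source_path: str = ""

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self) -> Iterator[Fragment]:
        return iter(self.fragments)

    def canonical_smiles(self) -> tuple[str, ...]:
        return tuple(f.smiles_canonical for f in self.fragments)


def _order_key(frag: Fragment) -> tuple[int, str]:
    return (-frag.n_heavy, frag.smiles_canonical)


def library_from_smiles(
    smiles_list: Sequence[str],
    role: Role,
    ids: Optional[Sequence[Optional[str]]] = None,
    source_path: str = "",
    stereo: StereoMode = "ignore",
) -> FragmentLibrary:
    """Build a library from in-memory SMILES.

    Rows that fail to parse are skipped with a warning; duplicates (identical
    canonical SMILES) collapse to the first occurrence. Fragments missing an
    id are assigned one from their position in the final deterministic
    ordering, so shuffled input yields a bit-identical library.
    """
    if role not in ROLES:
        raise LibraryError(f"unknown role {role!r}; expected one of {ROLES}")
    if ids is not None and len(ids) != len(smiles_list):
        raise LibraryError("ids and smiles_list must have equal length")

    seen: dict[str, Fragment] = {}
    for i, smi in enumerate(smiles_list):
        given_id = ids[i] if ids is not None else None
        try:
            std = standardize_molecule(smi, stereo=stereo)
        except ProtacDecError as exc:
            logger.warning("skipping unparseable library row %d (%r): %s", i, smi, exc)
            continue
        if std.smiles_canonical in seen:
            logger.warning(
                "duplicate library entry %r (canonical %s) collapsed to first occurrence",
                smi,
                std.smiles_canonical,
            )
            continue
        seen[std.smiles_canonical] = Fragment(
            id=given_id or "",
            smiles_input=smi,
            smiles_canonical=std.smiles_canonical,
            role=role,
            n_heavy=std.n_heavy,
            n_rings=std.n_rings,
            mol=std.mol,
        )
    if not seen:
        raise LibraryError(f"no parseable fragments for {role} library ({source_path or 'in-memory'})")

    ordered = sorted(seen.values(), key=_order_key)
    prefix = "W" if role == "warhead" else "E"
    final = tuple(
        f if f.id else replace(f, id=f"{prefix}{i + 1:04d}") for i, f in enumerate(ordered)
    )
    return FragmentLibrary(role=role, fragments=final, source_path=source_path)


def _read_rows(path: Path) -> tuple[list[str], list[Optional[str]]]:
    """Read (smiles, id) rows from a CSV or a plain SMILES file."""
    text = path.read_text()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    looks_csv = path.suffix.lower() == ".csv" or (
        "," in first and "smiles" in first.lower()
    )
    if looks_csv:
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
        smiles_col = next(
            (c for c in ("smiles", "smiles_canonical", "smiles_input") if c in df.columns),
            None,
        )
        if smiles_col is None:
            raise LibraryError(f"{path}: CSV has no smiles column (columns: {list(df.columns)})")
        smiles = df[smiles_col].astype(str).tolist()
        ids: list[Optional[str]]
        if "id" in df.columns:
            ids = [None if pd.isna(v) else str(v) for v in df["id"]]
        else:
            ids = [None] * len(smiles)
        return smiles, ids
    smiles, ids = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        smiles.append(tokens[0])
        ids.append(tokens[1] if len(tokens) > 1 else None)
    return smiles, ids


def load_library(path: str | Path, role: Role, stereo: StereoMode = "ignore") -> FragmentLibrary:
    """Load a fragment library from a SMILES file or CSV.

    Plain files hold one SMILES per line with an optional whitespace-separated
    id token; CSVs need at least a ``smiles`` column (an ``id`` column is
    honoured). Loading the library's own serialized output reproduces it.
    """
    path = Path(path)
    try:
        smiles, ids = _read_rows(path)
    except OSError as exc:
        raise LibraryError(f"cannot read library file {path}: {exc}") from exc
    return library_from_smiles(smiles, role, ids=ids, source_path=str(path), stereo=stereo)


def write_library(lib: FragmentLibrary, path: str | Path) -> None:
    """Serialize a library as CSV; ``load_library`` on the output round-trips."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles_input", "smiles_canonical", "n_heavy", "n_rings"])
        for f in lib.fragments:
            writer.writerow([f.id, f.smiles_input, f.smiles_canonical, f.n_heavy, f.n_rings])


def validate_library(
    lib: FragmentLibrary, min_heavy: int = MIN_FRAGMENT_HEAVY_ATOMS
) -> list[str]:
    """Return human-readable diagnostics; never mutates the library.

    Flags fragments below the minimum heavy-atom threshold, entries whose
    canonical SMILES is disconnected (should be impossible after
    standardization), and duplicated ids.
    """
    diagnostics: list[str] = []
    seen_ids: dict[str, str] = {}
    for f in lib.fragments:
        if f.n_heavy < min_heavy:
            diagnostics.append(
                f"{f.id}: only {f.n_heavy} heavy atoms (minimum {min_heavy})"
            )
        if "." in f.smiles_canonical:
            diagnostics.append(f"{f.id}: disconnected structure {f.smiles_canonical}")
        if f.id in seen_ids:
            diagnostics.append(
                f"duplicate id {f.id!r} ({seen_ids[f.id]} and {f.smiles_canonical})"
            )
        else:
            seen_ids[f.id] = f.smiles_canonical
    return diagnostics
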