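"""Batch decomposition driver.

Reads a degrader dataset (CSV with ``smiles`` and optional ``id`` columns, or
a plain SMILES file), decomposes every row against the supplied warhead and
E3 libraries, and writes solved rows to one file and unresolved rows — with
their failure category — to another, so that users can expand their
libraries in a targeted way. Re-running on the same inputs produces
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .decompose import (
    FAILURE_CATEGORIES,
    INPUT_ERROR,
    DecompositionReport,
    bidirectional_decompose,
)
from .errors import InputError
from .library import FragmentLibrary, load_library
from .standardize import StereoMode

logger = logging.getLogger(__name__)

SOLVED_COLUMNS = [
    "protac_id", "protac_smiles", "status", "n_solutions", "solution_index",
    "warhead_id", "warhead_smiles", "linker_smiles", "e3_id", "e3_smiles",
]
UNRESOLVED_COLUMNS = ["protac_id", "protac_smiles", "status", "failure_category"]


@dataclass
class BatchConfig:
    """Everything one batch run needs; all paths must be distinct."""

    input_path: str
    warhead_lib_path: str
    e3_lib_path: str
    output_path: str
    unresolved_path: str
    emit_all_solutions: bool = True
    stereo_mode: StereoMode = "ignore"
    min_fragment_heavy_atoms: int = 3
    log_level: str = "INFO"
    summary_json_path: Optional[str] = None

    def __post_init__(self) -> None:
        paths = [
            self.input_path, self.warhead_lib_path, self.e3_lib_path,
            self.output_path, self.unresolved_path,
        ]
        if len(set(paths)) != len(paths):
            raise InputError("batch paths must all be distinct")
        if self.min_fragment_heavy_atoms < 1:
            raise InputError("min_fragment_heavy_atoms must be >= 1")


def read_input_records(path: str | Path) -> list[tuple[str, str]]:
    """(id, smiles) pairs from a CSV or plain SMILES file.

    CSVs need a ``smiles`` column; a missing ``id`` column (and plain SMILES
    files) get row-number ids. Raises on a missing smiles column or on a file
    with zero rows.
    """
    path = Path(path)
    text = path.read_text()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    looks_csv = path.suffix.lower() == ".csv" or ("," in first and "smiles" in first.lower())
    records: list[tuple[str, str]] = []
    if looks_csv:
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
        if "smiles" not in df.columns:
            raise InputError(f"{path}: input CSV has no 'smiles' column")
        for i, row in df.iterrows():
            rid = str(row["id"]) if "id" in df.columns and not pd.isna(row["id"]) else f"row{i + 1}"
            records.append((rid, str(row["smiles"])))
    else:
        for i, line in enumerate(text.splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            rid = tokens[1] if len(tokens) > 1 else f"row{len(records) + 1}"
            records.append((rid, tokens[0]))
    if not records:
        raise InputError(f"{path}: no input rows")
    return records


def _filtered_library(lib: FragmentLibrary, min_heavy: int) -> FragmentLibrary:
    kept = tuple(f for f in lib.fragments if f.n_heavy >= min_heavy)
    dropped = len(lib) - len(kept)
    if dropped:
        logger.warning(
            "dropping %d %s fragment(s) below %d heavy atoms", dropped, lib.role, min_heavy
        )
    if not kept:
        raise InputError(
            f"{lib.role} library empty after the {min_heavy}-heavy-atom size filter"
        )
    return FragmentLibrary(role=lib.role, fragments=kept, source_path=lib.source_path)


def _solved_rows(report: DecompositionReport, emit_all: bool) -> list[dict]:
    sols = report.solutions if emit_all else report.solutions[:1]
    return [
        {
            "protac_id": report.protac_id,
            "protac_smiles": report.protac_smiles_canonical,
            "status": report.status,
            "n_solutions": len(report.solutions),
            "solution_index": i,
            "warhead_id": s.warhead.id,
            "warhead_smiles": s.warhead.smiles_canonical,
            "linker_smiles": s.linker_smiles,
            "e3_id": s.e3_ligand.id,
            "e3_smiles": s.e3_ligand.smiles_canonical,
        }
        for i, s in enumerate(sols)
    ]


def run_batch(config: BatchConfig) -> dict:
    """Run one batch; returns (and optionally writes) the summary record.

    Every parseable input row ends up in exactly one of the two output files;
    counts satisfy ``n_input = n_solved + n_failed + n_parse_errors`` and the
    per-category failure counts sum to ``n_failed``.
    """
    records = read_input_records(config.input_path)
    warheads = _filtered_library(
        load_library(config.warhead_lib_path, "warhead", stereo=config.stereo_mode),
        config.min_fragment_heavy_atoms,
    )
    e3s = _filtered_library(
        load_library(config.e3_lib_path, "e3_ligand", stereo=config.stereo_mode),
        config.min_fragment_heavy_atoms,
    )

    solved_rows: list[dict] = []
    unresolved_rows: list[dict] = []
    failure_counts = {c: 0 for c in FAILURE_CATEGORIES}
    n_parse_errors = 0
    n_multi = 0
    for rid, smiles in records:
        report = bidirectional_decompose(
            smiles, warheads, e3s, stereo=config.stereo_mode, protac_id=rid
        )
        if report.solved:
            solved_rows.extend(_solved_rows(report, config.emit_all_solutions))
            if len(report.solutions) > 1:
                n_multi += 1
        else:
            if report.failure_category == INPUT_ERROR:
                n_parse_errors += 1
            else:
                failure_counts[report.failure_category] += 1
            unresolved_rows.append(
                {
                    "protac_id": rid,
                    "protac_smiles": report.protac_smiles_canonical,
                    "status": report.status,
                    "failure_category": report.failure_category,
                }
            )

    pd.DataFrame(solved_rows, columns=SOLVED_COLUMNS).to_csv(config.output_path, index=False)
    pd.DataFrame(unresolved_rows, columns=UNRESOLVED_COLUMNS).to_csv(
        config.unresolved_path, index=False
    )

    n_solved = len({r["protac_id"] for r in solved_rows})
    summary = {
        "n_input": len(records),
        "n_solved": n_solved,
        "n_failed": sum(failure_counts.values()),
        "n_parse_errors": n_parse_errors,
        "n_multi_solution": n_multi,
        "failure_counts": failure_counts,
    }
    if config.summary_json_path:
        Path(config.summary_json_path).write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
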