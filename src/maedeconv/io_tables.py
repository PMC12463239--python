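"""Tabular I/O for peptide identification tables and identification-level filters.

The pipeline starts *after* database searching: its input is a flat table
with one row per observed peptide (sequence, provenance, spectral count,
cell line, replicate).  Different search engines name these columns
differently, so reading is driven by a *dialect* -- a mapping from the
logical field names used throughout this package to the column names of a
particular export.  Protein coordinates are 1-based inclusive (UniProt
convention) and are converted at this boundary only.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: the 20 standard amino acids; B, J, O, U, X, Z are rejected on input
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: logical fields every dialect must map
REQUIRED_FIELDS = ("sequence", "cell_line", "replicate", "spectral_count")
OPTIONAL_FIELDS = ("protein_id", "start", "end", "intensity")

#: built-in column mappings for common export styles
DIALECTS: dict[str, dict[str, str]] = {
    "default": {
        "sequence": "sequence",
        "protein_id": "protein_id",
        "start": "start",
        "end": "end",
        "cell_line": "cell_line",
        "replicate": "replicate",
        "spectral_count": "spectral_count",
        "intensity": "intensity",
    },
    "maxquant": {
        "sequence": "Sequence",
        "protein_id": "Leading razor protein",
        "start": "Start position",
        "end": "End position",
        "cell_line": "Experiment",
        "replicate": "Replicate",
        "spectral_count": "MS/MS count",
        "intensity": "Intensity",
    },
    "fragpipe": {
        "sequence": "Peptide",
        "protein_id": "Protein ID",
        "start": "Start",
        "end": "End",
        "cell_line": "Experiment",
        "replicate": "Replicate",
        "spectral_count": "Spectral Count",
        "intensity": "Intensity",
    },
}


@dataclasses.dataclass(frozen=True)
class PeptideRecord:
    """One observed peptide in one (cell line, replicate).

    Coordinates, when present, are 1-based inclusive on the source protein,
    so ``end - start + 1 == len(sequence)``.
    """

    sequence: str
    cell_line: str
    replicate: str
    spectral_count: int
    protein_id: str | None = None
    start: int | None = None
    end: int | None = None
    intensity: float | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"peptide sequence must be uppercase: {self.sequence!r}")
        bad = set(self.sequence) - STANDARD_AA
        if bad:
            raise ValueError(
                f"sequence {self.sequence!r} contains non-standard residue(s) "
                f"{''.join(sorted(bad))!r}"
            )
        if self.spectral_count < 0:
            raise ValueError("spectral_count must be >= 0")
        if (self.start is None) != (self.end is None):
            raise ValueError("start and end must be given together")
        if self.start is not None:
            if self.end - self.start + 1 != len(self.sequence):
                raise ValueError(
                    f"coordinates {self.start}-{self.end} inconsistent with "
                    f"length {len(self.sequence)} of {self.sequence!r}"
                )
        if self.intensity is not None and self.intensity < 0:
            raise ValueError("intensity must be >= 0")

    @property
    def has_coordinates(self) -> bool:
        return self.start is not None and self.protein_id is not None


def resolve_dialect(dialect: str | Mapping[str, str] | None) -> dict[str, str]:
    """Return a field->column mapping from a name or an explicit mapping."""
    if dialect is None:
        return dict(DIALECTS["default"])
    if isinstance(dialect, str):
        try:
            return dict(DIALECTS[dialect])
        except KeyError:
            raise KeyError(
                f"unknown dialect {dialect!r}; built-ins: {sorted(DIALECTS)}"
            ) from None
    mapping = dict(dialect)
    missing = [f for f in REQUIRED_FIELDS if f not in mapping]
    if missing:
        raise ValueError(f"dialect is missing required field mappings: {missing}")
    return mapping


def read_peptide_table(
    path: str | Path, dialect: str | Mapping[str, str] | None = None
) -> list[PeptideRecord]:
    """Read a TSV peptide table into records, preserving row order.

    Raises a ``ValueError`` naming the (1-based, header-excluded) row number
    for malformed rows, including sequences with non-standard letters.
    """
    mapping = resolve_dialect(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [mapping[f] for f in REQUIRED_FIELDS if mapping[f] not in df.columns]
    if missing:
        raise ValueError(f"peptide table {path} lacks required column(s): {missing}")
    have = {f: mapping.get(f) in df.columns for f in OPTIONAL_FIELDS}

    records: list[PeptideRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        try:
            kwargs: dict = {
                "sequence": row[mapping["sequence"]].strip(),
                "cell_line": row[mapping["cell_line"]].strip(),
                "replicate": row[mapping["replicate"]].strip(),
                "spectral_count": int(row[mapping["spectral_count"]]),
            }
            if have["protein_id"] and row[mapping["protein_id"]] != "":
                kwargs["protein_id"] = row[mapping["protein_id"]].strip()
            if have["start"] and have["end"] and row[mapping["start"]] != "":
                kwargs["start"] = int(row[mapping["start"]])
                kwargs["end"] = int(row[mapping["end"]])
            if have["intensity"] and row[mapping["intensity"]] != "":
                kwargs["intensity"] = float(row[mapping["intensity"]])
            records.append(PeptideRecord(**kwargs))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"malformed peptide table row {i}: {exc}") from exc
    return records


def write_peptide_table(
    records: Iterable[PeptideRecord], path: str | Path
) -> None:
    """Write records as TSV in the ``default`` dialect (round-trip exact)."""
    rows = []
    for r in records:
        rows.append(
            {
                "sequence": r.sequence,
                "protein_id": "" if r.protein_id is None else r.protein_id,
                "start": "" if r.start is None else r.start,
                "end": "" if r.end is None else r.end,
                "cell_line": r.cell_line,
                "replicate": r.replicate,
                "spectral_count": r.spectral_count,
                "intensity": "" if r.intensity is None else repr(r.intensity),
            }
        )
    pd.DataFrame(rows, columns=list(DIALECTS["default"].values())).to_csv(
        path, sep="\t", index=False
    )


def replicate_consistency_filter(
    records: Sequence[PeptideRecord], min_reps: int = 2, total_reps: int = 3
) -> list[PeptideRecord]:
    """Keep peptides identified in at least ``min_reps`` replicates of a line.

    A (sequence, cell line) pair is retained iff the peptide was observed
    with a positive spectral count in >= ``min_reps`` distinct replicates of
    that cell line; retention is decided per cell line independently.  A row
    with spectral count 0 counts as not observed.  Records are returned
    unmodified, in their input order.
    """
    if min_reps < 1:
        raise ValueError("min_reps must be >= 1")
    if min_reps > total_reps:
        raise ValueError(
            f"min_reps ({min_reps}) cannot exceed total_reps ({total_reps})"
        )
    seen: dict[tuple[str, str], set[str]] = defaultdict(set)
    for r in records:
        if r.spectral_count > 0:
            seen[(r.sequence, r.cell_line)].add(r.replicate)
    return [
        r
        for r in records
        if len(seen.get((r.sequence, r.cell_line), ())) >= min_reps
    ]
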