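"""Abundance indices: Peptide Index, Epitope Index matrix, knockdown ratios.

The Peptide Index (P_i) of a peptide in a cell line is its average spectral
count over that line's replicates; the mean is zero-inclusive (divide by
the total replicate number, counting replicates where the peptide is
absent as 0) so that P_i is comparable across peptides with different
detection rates.  The Epitope Index (E_i) of an epitope is the sum of the
P_i of its constituent peptides; arranged over a panel of cell lines these
form the E_i matrix that drives clustering and allele deconvolution.

The knockdown comparison classifies each peptide by its knockdown/control
intensity ratio: peptides exclusive to one sample get sentinel ratios (50
when absent from control, 0.02 when absent from knockdown), and a peptide
is *affected* when its ratio falls at or below the measured knockdown
factor (the fraction of target protein remaining, 0.21 by default).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .epitope_assembly import Epitope
from .io_tables import PeptideRecord


@dataclasses.dataclass
class EiMatrix:
    """Epitopes x cell lines matrix of Epitope Index values."""

    epitope_ids: list[str]
    cell_lines: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.epitope_ids), len(self.cell_lines)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.epitope_ids)} epitopes x {len(self.cell_lines)} lines"
            )
        if (self.values < 0).any():
            raise ValueError("E_i values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.epitope_ids, columns=self.cell_lines
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EiMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def row(self, epitope_id: str) -> np.ndarray:
        return self.values[self.epitope_ids.index(epitope_id)]

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="epitope_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "EiMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col="epitope_id"))


def peptide_index(
    records: Iterable[PeptideRecord], cell_line: str, total_reps: int
) -> dict[str, float]:
    """P_i per sequence for one cell line: summed counts / total replicates.

    Sequences never observed in the cell line are simply absent from the
    returned map (their P_i is 0 by convention).
    """
    if total_reps <= 0:
        raise ValueError("total_reps must be positive")
    sums: dict[str, int] = {}
    for r in records:
        if r.cell_line == cell_line:
            sums[r.sequence] = sums.get(r.sequence, 0) + r.spectral_count
    return {seq: s / total_reps for seq, s in sums.items()}


def peptide_index_all(
    records: Sequence[PeptideRecord], cell_lines: Sequence[str], total_reps: int
) -> dict[str, dict[str, float]]:
    """P_i maps for every cell line of a panel, in panel order."""
    return {c: peptide_index(records, c, total_reps) for c in cell_lines}


def epitope_index_matrix(
    epitopes: Sequence[Epitope],
    pi_maps: Mapping[str, Mapping[str, float]],
    cell_lines: Sequence[str] | None = None,
) -> EiMatrix:
    """E_i(e, c) = sum of P_i over e's constituent sequences in line c.

    ``pi_maps`` maps cell line -> (sequence -> P_i); sequences missing from
    a line's map contribute 0 (unobserved).  Conservation holds exactly:
    summing E_i over the epitopes of a partition returns the summed P_i of
    all their peptides, per cell line.
    """
    lines = list(cell_lines) if cell_lines is not None else sorted(pi_maps)
    for c in lines:
        if c not in pi_maps:
            raise ValueError(f"no P_i map for cell line {c!r}")
    known = set().union(*(set(pi_maps[c]) for c in lines)) if lines else set()
    ids = [e.epitope_id for e in epitopes]
    values = np.zeros((len(ids), len(lines)))
    for i, ep in enumerate(epitopes):
        for seq in ep.constituent_sequences:
            if seq not in known:
                raise ValueError(
                    f"constituent {seq!r} of epitope {ep.epitope_id} has no "
                    f"P_i entry in any cell line"
                )
        for j, c in enumerate(lines):
            values[i, j] = sum(
                pi_maps[c].get(seq, 0.0) for seq in ep.constituent_sequences
            )
    return EiMatrix(ids, lines, values)


@dataclasses.dataclass(frozen=True)
class KnockdownCall:
    ratio: float
    affected: bool


def normalize_intensities(
    intensities: Mapping[str, float], target_total: float = 1e6
) -> dict[str, float]:
    """Per-sample total-intensity scaling to a common sum."""
    total = float(sum(intensities.values()))
    if total <= 0:
        raise ValueError("total intensity must be positive")
    return {k: v * target_total / total for k, v in intensities.items()}


def knockdown_classification(
    kd: Mapping[str, float],
    ctrl: Mapping[str, float],
    exclusive_high: float = 50.0,
    exclusive_low: float = 0.02,
    knockdown_factor: float = 0.21,
) -> dict[str, KnockdownCall]:
    """Classify each peptide of the union as knockdown-affected or not.

    ratio = kd/ctrl when present in both samples; a peptide exclusive to
    the knockdown gets the arbitrary high ratio (default 50), one exclusive
    to the control the reciprocal low ratio (default 0.02).  Affected iff
    ratio <= ``knockdown_factor``.
    """
    if knockdown_factor <= 0:
        raise ValueError("knockdown_factor must be positive")
    calls: dict[str, KnockdownCall] = {}
    for seq in sorted(set(kd) | set(ctrl)):
        in_kd = seq in kd and kd[seq] > 0
        in_ctrl = seq in ctrl and ctrl[seq] > 0
        if in_kd and in_ctrl:
            ratio = kd[seq] / ctrl[seq]
        elif in_kd:
            ratio = exclusive_high
        elif in_ctrl:
            ratio = exclusive_low
        else:
            continue
        calls[seq] = KnockdownCall(ratio=ratio, affected=ratio <= knockdown_factor)
    return calls
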