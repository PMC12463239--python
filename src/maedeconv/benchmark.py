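"""Benchmarking retained/rejected epitope sets against binder predictions.

External predictors (NetMHCpan for 9-11-mers, NetMHCIIpan for longer
epitopes) tag each sequence as a strong binder, weak binder or non-binder
against a set of queried alleles.  Those calls are ingested -- never
computed -- and a retained/rejected split is scored against them: a
sequence is a *binder* iff it is a strong or weak binder for at least one
queried allele; retained binders are true positives, retained non-binders
false positives, and precision is TP / (TP + FP), the positive predictive
value of the filtering scheme.  Random peptides drawn uniformly over the
20 standard amino acids serve as a negative control.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_tables import STANDARD_AA

CALLS = ("strong", "weak", "none")


@dataclasses.dataclass(frozen=True)
class BinderAnnotation:
    sequence: str
    allele: str
    call: str

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValueError(f"call must be one of {CALLS}, got {self.call!r}")


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion_and_precision(
    retained: Iterable[str],
    rejected: Iterable[str],
    annotations: Iterable[BinderAnnotation],
    queried_alleles: Iterable[str],
) -> tuple[ConfusionCounts, float]:
    """Score a retained/rejected split against binder annotations.

    Precision = TP / (TP + FP); when nothing is retained it is undefined
    and returned as NaN with a warning.  Every sequence must be annotated
    against at least one queried allele.
    """
    retained = set(retained)
    rejected = set(rejected)
    overlap = retained & rejected
    if overlap:
        raise ValueError(f"sequences both retained and rejected: {sorted(overlap)[:5]}")
    queried = set(queried_alleles)

    binder: dict[str, bool] = {}
    for ann in annotations:
        if ann.allele not in queried:
            continue
        binder[ann.sequence] = binder.get(ann.sequence, False) or (
            ann.call in ("strong", "weak")
        )
    missing = (retained | rejected) - set(binder)
    if missing:
        raise ValueError(
            f"sequence(s) lack annotations for the queried alleles: "
            f"{sorted(missing)[:5]}"
        )

    tp = sum(1 for s in retained if binder[s])
    fp = len(retained) - tp
    fn = sum(1 for s in rejected if binder[s])
    tn = len(rejected) - fn
    counts = ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)
    if tp + fp == 0:
        warnings.warn("no retained sequences: precision is undefined")
        return counts, math.nan
    return counts, tp / (tp + fp)


def random_peptides(
    n: int, length_range: tuple[int, int], seed: int
) -> list[str]:
    """Random negative-control peptides: residues uniform over the 20
    standard amino acids, lengths uniform over ``length_range`` inclusive."""
    lo, hi = length_range
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid length range [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    letters = np.array(sorted(STANDARD_AA))
    out = []
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        out.append("".join(rng.choice(letters, size=length)))
    return out


def read_binder_annotations(
    path: str | Path,
    strong_rank: float = 0.5,
    weak_rank: float = 2.0,
    sequence_col: str = "peptide",
    allele_col: str = "allele",
    rank_col: str = "rank",
) -> list[BinderAnnotation]:
    """Parse a predictor's tab-separated %Rank output into annotations.

    Rows with rank <= ``strong_rank`` become strong binders, <= ``weak_rank``
    weak binders, everything else non-binders.  The defaults are the
    conventional class I rank cutoffs (0.5 / 2.0); class II output is
    usually parsed with 1 / 5.  These are parser thresholds applied to an
    external tool's output, not predictions made here.
    """
    if not (0 < strong_rank <= weak_rank):
        raise ValueError("need 0 < strong_rank <= weak_rank")
    df = pd.read_csv(path, sep="\t")
    cols = {c.lstrip("%").strip().lower(): c for c in df.columns}
    try:
        seq_c = cols[sequence_col.lower()]
        allele_c = cols[allele_col.lower()]
        rank_c = cols[rank_col.lower()]
    except KeyError as exc:
        raise ValueError(f"annotation table lacks column {exc}") from None
    out = []
    for _, row in df.iterrows():
        rank = float(row[rank_c])
        call = "strong" if rank <= strong_rank else "weak" if rank <= weak_rank else "none"
        out.append(
            BinderAnnotation(sequence=str(row[seq_c]), allele=str(row[allele_c]), call=call)
        )
    return out


def write_binder_annotations(
    annotations: Sequence[BinderAnnotation], path: str | Path
) -> None:
    pd.DataFrame(
        [dataclasses.asdict(a) for a in annotations],
        columns=["sequence", "allele", "call"],
    ).to_csv(path, sep="\t", index=False)
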