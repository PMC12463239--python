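"""Offset-only multiple alignment of the epitopes in a node.

At MHC peptide lengths, alignment with a prohibitive gap-open penalty
degenerates to sliding ungapped sequences against each other; this module
makes that regime explicit.  Each sequence gets a single integer offset
(terminal gaps only, unpenalized) and the alignment width is capped --
12 columns for MHC I nodes (9-11-mer epitopes), 30 for MHC II -- because
longer alignments of ragged class II ligands degrade badly.

Placement is progressive: the seed is the most abundant epitope (highest
total E_i; ties: longest, then lexicographically smallest), and each
remaining sequence in the same priority order takes the integer offset
that maximizes its summed substitution score (BLOSUM62 by default) against
the current column profile, subject to the width cap.  Offset ties prefer
the smaller resulting width, then the smaller offset.  Offsets already
assigned never change.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class NodeAlignment:
    """Gapless (offset-only) alignment of a node's epitope sequences."""

    node_id: str
    sequences: list[str]
    offsets: list[int]
    width: int
    score: float

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.offsets):
            raise ValueError("one offset per sequence required")
        if min(self.offsets, default=0) != 0:
            raise ValueError("offsets must be normalized to min 0")
        if self.width != max(
            o + len(s) for o, s in zip(self.offsets, self.sequences)
        ):
            raise ValueError("width inconsistent with offsets")

    def rows(self) -> list[str]:
        """Sequences padded with '-' to the alignment width."""
        return [
            "-" * o + s + "-" * (self.width - o - len(s))
            for o, s in zip(self.offsets, self.sequences)
        ]

    def columns(self) -> list[list[str]]:
        """Per-column residue lists (gaps excluded)."""
        cols: list[list[str]] = [[] for _ in range(self.width)]
        for o, s in zip(self.offsets, self.sequences):
            for i, aa in enumerate(s):
                cols[o + i].append(aa)
        return cols


def load_matrix(name: str = "BLOSUM62"):
    return substitution_matrices.load(name)


def sum_of_pairs_score(
    sequences: Sequence[str], offsets: Sequence[int], matrix
) -> float:
    """Sum of substitution scores over all pairs in co-occupied columns.

    Columns where a sequence has no residue contribute nothing to its
    pairwise terms (terminal gaps are free).
    """
    width = max(o + len(s) for o, s in zip(offsets, sequences))
    total = 0.0
    for col in range(min(offsets), width):
        residues = [
            s[col - o]
            for o, s in zip(offsets, sequences)
            if 0 <= col - o < len(s)
        ]
        for i in range(len(residues)):
            for j in range(i + 1, len(residues)):
                total += matrix[residues[i]][residues[j]]
    return total


def align_node(
    sequences: Sequence[str],
    max_len: int,
    matrix: str = "BLOSUM62",
    weights: Sequence[float] | None = None,
    node_id: str = "",
) -> NodeAlignment:
    """Progressively place each sequence at its best-scoring offset.

    ``weights`` (typically each epitope's total E_i) set the placement
    priority; without them, priority falls back to length then lexicographic
    order.  A sequence longer than ``max_len`` is an error -- such epitopes
    should have been excluded upstream by the class length filter.
    """
    if len(sequences) < 2:
        raise ValueError("alignment needs >= 2 sequences")
    for s in sequences:
        if len(s) > max_len:
            raise ValueError(
                f"sequence {s!r} (length {len(s)}) exceeds the alignment "
                f"cap {max_len}"
            )
    if weights is not None and len(weights) != len(sequences):
        raise ValueError("one weight per sequence required")
    sub = load_matrix(matrix)

    w = list(weights) if weights is not None else [0.0] * len(sequences)
    order = sorted(
        range(len(sequences)),
        key=lambda i: (-w[i], -len(sequences[i]), sequences[i]),
    )

    placed: dict[int, int] = {order[0]: 0}
    lo, hi = 0, len(sequences[order[0]])  # current occupied span
    profile: dict[int, dict[str, int]] = {
        i: {aa: 1} for i, aa in enumerate(sequences[order[0]])
    }
    for idx in order[1:]:
        seq = sequences[idx]
        best: tuple[float, int, int] | None = None  # (-score, width, offset)
        for off in range(lo - max_len, hi + max_len + 1):
            new_w = max(hi, off + len(seq)) - min(lo, off)
            if new_w > max_len:
                continue
            score = 0.0
            for i, aa in enumerate(seq):
                col = profile.get(off + i)
                if col:
                    score += sum(sub[aa][r] * c for r, c in col.items())
            key = (-score, new_w, off)
            if best is None or key < best:
                best = key
        # a feasible offset always exists when len(seq) <= max_len
        _neg, _w, off = best
        placed[idx] = off
        lo, hi = min(lo, off), max(hi, off + len(seq))
        for i, aa in enumerate(seq):
            col = profile.setdefault(off + i, {})
            col[aa] = col.get(aa, 0) + 1

    base = min(placed.values())
    offsets = [placed[i] - base for i in range(len(sequences))]
    score = sum_of_pairs_score(sequences, offsets, sub)
    return NodeAlignment(
        node_id=node_id,
        sequences=list(sequences),
        offsets=offsets,
        width=max(o + len(s) for o, s in zip(offsets, sequences)),
        score=score,
    )


def write_clustal(alignment: NodeAlignment, path: str | Path, names=None) -> None:
    names = names or [f"seq{i + 1}" for i in range(len(alignment.sequences))]
    pad = max(len(n) for n in names) + 2
    with open(path, "w") as fh:
        fh.write("CLUSTAL multiple sequence alignment (offset-only)\n\n")
        for name, row in zip(names, alignment.rows()):
            fh.write(f"{name:<{pad}}{row}\n")


def write_fasta_alignment(alignment: NodeAlignment, path: str | Path, names=None) -> None:
    names = names or [f"seq{i + 1}" for i in range(len(alignment.sequences))]
    with open(path, "w") as fh:
        for name, row in zip(names, alignment.rows()):
            fh.write(f">{name}\n{row}\n")
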