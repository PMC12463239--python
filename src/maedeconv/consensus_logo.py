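"""Per-column logo statistics and one-line consensus rendering.

For every alignment column this module computes the sequence-logo
quantities -- weight W (occupancy), information content E in bits with the
standard small-sample correction, and a lower 95% confidence bound L on E
from a seeded multinomial bootstrap -- and from them the two scores that
condense a logo into one line of text per node:

* the Amino Acid Positional Score  ``S = (A_x / N_n) * E * W``  of residue
  x at position n, where A_x is the residue's count and N_n the non-gap
  total of the column; and
* the Positional Threshold Score  ``R = E - L``.

A residue is significant at its position when ``S > R``.  Residues that
fail individually may still pass *grouped*: a physicochemical group is
significant when the summed S of its members exceeds R while no member
passes alone.  Positions with nothing significant are null, rendered as a
dash, which turns each node's logo into a compact regular-expression-like
consensus line; summarized views keep only the top-4 S entries.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np

from .io_tables import STANDARD_AA
from .node_alignment import NodeAlignment

N_ALPHABET = 20

#: physicochemical residue groups used for grouped significance
DEFAULT_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("AVLIM"),   # aliphatic / hydrophobic
    frozenset("FWY"),     # aromatic
    frozenset("KRH"),     # basic
    frozenset("DE"),      # acidic
    frozenset("STNQ"),    # polar uncharged
    frozenset("C"),
    frozenset("GP"),      # conformationally special
)


@dataclasses.dataclass
class LogoColumn:
    """All per-column logo statistics for one alignment position (1-based)."""

    position: int
    counts: dict[str, int]
    N_n: int
    M: int
    W: float = 0.0
    E: float = 0.0
    L: float = 0.0
    S: dict[str, float] = dataclasses.field(default_factory=dict)
    R: float = 0.0
    significant: frozenset[str] = frozenset()
    significant_groups: tuple[frozenset[str], ...] = ()
    null: bool = False

    @property
    def is_null(self) -> bool:
        return self.null or (not self.significant and not self.significant_groups)


def _information_content(counts: Sequence[int], n: int) -> float:
    """Bits of a column: log2(20) - H - e_n, clamped at 0.

    e_n = 19 / (2 ln2 n) is the small-sample (compositional bias)
    correction for n observations over a 20-letter alphabet.
    """
    p = np.asarray(counts, dtype=float) / n
    p = p[p > 0]
    h = float(-(p * np.log2(p)).sum())
    e_n = (N_ALPHABET - 1) / (2.0 * math.log(2.0) * n)
    return max(0.0, math.log2(N_ALPHABET) - h - e_n)


def column_stats(
    residues: Iterable[str],
    M: int,
    position: int = 1,
    bootstrap_reps: int = 200,
    seed: int = 0,
) -> LogoColumn:
    """Compute counts, W, E and the bootstrap lower bound L for one column.

    ``residues`` is the column's multiset; '-' entries are gaps and do not
    count toward N_n.  An all-gap column is returned as null.  L is the
    lower 95% confidence bound on E from a seeded multinomial bootstrap
    (``bootstrap_reps`` resamples of size N_n from the observed
    frequencies): L = E minus half the central 95% interval width of the
    resampled E*.  Centering the interval on E rather than taking the raw
    2.5th percentile of E* matters on low-information columns, where the
    plugin entropy of a resample is biased low, E* overshoots E, and the
    raw percentile would sit at or above the point estimate -- collapsing
    the threshold R to zero and flagging pure noise columns as
    significant.  L is floored at 0 and capped at E; with a fixed seed
    the bound is fully reproducible.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    counts: dict[str, int] = {}
    for aa in residues:
        if aa == "-":
            continue
        if aa not in STANDARD_AA:
            raise ValueError(f"non-standard residue {aa!r} in column")
        counts[aa] = counts.get(aa, 0) + 1
    n = sum(counts.values())
    if n == 0:
        return LogoColumn(position=position, counts={}, N_n=0, M=M, null=True)
    if n > M:
        raise ValueError(f"column holds {n} residues but alignment has M={M}")

    w = n / M
    letters = sorted(counts)
    vec = [counts[a] for a in letters]
    e = _information_content(vec, n)

    rng = np.random.default_rng(seed)
    p = np.asarray(vec, dtype=float) / n
    resamples = rng.multinomial(n, p, size=bootstrap_reps)
    boot = np.array([_information_content(row, n) for row in resamples])
    q025, q975 = np.percentile(boot, [2.5, 97.5])
    l = e - float(q975 - q025) / 2.0
    l = min(max(l, 0.0), e)  # bound stays within [0, E]
    return LogoColumn(position=position, counts=counts, N_n=n, M=M, W=w, E=e, L=l)


def positional_scores(col: LogoColumn) -> LogoColumn:
    """Fill S_x = (A_x / N_n) * E * W for every observed residue."""
    if col.null:
        return col
    col.S = {aa: (a / col.N_n) * col.E * col.W for aa, a in col.counts.items()}
    return col


def positional_threshold(
    col: LogoColumn, groups: Sequence[frozenset[str]] = DEFAULT_GROUPS
) -> LogoColumn:
    """Fill R = E - L and flag significant residues and grouped residues.

    A residue is significant iff S_x > R (strict).  A group is significant
    iff the summed S of its members exceeds R while no member passes
    individually.
    """
    if col.null:
        return col
    col.R = col.E - col.L
    col.significant = frozenset(aa for aa, s in col.S.items() if s > col.R)
    sig_groups = []
    for g in groups:
        members = [aa for aa in g if col.S.get(aa, 0.0) > 0.0]
        if not members:
            continue
        if any(aa in col.significant for aa in members):
            continue
        if sum(col.S[aa] for aa in members) > col.R:
            sig_groups.append(frozenset(members))
    col.significant_groups = tuple(
        sorted(sig_groups, key=lambda g: "".join(sorted(g)))
    )
    return col


def score_alignment(
    alignment: NodeAlignment,
    bootstrap_reps: int = 200,
    seed: int = 0,
    groups: Sequence[frozenset[str]] = DEFAULT_GROUPS,
) -> list[LogoColumn]:
    """Full per-column scoring of a node alignment.

    Each column's bootstrap stream is derived from ``seed`` and the column
    position so that columns are independent yet the whole logo is
    reproducible.
    """
    m = len(alignment.sequences)
    cols = []
    for i, residues in enumerate(alignment.columns(), start=1):
        col = column_stats(
            residues, M=m, position=i,
            bootstrap_reps=bootstrap_reps,
            seed=(seed * 100003 + i) % (2**31),
        )
        positional_scores(col)
        positional_threshold(col, groups=groups)
        cols.append(col)
    return cols


# --- consensus rendering ----------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ConsensusEntry:
    residue: str          # one letter, or several for a grouped entry
    S: float
    grouped: bool
    shade: float          # grayscale in [0.2, 1.0]; 1.0 = 100% black


@dataclasses.dataclass
class ConsensusLine:
    """One-line consensus: per-position tokens (None = null position)."""

    tokens: list[list[ConsensusEntry] | None]
    style: str

    def text(self, detail: bool = False) -> str:
        """Plain-text serialization.

        Individually significant residues are uppercase; grouped-only
        residues lowercase.  Multiple entries at a position are bracketed
        in regular-expression style.  With ``detail``, each token carries
        its shade as a percentage.
        """
        if self.style == "top4":
            parts = []
            for pos, entries in enumerate(self.tokens, start=1):
                if entries:
                    for e in entries:
                        parts.append(f"{pos}{_entry_text(e, detail)}")
            return " ".join(parts)
        out = []
        for entries in self.tokens:
            if entries is None:
                out.append("-")
                continue
            text = "".join(_entry_text(e, detail) for e in entries)
            n_residues = sum(len(e.residue) for e in entries)
            # regular-expression convention: bracket any multi-residue token
            out.append(f"[{text}]" if n_residues > 1 else text)
        return "".join(out)


def _entry_text(e: ConsensusEntry, detail: bool) -> str:
    text = e.residue.upper() if not e.grouped else e.residue.lower()
    if detail:
        text += f":{round(e.shade * 100)}%"
    return text


def _shade(s: float) -> float:
    return min(max(s, 0.2), 1.0)


def _column_entries(col: LogoColumn) -> list[ConsensusEntry] | None:
    if col.is_null:
        return None
    entries = [
        ConsensusEntry(residue=aa, S=col.S[aa], grouped=False, shade=_shade(col.S[aa]))
        for aa in sorted(col.significant, key=lambda a: (-col.S[a], a))
    ]
    for g in col.significant_groups:
        members = sorted(g, key=lambda a: (-col.S[a], a))
        s_sum = sum(col.S[a] for a in members)
        entries.append(
            ConsensusEntry(
                residue="".join(members), S=s_sum, grouped=True, shade=_shade(s_sum)
            )
        )
    return entries or None


def render_consensus(
    columns: Sequence[LogoColumn], style: str = "full"
) -> ConsensusLine:
    """Render scored columns as a consensus line.

    ``full`` shows every position (dash when null); ``top4`` keeps only the
    four (position, residue) entries with the highest S among significant
    ones; ``top4_dashed`` additionally shows dashes for non-significant
    positions lying between the first and last retained ones.
    """
    if style not in ("full", "top4", "top4_dashed"):
        raise ValueError(f"unknown consensus style {style!r}")
    base = [_column_entries(c) for c in columns]
    if style == "full":
        return ConsensusLine(tokens=base, style=style)

    scored = [
        (e.S, pos, e)
        for pos, entries in enumerate(base)
        if entries
        for e in entries
    ]
    top = sorted(scored, key=lambda t: (-t[0], t[1], t[2].residue))[:4]
    keep: dict[int, list[ConsensusEntry]] = {}
    for _s, pos, e in top:
        keep.setdefault(pos, []).append(e)

    tokens: list[list[ConsensusEntry] | None] = [None] * len(columns)
    for pos, entries in keep.items():
        tokens[pos] = sorted(entries, key=lambda e: (-e.S, e.residue))
    if style == "top4":
        return ConsensusLine(tokens=tokens, style=style)
    # top4_dashed: trim to the retained span, dashes inside it
    if keep:
        first, last = min(keep), max(keep)
        tokens = tokens[first : last + 1]
    return ConsensusLine(tokens=tokens, style=style)


def write_column_table(columns: Sequence[LogoColumn], path) -> None:
    """WebLogo-style per-column TSV: position, 20 residue counts, E, L, W."""
    import pandas as pd

    letters = sorted(STANDARD_AA)
    rows = []
    for c in columns:
        row = {"position": c.position}
        row.update({aa: c.counts.get(aa, 0) for aa in letters})
        row.update({"E": c.E, "L": c.L, "W": c.W, "R": c.R})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_consensus_lines(lines: dict[str, ConsensusLine], path) -> None:
    """One node per line: node_id <TAB> consensus text."""
    with open(path, "w") as fh:
        for node_id in sorted(lines):
            fh.write(f"{node_id}\t{lines[node_id].text()}\n")
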