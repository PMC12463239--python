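"""Condense overlapping peptides into maximal epitopes and classify them.

Surface-eluted peptide sets are highly redundant: antigen processing and
sample handling produce many length variants of the same presented ligand.
Counting each variant as an independent ligand overstates sample
complexity, so overlapping peptides are coalesced into the longest possible
sequence -- the *epitope* -- which becomes the unit of all downstream
abundance, clustering and motif analysis.

Condensation runs in one of two modes:

* ``coordinates`` -- peptides sharing a source protein are merged whenever
  their 1-based [start, end] intervals overlap by at least one residue;
  each maximal connected component becomes one epitope spanning the union
  interval.
* ``string`` -- for tables without protein coordinates.  Two peptides
  overlap iff one contains the other or a suffix of one equals a prefix of
  the other with overlap length >= ``min_overlap``; components are merged
  into the unique maximal superstring.

Classification follows the identification filters: epitopes with a total
spectral count of 2 or fewer are removed, 9-11-mers form the MHC I group,
12-20-mers the MHC II group, and an MHC II epitope must be composed of
three or more distinct overlapping peptides (the nested-set hallmark of
class II ligands).  Peptides of 8 or fewer residues are rejected before
condensation.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io_tables import PeptideRecord

logger = logging.getLogger(__name__)

MHC_I = "I"
MHC_II = "II"
REJECTED = "rejected"


@dataclasses.dataclass(frozen=True)
class Epitope:
    """A condensed maximal sequence with its constituent peptide records."""

    epitope_id: str
    sequence: str
    constituents: tuple[PeptideRecord, ...]
    protein_id: str | None = None
    start: int | None = None
    end: int | None = None
    mhc_class: str | None = None

    def __post_init__(self) -> None:
        if not self.constituents:
            raise ValueError("epitope must have at least one constituent")
        for rec in self.constituents:
            if rec.sequence not in self.sequence:
                raise ValueError(
                    f"constituent {rec.sequence!r} is not a substring of "
                    f"epitope {self.sequence!r}"
                )

    @property
    def total_spectral_count(self) -> int:
        """Sum of spectral counts over all constituents, lines and replicates."""
        return sum(r.spectral_count for r in self.constituents)

    @property
    def constituent_sequences(self) -> frozenset[str]:
        return frozenset(r.sequence for r in self.constituents)

    @property
    def n_constituents(self) -> int:
        return len(self.constituent_sequences)


class CondensationError(ValueError):
    """Raised when a component's overlaps imply conflicting residues."""


def drop_short_peptides(
    records: Iterable[PeptideRecord], max_rejected_length: int = 8
) -> list[PeptideRecord]:
    """Reject peptides of ``max_rejected_length`` or fewer residues.

    Applied before condensation: the MHC I groove prefers 9-mers, and
    shorter sequences are overwhelmingly non-specific.
    """
    return [r for r in records if len(r.sequence) > max_rejected_length]


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def condense_peptides(
    records: Sequence[PeptideRecord],
    mode: str = "coordinates",
    min_overlap: int = 5,
) -> list[Epitope]:
    """Merge overlapping peptides into maximal epitopes.

    The result is independent of the input record order: distinct peptides
    are processed in sorted order and epitope ids are assigned after a final
    deterministic sort.  Every input record ends up in exactly one epitope.
    """
    if mode not in ("coordinates", "string"):
        raise ValueError(f"unknown condensation mode {mode!r}")
    if not records:
        raise ValueError("no peptide records to condense")
    if mode == "string" and min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")

    if mode == "coordinates":
        epitopes = _condense_by_coordinates(records)
    else:
        epitopes = _condense_by_string(records, min_overlap)

    epitopes.sort(key=lambda e: (e.protein_id or "", e.start or 0, e.sequence))
    return [
        dataclasses.replace(e, epitope_id=f"EP{i:06d}")
        for i, e in enumerate(epitopes, start=1)
    ]


def _resolve_protein(record: PeptideRecord) -> str:
    # multi-mapping peptides carry ';'-joined accessions; the
    # lexicographically smallest wins so grouping is order-free
    parts = sorted(p for p in record.protein_id.split(";") if p)
    if len(parts) > 1:
        logger.info(
            "peptide %s maps to %d proteins; using %s",
            record.sequence, len(parts), parts[0],
        )
    return parts[0]


def _condense_by_coordinates(records: Sequence[PeptideRecord]) -> list[Epitope]:
    for r in records:
        if not r.has_coordinates:
            raise ValueError(
                f"coordinates mode requires protein_id/start/end on every "
                f"record; missing for {r.sequence!r}"
            )
    by_unit: dict[tuple[str, int, int, str], list[PeptideRecord]] = defaultdict(list)
    for r in records:
        by_unit[(_resolve_protein(r), r.start, r.end, r.sequence)].append(r)

    by_protein: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
    for (prot, start, end, seq) in by_unit:
        by_protein[prot].append((start, end, seq))

    epitopes: list[Epitope] = []
    for prot in sorted(by_protein):
        units = sorted(by_protein[prot])
        # sweep: intervals sorted by start; overlap of >= 1 residue chains
        component: list[tuple[int, int, str]] = []
        comp_end = None
        for unit in units:
            if comp_end is not None and unit[0] <= comp_end:
                component.append(unit)
                comp_end = max(comp_end, unit[1])
            else:
                if component:
                    epitopes.append(_build_coordinate_epitope(prot, component, by_unit))
                component = [unit]
                comp_end = unit[1]
        if component:
            epitopes.append(_build_coordinate_epitope(prot, component, by_unit))
    return epitopes


def _build_coordinate_epitope(
    prot: str,
    units: list[tuple[int, int, str]],
    by_unit: dict[tuple[str, int, int, str], list[PeptideRecord]],
) -> Epitope:
    start = min(u[0] for u in units)
    end = max(u[1] for u in units)
    letters: dict[int, str] = {}
    for (s, e, seq) in units:
        for pos, aa in zip(range(s, e + 1), seq):
            if letters.setdefault(pos, aa) != aa:
                raise CondensationError(
                    f"conflicting residues at {prot}:{pos} while condensing "
                    f"{sorted(u[2] for u in units)}"
                )
    sequence = "".join(letters[p] for p in range(start, end + 1))
    constituents = tuple(
        rec
        for u in sorted(units)
        for rec in by_unit[(prot, u[0], u[1], u[2])]
    )
    return Epitope(
        epitope_id="", sequence=sequence, constituents=constituents,
        protein_id=prot, start=start, end=end,
    )


def _string_overlap_offset(u: str, v: str, min_overlap: int) -> int | None:
    """Offset of ``v`` relative to ``u`` under the best admissible overlap.

    Containment takes priority; otherwise the longest suffix/prefix overlap
    >= ``min_overlap`` wins, preferring v-right-of-u on ties.  ``None`` means
    the two peptides do not overlap.
    """
    if v in u:
        return u.find(v)
    if u in v:
        return -v.find(u)
    best: tuple[int, int] | None = None  # (overlap_len, offset)
    for k in range(min(len(u), len(v)) - 1, min_overlap - 1, -1):
        if u[-k:] == v[:k]:  # v extends u to the right
            best = (k, len(u) - k)
            break
    for k in range(min(len(u), len(v)) - 1, min_overlap - 1, -1):
        if v[-k:] == u[:k]:  # v extends u to the left
            if best is None or k > best[0]:
                best = (k, -(len(v) - k))
            break
    return None if best is None else best[1]


def _condense_by_string(
    records: Sequence[PeptideRecord], min_overlap: int
) -> list[Epitope]:
    by_seq: dict[str, list[PeptideRecord]] = defaultdict(list)
    for r in records:
        by_seq[r.sequence].append(r)
    seqs = sorted(by_seq)
    n = len(seqs)

    offsets_rel: dict[tuple[int, int], int] = {}
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            off = _string_overlap_offset(seqs[i], seqs[j], min_overlap)
            if off is not None:
                offsets_rel[(i, j)] = off
                uf.union(i, j)

    adjacency: dict[int, list[int]] = defaultdict(list)
    for (i, j) in offsets_rel:
        adjacency[i].append(j)
        adjacency[j].append(i)

    components: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        components[uf.find(i)].append(i)

    epitopes: list[Epitope] = []
    for root in sorted(components):
        members = sorted(components[root])
        # BFS placement from the lexicographically smallest member
        placed: dict[int, int] = {members[0]: 0}
        queue = [members[0]]
        while queue:
            cur = queue.pop(0)
            for nxt in sorted(adjacency[cur]):
                if nxt in placed:
                    continue
                key = (cur, nxt) if cur < nxt else (nxt, cur)
                rel = offsets_rel[key]
                placed[nxt] = placed[cur] + (rel if cur < nxt else -rel)
                queue.append(nxt)
        base = min(placed.values())
        letters: dict[int, str] = {}
        for idx, off in placed.items():
            for pos, aa in enumerate(seqs[idx], start=off - base):
                if letters.setdefault(pos, aa) != aa:
                    raise CondensationError(
                        "overlaps imply conflicting residues while merging "
                        f"{sorted(seqs[m] for m in members)}"
                    )
        width = max(letters) + 1
        if set(letters) != set(range(width)):
            raise CondensationError(
                f"overlap placement leaves gaps while merging "
                f"{sorted(seqs[m] for m in members)}"
            )
        sequence = "".join(letters[p] for p in range(width))
        constituents = tuple(
            rec for idx in members for rec in by_seq[seqs[idx]]
        )
        epitopes.append(
            Epitope(epitope_id="", sequence=sequence, constituents=constituents)
        )
    return epitopes


def classify_epitopes(
    epitopes: Iterable[Epitope],
    min_total_count: int = 3,
    mhc1_range: tuple[int, int] = (9, 11),
    mhc2_range: tuple[int, int] = (12, 20),
    mhc2_min_constituents: int = 3,
    retain_over_max: bool = False,
) -> list[Epitope]:
    """Assign each epitope to the MHC I or MHC II group, or reject it.

    Rejection reasons: total spectral count below ``min_total_count``;
    length of 8 or fewer; length outside both class ranges (spans beyond the
    class II maximum are rejected with a warning unless ``retain_over_max``,
    in which case they stay unclassified); an MHC II-length epitope with
    fewer than ``mhc2_min_constituents`` distinct constituent peptides.
    """
    if mhc1_range[1] >= mhc2_range[0]:
        raise ValueError(
            f"class ranges overlap: MHC I {mhc1_range} vs MHC II {mhc2_range}"
        )
    out: list[Epitope] = []
    for ep in epitopes:
        length = len(ep.sequence)
        if retain_over_max and length > mhc2_range[1]:
            logger.warning(
                "epitope %s length %d exceeds the class II maximum; retained "
                "unclassified", ep.epitope_id, length,
            )
            out.append(dataclasses.replace(ep, mhc_class=None))
            continue
        if ep.total_spectral_count < min_total_count:
            cls = REJECTED
        elif length <= 8:
            cls = REJECTED
        elif mhc1_range[0] <= length <= mhc1_range[1]:
            cls = MHC_I
        elif mhc2_range[0] <= length <= mhc2_range[1]:
            if ep.n_constituents >= mhc2_min_constituents:
                cls = MHC_II
            else:
                cls = REJECTED
        else:
            if length > mhc2_range[1]:
                logger.warning(
                    "epitope %s length %d exceeds the class II maximum; "
                    "rejected", ep.epitope_id, length,
                )
            cls = REJECTED
        out.append(dataclasses.replace(ep, mhc_class=cls))
    return out


def write_epitope_table(epitopes: Iterable[Epitope], path: str | Path) -> None:
    rows = [
        {
            "epitope_id": e.epitope_id,
            "sequence": e.sequence,
            "protein_id": "" if e.protein_id is None else e.protein_id,
            "start": "" if e.start is None else e.start,
            "end": "" if e.end is None else e.end,
            "mhc_class": "" if e.mhc_class is None else e.mhc_class,
            "n_constituents": e.n_constituents,
            "total_spectral_count": e.total_spectral_count,
        }
        for e in epitopes
    ]
    pd.DataFrame(
        rows,
        columns=[
            "epitope_id", "sequence", "protein_id", "start", "end",
            "mhc_class", "n_constituents", "total_spectral_count",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_epitope_fasta(
    epitopes: Iterable[Epitope],
    path: str | Path,
    ei_summary: dict[str, str] | None = None,
) -> None:
    """Write epitope sequences as FASTA (id = epitope id, description =
    class plus an optional per-epitope abundance summary)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = []
    for e in epitopes:
        desc = f"class={e.mhc_class or 'NA'}"
        if ei_summary and e.epitope_id in ei_summary:
            desc += f" {ei_summary[e.epitope_id]}"
        recs.append(SeqRecord(Seq(e.sequence), id=e.epitope_id, description=desc))
    seqio_write(recs, str(path), "fasta")
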