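"""Allele deconvolution: matching E_i presence profiles to HLA genotypes.

Across a panel of genetically related cell lines, an epitope presented by
a given HLA allele should appear in exactly the lines that carry that
allele.  Binarizing each epitope's E_i vector (present iff E_i > 0) and
comparing it with the *theoretical profile* of every allele in the panel
(1 in each line whose genotype contains the allele) assigns candidate
presenting alleles by Hamming distance.  Alleles that co-segregate on one
haplotype share a profile and stay mutually ambiguous; an epitope matching
no allele is a putative contaminant.

An allele is *traceable* in a panel when its presence vector is unique
among all alleles -- the count of traceable alleles quantifies how much
deconvolution power a panel offers and can only grow as lines are added.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance_indices import EiMatrix

#: classical class I loci; anything else is treated as class II
CLASS_I_LOCI = frozenset({"A", "B", "C"})


@dataclasses.dataclass(frozen=True)
class Genotype:
    """One cell line's HLA typing: two (possibly identical) alleles per locus."""

    cell_line: str
    alleles: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for locus, pair in self.alleles.items():
            if len(pair) != 2:
                raise ValueError(
                    f"{self.cell_line}: locus {locus} needs exactly two alleles"
                )

    def carries(self, allele: str) -> bool:
        return any(allele in pair for pair in self.alleles.values())


@dataclasses.dataclass(frozen=True)
class AlleleProfile:
    """Binary presence of one allele across the panel's cell lines."""

    allele: str
    presence: tuple[int, ...]

    def __post_init__(self) -> None:
        if not any(self.presence):
            raise ValueError(f"allele {self.allele} occurs in no cell line")


def read_genotype_table(path: str | Path) -> list[Genotype]:
    """Genotype TSV: cell_line, locus, allele1, allele2 (one row per locus)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    genotypes = []
    for line, group in df.groupby("cell_line", sort=False):
        alleles = {
            row.locus: (row.allele1, row.allele2)
            for row in group.itertuples(index=False)
        }
        genotypes.append(Genotype(cell_line=line, alleles=alleles))
    return genotypes


def write_genotype_table(genotypes: Iterable[Genotype], path: str | Path) -> None:
    rows = [
        {
            "cell_line": g.cell_line,
            "locus": locus,
            "allele1": pair[0],
            "allele2": pair[1],
        }
        for g in genotypes
        for locus, pair in g.alleles.items()
    ]
    pd.DataFrame(rows, columns=["cell_line", "locus", "allele1", "allele2"]).to_csv(
        path, sep="\t", index=False
    )


def theoretical_profiles(
    genotypes: Sequence[Genotype], loci: Iterable[str] | None = None
) -> list[AlleleProfile]:
    """One profile per distinct allele carried anywhere in the panel.

    Cell-line order follows the genotype list; profiles come out sorted by
    (locus, allele name).  A line missing a requested locus is an error.
    """
    panel_loci = sorted({l for g in genotypes for l in g.alleles})
    loci = sorted(loci) if loci is not None else panel_loci
    for g in genotypes:
        for locus in loci:
            if locus not in g.alleles:
                raise ValueError(
                    f"cell line {g.cell_line} is not genotyped at locus {locus}"
                )
    profiles = []
    for locus in loci:
        alleles = sorted({a for g in genotypes for a in g.alleles[locus]})
        for allele in alleles:
            presence = tuple(
                int(allele in g.alleles[locus]) for g in genotypes
            )
            profiles.append(AlleleProfile(allele=allele, presence=presence))
    return profiles


def binarize(observed: Sequence[float], floor: float = 0.0) -> tuple[int, ...]:
    """Presence iff E_i strictly above ``floor`` (default: E_i > 0)."""
    return tuple(int(v > floor) for v in observed)


def assign_epitope_alleles(
    observed: Sequence[float],
    profiles: Sequence[AlleleProfile],
    max_mismatch: int = 0,
    floor: float = 0.0,
) -> set[str]:
    """Candidate alleles within Hamming distance ``max_mismatch`` of the
    binarized observed profile.  An empty set flags a putative contaminant
    (or an epitope whose pattern fits no single allele)."""
    obs = binarize(observed, floor=floor)
    out = set()
    for p in profiles:
        if len(p.presence) != len(obs):
            raise ValueError(
                f"profile for {p.allele} has {len(p.presence)} lines, "
                f"observed vector has {len(obs)}"
            )
        d = sum(a != b for a, b in zip(p.presence, obs))
        if d <= max_mismatch:
            out.add(p.allele)
    return out


def assignment_table(
    matrix: EiMatrix,
    profiles: Sequence[AlleleProfile],
    max_mismatch: int = 0,
    floor: float = 0.0,
) -> pd.DataFrame:
    """Per-epitope candidate alleles over a whole E_i matrix."""
    rows = []
    for i, eid in enumerate(matrix.epitope_ids):
        cands = assign_epitope_alleles(
            matrix.values[i], profiles, max_mismatch=max_mismatch, floor=floor
        )
        rows.append(
            {
                "epitope_id": eid,
                "candidate_alleles": ";".join(sorted(cands)),
                "n_candidates": len(cands),
            }
        )
    return pd.DataFrame(rows, columns=["epitope_id", "candidate_alleles", "n_candidates"])


def locus_of_allele(allele: str) -> str:
    """Locus part of a standard allele name (everything before '*')."""
    return allele.split("*", 1)[0]


def traceable_allele_count(
    profiles: Sequence[AlleleProfile],
    locus_of: Mapping[str, str] | None = None,
) -> tuple[int, list[str]]:
    """Alleles whose presence vector is unique among all profiles.

    By default uniqueness is judged across all loci (the stricter
    reading); duplicate profiles -- typically alleles co-segregating on
    one haplotype -- are mutually untraceable.  With ``locus_of`` (allele
    -> locus) uniqueness is judged only against alleles of the same locus,
    which is the relevant question when the epitope's class already
    narrows the locus.  Extending every vector with a new cell line can
    only split duplicates, never create them, so the count is monotone
    non-decreasing in panel size.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    vecs: dict[tuple, list[str]] = {}
    for p in profiles:
        key: tuple = p.presence
        if locus_of is not None:
            key = (locus_of[p.allele], p.presence)
        vecs.setdefault(key, []).append(p.allele)
    unique = sorted(a for group in vecs.values() if len(group) == 1 for a in group)
    return len(unique), unique


def traceability_by_panel_size(
    genotypes: Sequence[Genotype],
    loci: Iterable[str] | None = None,
    per_locus: bool = False,
) -> pd.DataFrame:
    """Traceable-allele count for each incremental panel prefix.

    Quantifies how each added cell line improves allele traceability.
    With ``per_locus``, allele names are parsed as locus*designation and
    uniqueness is judged within each locus.
    """
    rows = []
    for k in range(1, len(genotypes) + 1):
        profiles = theoretical_profiles(genotypes[:k], loci=loci)
        locus_of = (
            {p.allele: locus_of_allele(p.allele) for p in profiles}
            if per_locus
            else None
        )
        count, unique = traceable_allele_count(profiles, locus_of=locus_of)
        rows.append(
            {
                "n_cell_lines": k,
                "last_added": genotypes[k - 1].cell_line,
                "n_alleles": len(profiles),
                "n_traceable": count,
                "traceable_alleles": ";".join(unique),
            }
        )
    return pd.DataFrame(rows)
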