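"""Synthetic consanguineous-family peptidome with known ground truth.

The generator emulates the study design the pipeline is built for: a
panel of B-lymphocyte lines from one nuclear family (two parents plus
children), where each child inherits one complete HLA haplotype from each
parent (no recombination -- the HLA region is tightly linked), so alleles
co-segregate in blocks and epitope presence patterns across the panel are
Mendelian.

Each allele gets its own binding motif: a position-weight matrix that is
near-uniform except at anchor positions (2 and 9 for MHC I; 1, 4, 6 and 9
of the 9-mer core for MHC II), where one allele-specific residue carries
high probability.  MHC I epitopes emit one or two peptides of 9-11
residues; MHC II epitopes emit nested sets of ragged 12-20-mers sharing
the core.  Every epitope is embedded in its own synthetic protein at
known coordinates, and appears only in cell lines whose genotype carries
its allele.  Spectral counts are Poisson per replicate, modulated by a
per-epitope immunodominance factor and a per-(allele, cell line)
presentation-efficiency factor -- the latter is what lets abundance
clustering separate co-segregating alleles, as it does in real data.
Replicate dropout and uniformly random contaminant peptides (present in
every line) provide the configurable noise.  Everything derives from one
seed; identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .deconvolution import CLASS_I_LOCI, Genotype, write_genotype_table
from .io_tables import PeptideRecord, write_peptide_table

AMINO_ACIDS = np.array(sorted("ACDEFGHIKLMNPQRSTVWY"))


@dataclasses.dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic family peptidome."""

    n_children: int = 5
    loci: tuple[str, ...] = ("A", "B", "C", "DRB1", "DQB1")
    allele_pool: dict[str, list[str]] | None = None  # default: 6 per locus
    epitopes_per_allele: int = 20
    mhc1_length_weights: dict[int, float] = dataclasses.field(
        default_factory=lambda: {9: 0.6, 10: 0.25, 11: 0.15}
    )
    mhc1_anchors: tuple[int, ...] = (2, 9)
    mhc2_core_anchors: tuple[int, ...] = (1, 4, 6, 9)
    mhc2_flank_range: tuple[int, int] = (2, 5)
    nested_min: int = 3
    nested_max: int = 6
    mhc1_extra_peptide_prob: float = 0.5
    anchor_probability: float = 0.8
    count_lambda: float = 12.0
    abundance_sigma: float = 0.3
    presentation_sigma: float = 0.6
    replicate_dropout: float = 0.1
    contaminant_fraction: float = 0.1
    n_replicates: int = 3
    protein_flank: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.anchor_probability,
            self.replicate_dropout,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ValueError("contaminant_fraction must be in [0, 1)")
        if any(not 1 <= a <= 9 for a in self.mhc1_anchors + self.mhc2_core_anchors):
            raise ValueError("anchor positions must lie within the 9-mer core")
        if self.count_lambda <= 0:
            raise ValueError("count_lambda must be positive")
        if not 1 <= self.nested_min <= self.nested_max:
            raise ValueError("need 1 <= nested_min <= nested_max")
        lo, hi = self.mhc2_flank_range
        if not 0 <= lo <= hi:
            raise ValueError("invalid mhc2_flank_range")
        if 9 + 2 * hi > 20:
            raise ValueError(
                f"core (9) plus flanks up to {hi} per side exceeds the 20-mer "
                f"class II maximum"
            )

    def pool(self) -> dict[str, list[str]]:
        if self.allele_pool is not None:
            return self.allele_pool
        return {
            locus: [f"{locus}*{i:02d}" for i in range(1, 7)] for locus in self.loci
        }


@dataclasses.dataclass
class SimulatedDataset:
    """Peptide observations plus the ground truth behind them."""

    genotypes: list[Genotype]
    records: list[PeptideRecord]
    proteins: dict[str, str]
    truth_peptides: pd.DataFrame   # sequence, protein_id, start, end, epitope_id, allele
    truth_epitopes: pd.DataFrame   # epitope_id, allele, protein_id, start, end, sequence, group
    config: SimulationConfig

    @property
    def cell_lines(self) -> list[str]:
        return [g.cell_line for g in self.genotypes]


def simulate_family(config: SimulationConfig) -> list[Genotype]:
    """Mendelian family genotypes: 2 parents + ``n_children`` children.

    Per locus, four distinct parental alleles are drawn from the pool
    (error if the pool is smaller); each child inherits one complete
    haplotype from each parent, without recombination.
    """
    rng = np.random.default_rng([config.seed, 1])
    pool = config.pool()
    haplotypes: list[dict[str, str]] = [{}, {}, {}, {}]  # F0 F1 M0 M1
    for locus in config.loci:
        alleles = pool[locus]
        if len(set(alleles)) < 4:
            raise ValueError(
                f"allele pool at locus {locus} has fewer than 4 distinct "
                f"entries; cannot build four parental haplotypes"
            )
        picks = rng.choice(sorted(set(alleles)), size=4, replace=False)
        for h, a in zip(haplotypes, picks):
            h[locus] = str(a)

    def geno(name: str, hap_a: dict, hap_b: dict) -> Genotype:
        return Genotype(
            cell_line=name,
            alleles={l: (hap_a[l], hap_b[l]) for l in config.loci},
        )

    genotypes = [
        geno("father", haplotypes[0], haplotypes[1]),
        geno("mother", haplotypes[2], haplotypes[3]),
    ]
    for i in range(1, config.n_children + 1):
        fi = int(rng.integers(2))
        mi = int(rng.integers(2))
        genotypes.append(geno(f"child{i}", haplotypes[fi], haplotypes[2 + mi]))
    return genotypes


def _sample_sequence(rng, length: int, anchors: dict[int, str], prob: float) -> str:
    out = []
    for pos in range(1, length + 1):
        if pos in anchors and rng.random() < prob:
            out.append(anchors[pos])
        else:
            out.append(str(rng.choice(AMINO_ACIDS)))
    return "".join(out)


def _clipped_lognormal(rng, sigma: float, lo: float = 0.7, hi: float = 1.6) -> float:
    return float(np.clip(rng.lognormal(0.0, sigma), lo, hi))


def _presentation_factor(rng, sigma: float) -> float:
    # per-(allele, cell line) surface-presentation efficiency; wide but
    # bounded away from 0 so carried alleles stay detectable
    return float(np.clip(rng.lognormal(0.0, sigma), 0.5, 3.0))


def simulate_peptidome(
    genotypes: Sequence[Genotype], config: SimulationConfig
) -> SimulatedDataset:
    """Generate peptide observations, proteins and the truth tables."""
    rng = np.random.default_rng([config.seed, 2])
    lines = [g.cell_line for g in genotypes]
    loci = list(config.loci)
    alleles_by_locus = {
        locus: sorted({a for g in genotypes for a in g.alleles[locus]})
        for locus in loci
    }

    # allele-specific anchor residues (distinct draw per allele)
    anchor_residues: dict[str, dict[int, str]] = {}
    for locus in loci:
        positions = (
            config.mhc1_anchors if locus in CLASS_I_LOCI else config.mhc2_core_anchors
        )
        for allele in alleles_by_locus[locus]:
            anchor_residues[allele] = {
                pos: str(rng.choice(AMINO_ACIDS)) for pos in positions
            }

    line_factor: dict[tuple[str, str], float] = {}
    for locus in loci:
        for allele in alleles_by_locus[locus]:
            for line in lines:
                line_factor[(allele, line)] = _presentation_factor(
                    rng, config.presentation_sigma
                )

    proteins: dict[str, str] = {}
    truth_peptides: list[dict] = []
    truth_epitopes: list[dict] = []
    # peptide definitions: (sequence, protein_id, start, end, epitope_id,
    #                       allele, carrier_lines, effective_lambda)
    peptide_defs: list[dict] = []
    ep_counter = 0

    lengths = sorted(config.mhc1_length_weights)
    weights = np.array([config.mhc1_length_weights[l] for l in lengths], dtype=float)
    weights = weights / weights.sum()

    def embed_protein(ep_seq: str, prefix: str, idx: int) -> tuple[str, int, int]:
        flank = config.protein_flank
        left = "".join(rng.choice(AMINO_ACIDS, size=flank))
        right = "".join(rng.choice(AMINO_ACIDS, size=flank))
        pid = f"{prefix}{idx:05d}"
        proteins[pid] = left + ep_seq + right
        return pid, flank + 1, flank + len(ep_seq)

    for locus in loci:
        is_class_i = locus in CLASS_I_LOCI
        for allele in alleles_by_locus[locus]:
            carriers = [g.cell_line for g in genotypes if allele in g.alleles[locus]]
            for _k in range(config.epitopes_per_allele):
                ep_counter += 1
                ep_id = f"T{ep_counter:05d}"
                ep_factor = _clipped_lognormal(rng, config.abundance_sigma)
                if is_class_i:
                    length = int(rng.choice(lengths, p=weights))
                    ep_seq = _sample_sequence(
                        rng, length, anchor_residues[allele],
                        config.anchor_probability,
                    )
                    pid, ep_start, ep_end = embed_protein(ep_seq, "SYNP", ep_counter)
                    peptides = [(1, length)]
                    if length > 9 and rng.random() < config.mhc1_extra_peptide_prob:
                        sub_len = int(rng.integers(9, length))
                        sub_off = int(rng.integers(0, length - sub_len + 1))
                        peptides.append((sub_off + 1, sub_off + sub_len))
                    group = "I"
                else:
                    lo, hi = config.mhc2_flank_range
                    lf = int(rng.integers(lo, hi + 1))
                    rf = int(rng.integers(lo, hi + 1))
                    core_anchors = {
                        lf + pos: aa
                        for pos, aa in anchor_residues[allele].items()
                    }
                    span = lf + 9 + rf
                    ep_seq = _sample_sequence(
                        rng, span, core_anchors, config.anchor_probability
                    )
                    pid, ep_start, ep_end = embed_protein(ep_seq, "SYNP", ep_counter)
                    # nested ragged set sharing the core: trims of the flanks
                    trims = [
                        (dl, dr)
                        for dl in range(lf + 1)
                        for dr in range(rf + 1)
                        if (dl, dr) != (0, 0) and span - dl - dr >= 12
                    ]
                    k = int(rng.integers(config.nested_min, config.nested_max + 1))
                    n_extra = min(k - 1, len(trims))
                    chosen = rng.choice(len(trims), size=n_extra, replace=False)
                    peptides = [(1, span)] + [
                        (trims[c][0] + 1, span - trims[c][1]) for c in sorted(chosen)
                    ]
                    group = "II"
                truth_epitopes.append(
                    {
                        "epitope_id": ep_id, "allele": allele, "protein_id": pid,
                        "start": ep_start, "end": ep_end, "sequence": ep_seq,
                        "group": group,
                    }
                )
                eff = {
                    line: config.count_lambda * ep_factor * line_factor[(allele, line)]
                    for line in carriers
                }
                for (s, e) in peptides:
                    pep_seq = ep_seq[s - 1 : e]
                    truth_peptides.append(
                        {
                            "sequence": pep_seq, "protein_id": pid,
                            "start": ep_start + s - 1, "end": ep_start + e - 1,
                            "epitope_id": ep_id, "allele": allele,
                        }
                    )
                    peptide_defs.append(
                        {
                            "sequence": pep_seq, "protein_id": pid,
                            "start": ep_start + s - 1, "end": ep_start + e - 1,
                            "lines": {line: eff[line] for line in carriers},
                        }
                    )

    # contaminants: random sequences present in every line
    n_true = len(peptide_defs)
    f = config.contaminant_fraction
    n_cont = int(round(f / (1.0 - f) * n_true)) if f > 0 else 0
    for i in range(1, n_cont + 1):
        ep_counter += 1
        length = int(rng.integers(8, 21))
        seq = "".join(rng.choice(AMINO_ACIDS, size=length))
        pid, s, e = embed_protein(seq, "CONT", ep_counter)
        ep_id = f"C{ep_counter:05d}"
        ep_factor = _clipped_lognormal(rng, config.abundance_sigma)
        truth_epitopes.append(
            {
                "epitope_id": ep_id, "allele": "contaminant", "protein_id": pid,
                "start": s, "end": e, "sequence": seq, "group": "contaminant",
            }
        )
        truth_peptides.append(
            {
                "sequence": seq, "protein_id": pid, "start": s, "end": e,
                "epitope_id": ep_id, "allele": "contaminant",
            }
        )
        peptide_defs.append(
            {
                "sequence": seq, "protein_id": pid, "start": s, "end": e,
                "lines": {
                    line: config.count_lambda * ep_factor for line in lines
                },
            }
        )

    records: list[PeptideRecord] = []
    for pdef in peptide_defs:
        for line in lines:
            if line not in pdef["lines"]:
                continue
            lam = pdef["lines"][line]
            for rep in range(1, config.n_replicates + 1):
                if (
                    config.replicate_dropout > 0
                    and rng.random() < config.replicate_dropout
                ):
                    continue
                count = int(rng.poisson(lam))
                if count == 0:
                    continue
                records.append(
                    PeptideRecord(
                        sequence=pdef["sequence"],
                        cell_line=line,
                        replicate=f"r{rep}",
                        spectral_count=count,
                        protein_id=pdef["protein_id"],
                        start=pdef["start"],
                        end=pdef["end"],
                    )
                )

    return SimulatedDataset(
        genotypes=list(genotypes),
        records=records,
        proteins=proteins,
        truth_peptides=pd.DataFrame(truth_peptides),
        truth_epitopes=pd.DataFrame(truth_epitopes),
        config=config,
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Family plus peptidome in one call."""
    return simulate_peptidome(simulate_family(config), config)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Emit the TSV/FASTA artifacts the pipeline ingests, plus the truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_peptide_table(dataset.records, outdir / "peptides.tsv")
    write_genotype_table(dataset.genotypes, outdir / "genotypes.tsv")
    with open(outdir / "proteins.fasta", "w") as fh:
        for pid in sorted(dataset.proteins):
            fh.write(f">{pid}\n{dataset.proteins[pid]}\n")
    dataset.truth_peptides.to_csv(
        outdir / "truth_peptides.tsv", sep="\t", index=False
    )
    dataset.truth_epitopes.to_csv(
        outdir / "truth_epitopes.tsv", sep="\t", index=False
    )
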