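"""Core domain containers shared across the package.

The central objects mirror the experimental design: a *cell family* is the
small set of related single cells (a micronucleated cell plus its sister, or
their respective daughters) whose haplotype-resolved transcriptomes jointly
constrain which chromosome was trapped in the micronucleus and how it
segregated.

Units convention: per-homologue transcription is expressed as *normalized
haplotype-specific transcription* ("yield"), defined as (TPM ratio vs control
mean) x (allele fraction).  One normally transcribing homologue in a disomic
cell contributes 0.5, so a disomic chromosome totals 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Transcriptional copy-number state labels, in increasing order of yield.
LABELS = ("0", "1-", "1", "1+", "2")

HAPLOTYPES = ("A", "B")

#: Cell roles within a micronucleation family.
ROLE_CONTROL = "control"
ROLE_MN_CELL = "mn_cell"
ROLE_MN_SISTER = "mn_sister"
ROLE_MN_DAUGHTER = "mn_daughter"
ROLE_MN_NIECE = "mn_niece"

MN_ROLES = (ROLE_MN_CELL, ROLE_MN_SISTER, ROLE_MN_DAUGHTER, ROLE_MN_NIECE)

#: Columns of a per-cell expression table.
CELL_COLUMNS = ("gene_id", "tpm", "hapA_count", "hapB_count")


def other_haplotype(hap: str) -> str:
    if hap not in HAPLOTYPES:
        raise ValueError(f"unknown haplotype {hap!r}; expected one of {HAPLOTYPES}")
    return "B" if hap == "A" else "A"


@dataclass(frozen=True)
class GeneCatalog:
    """A gene annotation: positions plus simulation baselines.

    ``genes`` columns: chrom, start, end, gene_id, mean_tpm, dispersion
    (0-based half-open coordinates).  ``chrom_lengths`` declares chromosome
    sizes in base pairs.
    """

    genes: pd.DataFrame
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        g = self.genes
        required = {"chrom", "start", "end", "gene_id", "mean_tpm"}
        missing = required - set(g.columns)
        if missing:
            raise ValueError(f"gene catalog missing columns: {sorted(missing)}")
        if (g["start"] >= g["end"]).any():
            raise ValueError("gene catalog contains records with start >= end")
        if g["gene_id"].duplicated().any():
            dups = g.loc[g["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        for chrom, sub in g.groupby("chrom", sort=False):
            if chrom not in self.chrom_lengths:
                raise ValueError(f"gene on undeclared chromosome {chrom!r}")
            if (sub["end"] > self.chrom_lengths[chrom]).any():
                raise ValueError(f"gene extends beyond {chrom} length")
        if not pd.notna(g["mean_tpm"]).all() or (g["mean_tpm"] <= 0).any():
            raise ValueError("baseline mean TPM must be positive and finite")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SegregationScenario:
    """Ground-truth description of one micronucleation event.

    ``pattern`` is the mitotic split of the four chromatids of the affected
    homologue pair: "1:3" (sister monosomic, micronucleated cell trisomic for
    the MN haplotype) or "2:2" (both cells disomic, one chromatid in the
    micronucleus).  ``mn_yield`` (a) is the transcriptional yield of the MN
    chromatid in per-homologue units, 0 (silent) to 0.5 (fully normal).
    ``split`` applies in generation 2 only: the fraction of the MN chromatid's
    output re-incorporated into daughter 1 (fragmentation may distribute it
    across both daughters).
    """

    chrom: str
    mn_haplotype: str
    pattern: str
    generation: int
    mn_yield: float
    split: float | None = None

    def __post_init__(self) -> None:
        if self.mn_haplotype not in HAPLOTYPES:
            raise ValueError(f"mn_haplotype must be one of {HAPLOTYPES}")
        if self.pattern not in ("1:3", "2:2"):
            raise ValueError("pattern must be '1:3' or '2:2'")
        if self.generation not in (1, 2):
            raise ValueError("generation must be 1 or 2")
        if not 0.0 <= self.mn_yield <= 0.5:
            raise ValueError("mn_yield (a) must lie in [0, 0.5]")
        if self.generation == 2:
            if self.split is None or not 0.0 <= self.split <= 1.0:
                raise ValueError("generation-2 scenarios require split in [0, 1]")
        elif self.split is not None:
            raise ValueError("split is defined only for generation-2 scenarios")


@dataclass
class Cell:
    """One cell's gene-level expression table with its family role."""

    cell_id: str
    role: str
    generation: int
    data: pd.DataFrame  # columns CELL_COLUMNS

    def __post_init__(self) -> None:
        missing = set(CELL_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"cell table missing columns: {sorted(missing)}")

    @property
    def reads(self) -> pd.Series:
        """Informative (haplotype-assigned) reads per gene."""
        return self.data["hapA_count"] + self.data["hapB_count"]


@dataclass
class Family:
    """The 2-4 related cells of one micronucleation event."""

    family_id: str
    generation: int
    cells: list[Cell]
    truth: SegregationScenario | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if len(self.cells) < 2:
            raise ValueError("a family needs at least 2 cells")
        roles = [c.role for c in self.cells]
        if self.generation == 1:
            expected = {ROLE_MN_CELL, ROLE_MN_SISTER}
            if not expected.issubset(roles):
                raise ValueError(
                    f"generation-1 family requires roles {sorted(expected)}, got {roles}"
                )
        else:
            if roles.count(ROLE_MN_DAUGHTER) != 2:
                raise ValueError("generation-2 family requires two MN daughters")
            n_nieces = roles.count(ROLE_MN_NIECE)
            if n_nieces not in (0, 2):
                raise ValueError("nieces, when present, come as a pair")

    @property
    def has_nieces(self) -> bool:
        return any(c.role == ROLE_MN_NIECE for c in self.cells)

    def cells_by_role(self, role: str) -> list[Cell]:
        return [c for c in self.cells if c.role == role]
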