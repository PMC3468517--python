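"""Reading, writing and filtering of dominant-marker (AFLP) genotype matrices.

AFLP loci are anonymous dominant markers scored as band presence/absence.
The on-disk format is a plain UTF-8 TSV: a header row of locus IDs, one row
per individual whose first cell is the individual ID, and cells in
``{0, 1, NA}`` (absence / presence / missing).  A companion population-map
TSV assigns each individual to a sampling site, a geographical population
and a chromosomal race, giving the 4-level hierarchy used by the AMOVA and
the pairwise F_ST machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AFLPDataset",
    "PopulationHierarchy",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_population_map",
    "write_population_map",
    "filter_polymorphism",
    "replicate_mismatch_rate",
]

MISSING = -1  # internal code for a missing phenotype cell


@dataclass
class AFLPDataset:
    """Binary phenotype matrix (individuals x loci) with a missing-data code.

    ``phenotypes`` is an int8 array with 1 = band present, 0 = band absent,
    -1 = missing.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    phenotypes: np.ndarray

    def __post_init__(self) -> None:
        self.phenotypes = np.asarray(self.phenotypes, dtype=np.int8)
        n, m = self.phenotypes.shape
        if n != len(self.individual_ids) or m != len(self.locus_ids):
            raise ValueError(
                f"phenotype matrix is {n}x{m} but there are "
                f"{len(self.individual_ids)} individuals and {len(self.locus_ids)} loci"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual IDs")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus IDs")
        bad = ~np.isin(self.phenotypes, (0, 1, MISSING))
        if bad.any():
            raise ValueError("phenotype values must be 0, 1 or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.phenotypes == MISSING

    def row(self, individual: str) -> np.ndarray:
        return self.phenotypes[self.individual_ids.index(individual)]

    def subset(self, individuals=None, loci=None) -> "AFLPDataset":
        """Return a copy restricted to the given individual and/or locus IDs."""
        ind = list(individuals) if individuals is not None else self.individual_ids
        loc = list(loci) if loci is not None else self.locus_ids
        ridx = [self.individual_ids.index(i) for i in ind]
        cidx = [self.locus_ids.index(l) for l in loc]
        return AFLPDataset(ind, loc, self.phenotypes[np.ix_(ridx, cidx)].copy())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.phenotypes.astype(float), index=self.individual_ids, columns=self.locus_ids
        )
        return df.where(self.phenotypes != MISSING)


@dataclass
class PopulationHierarchy:
    """individual -> sampling site -> population -> chromosomal race.

    Sites nest in populations and populations nest in races: a site assigned
    to two populations (or a population to two races) is rejected.
    """

    table: pd.DataFrame  # columns: individual, site, population, race
    site_to_population: dict = field(init=False)
    population_to_race: dict = field(init=False)

    def __post_init__(self) -> None:
        required = ["individual", "site", "population", "race"]
        missing_cols = [c for c in required if c not in self.table.columns]
        if missing_cols:
            raise ValueError(f"population map missing columns: {missing_cols}")
        self.table = self.table[required].astype(str).reset_index(drop=True)
        if self.table["individual"].duplicated().any():
            dups = self.table["individual"][self.table["individual"].duplicated()]
            raise ValueError(f"duplicate individuals in population map: {sorted(set(dups))}")
        s2p = self.table.groupby("site")["population"].nunique()
        if (s2p > 1).any():
            raise ValueError(
                f"sites assigned to more than one population: {sorted(s2p[s2p > 1].index)}"
            )
        p2r = self.table.groupby("population")["race"].nunique()
        if (p2r > 1).any():
            raise ValueError(
                f"populations assigned to more than one race: {sorted(p2r[p2r > 1].index)}"
            )
        self.site_to_population = dict(
            self.table.drop_duplicates("site")[["site", "population"]].values
        )
        self.population_to_race = dict(
            self.table.drop_duplicates("population")[["population", "race"]].values
        )

    @property
    def individuals(self) -> list[str]:
        return list(self.table["individual"])

    def individuals_in(self, label: str, level: str = "population") -> list[str]:
        return list(self.table.loc[self.table[level] == label, "individual"])

    def labels(self, level: str) -> list[str]:
        return list(dict.fromkeys(self.table[level]))

    def validate_against(self, dataset: AFLPDataset) -> None:
        """Every dataset individual must be mapped; extras in the map only warn."""
        mapped = set(self.individuals)
        in_data = set(dataset.individual_ids)
        unmapped = sorted(in_data - mapped)
        if unmapped:
            raise ValueError(f"dataset individuals absent from population map: {unmapped}")
        extra = sorted(mapped - in_data)
        if extra:
            warnings.warn(f"population map lists individuals not in dataset: {extra}")


def read_genotype_matrix(path) -> AFLPDataset:
    """Read a genotype TSV (header: locus IDs; rows: individual then 0/1/NA)."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty genotype file")
    header = lines[0].split("\t")
    locus_ids = header[1:]
    if not locus_ids:
        raise ValueError(f"{path}: header defines no loci")
    codes = {"0": 0, "1": 1, "NA": MISSING}
    individual_ids: list[str] = []
    rows = []
    for rno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(locus_ids) + 1:
            raise ValueError(
                f"{path}: row {rno} has {len(cells) - 1} genotype cells, "
                f"expected {len(locus_ids)}"
            )
        individual_ids.append(cells[0])
        row = np.empty(len(locus_ids), dtype=np.int8)
        for cno, cell in enumerate(cells[1:]):
            try:
                row[cno] = codes[cell]
            except KeyError:
                raise ValueError(
                    f"{path}: invalid cell {cell!r} at row {rno} "
                    f"(individual {cells[0]!r}), column {locus_ids[cno]!r}; "
                    "expected 0, 1 or NA"
                ) from None
        rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no individuals in genotype file")
    return AFLPDataset(individual_ids, locus_ids, np.vstack(rows))


def write_genotype_matrix(dataset: AFLPDataset, path) -> None:
    """Write a dataset in the same TSV dialect read_genotype_matrix expects."""
    rev = {0: "0", 1: "1", MISSING: "NA"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("individual\t" + "\t".join(dataset.locus_ids) + "\n")
        for ind, row in zip(dataset.individual_ids, dataset.phenotypes):
            fh.write(ind + "\t" + "\t".join(rev[int(v)] for v in row) + "\n")


def read_population_map(path, dataset: AFLPDataset | None = None) -> PopulationHierarchy:
    """Read a population map TSV (individual, site, population, race)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    hierarchy = PopulationHierarchy(table)
    if dataset is not None:
        hierarchy.validate_against(dataset)
    return hierarchy


def write_population_map(hierarchy: PopulationHierarchy, path) -> None:
    hierarchy.table.to_csv(path, sep="\t", index=False)


def filter_polymorphism(
    dataset: AFLPDataset,
    subset: list[str] | None = None,
    threshold: float = 0.10,
) -> tuple[AFLPDataset, list[str]]:
    """Drop loci whose minor phenotype frequency within ``subset`` is < threshold.

    The frequency is computed on band phenotypes (not inferred alleles) over
    non-missing cells; a locus at exactly the threshold is retained (the
    removal rule is a strict "< threshold").  Returns the filtered dataset and
    the removed locus IDs.
    """
    if not 0 <= threshold <= 0.5:
        raise ValueError("threshold must lie in [0, 0.5]")
    ids = subset if subset is not None else dataset.individual_ids
    if len(ids) == 0:
        raise ValueError("empty individual subset")
    ridx = [dataset.individual_ids.index(i) for i in ids]
    sub = dataset.phenotypes[ridx]
    present = (sub == 1).sum(axis=0)
    observed = (sub != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(observed > 0, present / np.maximum(observed, 1), 0.0)
    minor = np.minimum(freq, 1.0 - freq)
    minor[observed == 0] = 0.0
    keep = minor >= threshold
    removed = [l for l, k in zip(dataset.locus_ids, keep) if not k]
    kept_ids = [l for l, k in zip(dataset.locus_ids, keep) if k]
    return dataset.subset(loci=kept_ids), removed


def replicate_mismatch_rate(dataset: AFLPDataset, pairs: list[tuple[str, str]]) -> float:
    """Percentage of discordant phenotype calls between replicate individuals.

    Cells missing in either member of a pair are excluded from both the
    numerator and the denominator.
    """
    mismatches = 0
    compared = 0
    for a, b in pairs:
        ra, rb = dataset.row(a), dataset.row(b)
        ok = (ra != MISSING) & (rb != MISSING)
        compared += int(ok.sum())
        mismatches += int((ra[ok] != rb[ok]).sum())
    if compared == 0:
        raise ValueError("no comparable non-missing cells in the replicate pairs")
    return 100.0 * mismatches / compared
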