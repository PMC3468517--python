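"""Synthetic dominant-marker datasets with hybrid-zone structure.

The generator emulates the sampling design the analysis assumes: two
differentiated parental populations (chromosomal races), a pool of admixed
hybrid-zone individuals, and an optional low-recombination block that can
carry the strongly differentiated (outlier) loci.

Model choices
-------------
* Background differentiation follows the Balding-Nichols model: per locus,
  each population's presence-allele frequency is a Beta draw with mean equal
  to the ancestral frequency and variance F * p * (1 - p).  This is also the
  sampling model of the outlier scan, so simulated neutral loci are a
  coherent null for it.
* Outlier loci default to fixed differences (presence fixed in one
  population, absent in the other, alternating direction across loci) --
  the architecture reported for hybrid-zone outliers.  A sub-unity
  ``outlier_fst`` instead places frequencies symmetrically about 1/2 at the
  difference giving that Hudson-style F_ST.
* Hybrid ancestry is a two-state Markov mosaic along the genetic map: each
  haplotype starts in parent-1 ancestry with probability Q (the
  individual's admixture proportion) and re-draws its ancestry at switch
  points arriving with intensity g per Morgan, where g is the number of
  generations since contact.  This reproduces admixture LD between
  fixed-difference loci of Var(Q) + E[Q(1-Q)] * exp(-g d).
* Ancestry switches are disabled inside the rearranged block: a switch
  there would require a crossover in an individual heterozygous for the
  block (a heterokaryotype), where recombination is taken as completely
  eliminated; in block homokaryotypes a crossover exchanges identical
  ancestry and is invisible.
* Diploid genotypes are drawn under HWE within populations, and dominance
  masking (band present iff at least one presence allele) is always applied
  to phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .aflp_io import AFLPDataset, MISSING, PopulationHierarchy

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_parental_populations",
    "simulate_hybrid_zone",
    "simulate_study",
    "simulate_race_structure",
    "simulate_nested_design",
    "write_truth",
    "read_truth",
    "write_hybrid_truth",
]


@dataclass
class SimConfig:
    """Study-condition parameters of the two-race hybrid-zone generator.

    Defaults emulate the analysed population pair at desk scale: a few
    hundred loci, ~50 individuals per parental population and ~50 hybrids,
    background F_ST 0.38, and a small set of fixed-difference outliers that
    sit together in a zero-recombination block.
    """

    n_loci: int = 600
    n_outliers: int = 7
    outliers_in_block: bool = True
    block_span: tuple[float, float] = (0.0, 0.25)  # Morgans
    map_length: float = 10.0  # Morgans
    background_fst: float = 0.38
    outlier_fst: float = 1.0  # 1.0 => fixed differences
    n_per_population: tuple[int, int] = (50, 50)
    n_hybrids: int = 51
    admixture_mean: float = 0.5
    admixture_sd: float = 0.2236  # Beta(2, 2)
    generations_since_contact: int = 100
    dominance: bool = True
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.background_fst < 1:
            raise ValueError("background_fst must lie in [0, 1)")
        if not self.background_fst < self.outlier_fst <= 1:
            raise ValueError("need background_fst < outlier_fst <= 1")
        lo, hi = self.block_span
        if not (0 <= lo < hi <= self.map_length):
            raise ValueError("block_span must be a nonempty interval within [0, map_length]")
        for name in ("n_loci", "n_hybrids", "generations_since_contact"):
            if getattr(self, name) < 0 or (name == "n_loci" and self.n_loci <= 0):
                raise ValueError(f"{name} must be positive")
        if any(n <= 0 for n in self.n_per_population):
            raise ValueError("parental sample sizes must be positive")
        if self.n_outliers < 0 or self.n_outliers > self.n_loci:
            raise ValueError("n_outliers must lie in [0, n_loci]")
        if not 0 < self.admixture_mean < 1 or self.admixture_sd <= 0:
            raise ValueError("admixture parameters must give a distribution on (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")

    def admixture_beta_shapes(self) -> tuple[float, float]:
        """Method-of-moments Beta shapes for the hybrid Q distribution."""
        m, v = self.admixture_mean, self.admixture_sd**2
        if v >= m * (1 - m):
            raise ValueError("admixture_sd too large for a Beta on (0, 1)")
        common = m * (1 - m) / v - 1.0
        return m * common, (1 - m) * common


@dataclass
class SimTruth:
    """Ground truth written alongside a simulated dataset."""

    locus_ids: list[str]
    ancestral_freq: np.ndarray  # presence-allele freq, per locus
    pop_freq: np.ndarray  # (n_loci, 2) presence-allele freqs (p and q / r and s)
    outlier_flag: np.ndarray  # bool per locus
    map_position: np.ndarray  # Morgans
    in_block: np.ndarray  # bool per locus
    true_Q: pd.Series | None = None  # per hybrid individual
    effective_recomb: np.ndarray | None = None  # Morgans per adjacent sorted pair
    haplotypes: dict = field(default_factory=dict)  # individual -> (2, n_loci) 0/1

    def sorted_order(self) -> np.ndarray:
        return np.argsort(self.map_position, kind="stable")


def _balding_nichols(rng, p_anc: np.ndarray, fst: float, n_pops: int) -> np.ndarray:
    if fst == 0.0:
        return np.tile(p_anc[:, None], (1, n_pops))
    ratio = (1.0 - fst) / fst
    a = np.clip(p_anc * ratio, 1e-8, None)
    b = np.clip((1.0 - p_anc) * ratio, 1e-8, None)
    return rng.beta(a[:, None], b[:, None], size=(p_anc.size, n_pops))


def _draw_phenotypes(rng, freqs, n_ind, dominance=True):
    """HWE diploid draws at per-locus presence frequencies -> (phenotypes, haps)."""
    haps = (rng.random((2, n_ind, freqs.size)) < freqs[None, None, :]).astype(np.int8)
    if dominance:
        pheno = np.maximum(haps[0], haps[1])
    else:  # allele dosage, not used for AFLP emulation
        pheno = (haps[0] + haps[1]).astype(np.int8)
    return pheno, haps


def _inject_missing(rng, phenotypes: np.ndarray, rate: float) -> np.ndarray:
    if rate > 0:
        mask = rng.random(phenotypes.shape) < rate
        phenotypes = phenotypes.copy()
        phenotypes[mask] = MISSING
    return phenotypes


def simulate_parental_populations(config: SimConfig) -> tuple[AFLPDataset, SimTruth]:
    """Two parental populations under the Balding-Nichols model.

    Non-outlier loci: ancestral presence frequency ~ U(0.05, 0.95), each
    population's frequency a Beta draw at ``background_fst``.  Outlier loci:
    fixed differences by default (direction alternating across outliers so
    both tails of the allele-frequency-difference product are populated).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    L, n_out = config.n_loci, config.n_outliers
    locus_ids = [f"L{i:04d}" for i in range(L)]
    outlier_flag = np.zeros(L, dtype=bool)
    outlier_flag[:n_out] = True

    p_anc = rng.uniform(0.05, 0.95, size=L)
    pop_freq = _balding_nichols(rng, p_anc, config.background_fst, 2)

    if n_out:
        if config.outlier_fst >= 1.0:
            delta = 1.0
            hi, lo = 1.0, 0.0
        else:
            # symmetric frequencies about 1/2 giving Hudson F_ST = outlier_fst
            delta = np.sqrt(config.outlier_fst / (2.0 - config.outlier_fst))
            hi, lo = 0.5 * (1 + delta), 0.5 * (1 - delta)
        direction = np.resize([0, 1], n_out)  # alternate which pop carries the band
        pop_freq[:n_out, 0] = np.where(direction == 0, hi, lo)
        pop_freq[:n_out, 1] = np.where(direction == 0, lo, hi)
        p_anc[:n_out] = 0.5
        if config.outlier_fst < 1.0:
            # construction guarantee: no neutral locus more differentiated
            # than the outliers (only needed off the fixed-difference default)
            diff = np.abs(pop_freq[:, 0] - pop_freq[:, 1])
            bad = np.where(~outlier_flag & (diff > delta))[0]
            while bad.size:
                pop_freq[bad] = _balding_nichols(
                    rng, p_anc[bad], config.background_fst, 2
                )
                diff = np.abs(pop_freq[:, 0] - pop_freq[:, 1])
                bad = np.where(~outlier_flag & (diff > delta))[0]

    # genetic map: outliers inside the block when requested, else scattered
    map_position = rng.uniform(0.0, config.map_length, size=L)
    in_block = np.zeros(L, dtype=bool)
    lo_b, hi_b = config.block_span
    if config.outliers_in_block and n_out:
        map_position[:n_out] = rng.uniform(lo_b, hi_b, size=n_out)
    in_block = (map_position >= lo_b) & (map_position <= hi_b)

    n1, n2 = config.n_per_population
    ids, blocks, haplotypes = [], [], {}
    for j, (n_j, tag) in enumerate(((n1, "pop1"), (n2, "pop2"))):
        pheno, haps = _draw_phenotypes(rng, pop_freq[:, j], n_j, config.dominance)
        pheno = _inject_missing(rng, pheno, config.missing_rate)
        pids = [f"{tag}_{i:03d}" for i in range(n_j)]
        ids.extend(pids)
        blocks.append(pheno)
        for i, pid in enumerate(pids):
            haplotypes[pid] = haps[:, i, :]
    dataset = AFLPDataset(ids, locus_ids, np.vstack(blocks))

    order = np.argsort(map_position, kind="stable")
    gaps = np.diff(map_position[order])
    truth = SimTruth(
        locus_ids=locus_ids,
        ancestral_freq=p_anc,
        pop_freq=pop_freq,
        outlier_flag=outlier_flag,
        map_position=map_position,
        in_block=in_block,
        effective_recomb=_effective_gaps(map_position[order], config),
        haplotypes=haplotypes,
    )
    return dataset, truth


def _effective_gaps(sorted_pos: np.ndarray, config: SimConfig) -> np.ndarray:
    """Map distance between adjacent sorted loci, excluding the block interior."""
    lo, hi = config.block_span
    left = sorted_pos[:-1]
    right = sorted_pos[1:]
    overlap = np.clip(np.minimum(right, hi) - np.maximum(left, lo), 0.0, None)
    return (right - left) - overlap


def simulate_hybrid_zone(truth: SimTruth, config: SimConfig) -> tuple[AFLPDataset, SimTruth]:
    """Admixed hybrid-zone individuals given parental truth.

    Each hybrid draws a true admixture proportion Q from the configured Beta
    distribution; each of its two haplotypes is an ancestry mosaic along the
    map (Markov switching at intensity g per Morgan outside the block, zero
    inside), and alleles are drawn from the ancestral population's
    frequencies.  Returns the hybrid dataset and an updated truth carrying
    ``true_Q`` and the hybrids' haplotypes.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    L = len(truth.locus_ids)
    H = config.n_hybrids
    a, b = config.admixture_beta_shapes()
    Q = rng.beta(a, b, size=H)
    g = config.generations_since_contact

    order = truth.sorted_order()
    gaps_eff = _effective_gaps(truth.map_position[order], config)
    switch_prob = 1.0 - np.exp(-g * gaps_eff)  # >=1 switch event in the gap

    n_haps = 2 * H
    q_hap = np.repeat(Q, 2)
    anc_sorted = np.empty((n_haps, L), dtype=np.int8)
    anc_sorted[:, 0] = rng.random(n_haps) < q_hap  # 1 = parent-1 ancestry
    for j in range(1, L):
        redraw = rng.random(n_haps) < switch_prob[j - 1]
        new_state = (rng.random(n_haps) < q_hap).astype(np.int8)
        anc_sorted[:, j] = np.where(redraw, new_state, anc_sorted[:, j - 1])
    anc = np.empty_like(anc_sorted)
    anc[:, order] = anc_sorted

    freq_by_anc = np.stack([truth.pop_freq[:, 1], truth.pop_freq[:, 0]])  # index by ancestry
    alleles = (rng.random((n_haps, L)) < freq_by_anc[anc, np.arange(L)[None, :]]).astype(np.int8)
    haps = alleles.reshape(H, 2, L)
    pheno = np.maximum(haps[:, 0, :], haps[:, 1, :]) if config.dominance else haps.sum(axis=1)
    pheno = _inject_missing(rng, pheno.astype(np.int8), config.missing_rate)

    ids = [f"hyb_{i:03d}" for i in range(H)]
    dataset = AFLPDataset(ids, list(truth.locus_ids), pheno)
    new_truth = replace(
        truth,
        true_Q=pd.Series(Q, index=ids, name="true_Q"),
        haplotypes={**truth.haplotypes, **{ids[i]: haps[i] for i in range(H)}},
    )
    return dataset, new_truth


def simulate_study(config: SimConfig):
    """Full two-race hybrid-zone study: parental populations plus hybrids.

    Returns (dataset, hierarchy, truth) with a population map in which each
    parental population doubles as its own sampling site and chromosomal
    race, and the hybrid pool is a separate population.
    """
    parents, truth = simulate_parental_populations(config)
    hybrids, truth = simulate_hybrid_zone(truth, config)
    ids = parents.individual_ids + hybrids.individual_ids
    dataset = AFLPDataset(
        ids, parents.locus_ids, np.vstack([parents.phenotypes, hybrids.phenotypes])
    )
    rows = []
    for ind in parents.individual_ids:
        pop = ind.split("_")[0]
        race = "race1" if pop == "pop1" else "race2"
        rows.append((ind, pop, pop, race))
    for ind in hybrids.individual_ids:
        rows.append((ind, "hybrid_zone", "hybrid", "hybrid"))
    hierarchy = PopulationHierarchy(
        pd.DataFrame(rows, columns=["individual", "site", "population", "race"])
    )
    return dataset, hierarchy, truth


def simulate_race_structure(
    n_races: int = 3,
    pops_per_race: tuple[int, ...] = (2, 2, 1),
    sites_per_pop: int = 2,
    n_per_site: int = 10,
    n_loci: int = 300,
    fst_race: float = 0.45,
    fst_pop: float = 0.20,
    fst_site: float = 0.05,
    seed: int = 0,
):
    """Hierarchically structured binary dataset: races / populations / sites.

    Frequencies drift by nested Balding-Nichols steps (ancestral -> race ->
    population -> site) with the given F values per step; individuals are
    HWE diploids with dominance masking.  Emulates the multi-race island
    design (3 races / 5 populations by default) for ordination and AMOVA
    exercises.  Returns (dataset, hierarchy, site_freqs).
    """
    if len(pops_per_race) != n_races:
        raise ValueError("pops_per_race must list one count per race")
    rng = np.random.default_rng([seed, 2])
    locus_ids = [f"L{i:04d}" for i in range(n_loci)]
    p_anc = rng.uniform(0.1, 0.9, size=n_loci)
    race_freq = _balding_nichols(rng, p_anc, fst_race, n_races)
    ids, blocks, rows = [], [], []
    for r in range(n_races):
        pop_freq = np.column_stack(
            [_balding_nichols(rng, race_freq[:, r], fst_pop, 1)[:, 0]
             for _ in range(pops_per_race[r])]
        )
        for p in range(pops_per_race[r]):
            for s in range(sites_per_pop):
                sf = _balding_nichols(rng, pop_freq[:, p], fst_site, 1)[:, 0]
                pheno, _ = _draw_phenotypes(rng, sf, n_per_site)
                site = f"race{r}_pop{p}_site{s}"
                pids = [f"{site}_i{i:02d}" for i in range(n_per_site)]
                ids.extend(pids)
                blocks.append(pheno)
                rows.extend((pid, site, f"race{r}_pop{p}", f"race{r}") for pid in pids)
    dataset = AFLPDataset(ids, locus_ids, np.vstack(blocks))
    hierarchy = PopulationHierarchy(
        pd.DataFrame(rows, columns=["individual", "site", "population", "race"])
    )
    return dataset, hierarchy


def simulate_nested_design(
    fractions: tuple[float, float, float, float] = (0.37, 0.16, 0.07, 0.38),
    n_races: int = 3,
    pops_per_race: int = 3,
    sites_per_pop: int = 2,
    n_per_site: int = 8,
    n_traits: int = 300,
    seed: int = 0,
):
    """Balanced 4-level design with exactly realised variance fractions.

    Individuals carry continuous trait vectors y = a_race + b_pop + c_site +
    e; the effect matrices at each level are rescaled so their pooled sample
    variances hit the requested fractions of the total exactly, making the
    design a sharp recovery target for the AMOVA variance decomposition
    (squared-Euclidean AMOVA is agnostic to whether coordinates are binary
    band scores or continuous traits).  Returns (data, hierarchy) where
    ``data`` is an (N, n_traits) array.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (4,) or np.any(fractions < 0) or fractions.sum() <= 0:
        raise ValueError("fractions must be 4 non-negative weights")
    fractions = fractions / fractions.sum()  # printed percentages may not sum to 100
    rng = np.random.default_rng([seed, 3])
    R, P, S = n_races, n_races * pops_per_race, n_races * pops_per_race * sites_per_pop
    N = S * n_per_site

    def scaled_effects(n_groups, target_var):
        e = rng.standard_normal((n_groups, n_traits))
        e -= e.mean(axis=0)
        pooled = e.var(axis=0, ddof=1).mean()
        return e * np.sqrt(target_var / pooled)

    v_a, v_b, v_c, v_w = fractions
    a = scaled_effects(R, v_a)
    b = scaled_effects(P, v_b)
    c = scaled_effects(S, v_c)
    e = rng.standard_normal((N, n_traits))
    e -= e.mean(axis=0)
    e *= np.sqrt(v_w / e.var(axis=0, ddof=1).mean())

    rows, data = [], []
    i = 0
    for r in range(R):
        for p in range(pops_per_race):
            pop_idx = r * pops_per_race + p
            for s in range(sites_per_pop):
                site_idx = pop_idx * sites_per_pop + s
                for k in range(n_per_site):
                    rows.append(
                        (f"i{i:03d}", f"s{site_idx}", f"p{pop_idx}", f"r{r}")
                    )
                    data.append(a[r] + b[pop_idx] + c[site_idx] + e[i])
                    i += 1
    hierarchy = PopulationHierarchy(
        pd.DataFrame(rows, columns=["individual", "site", "population", "race"])
    )
    return np.vstack(data), hierarchy


def write_truth(truth: SimTruth, path) -> None:
    """Locus-level truth TSV: locus, ancestral_freq, freq_pop1, freq_pop2,
    outlier, map_pos, in_block.  Round-trips losslessly via read_truth."""
    df = pd.DataFrame(
        {
            "locus": truth.locus_ids,
            "ancestral_freq": truth.ancestral_freq,
            "freq_pop1": truth.pop_freq[:, 0],
            "freq_pop2": truth.pop_freq[:, 1],
            "outlier": truth.outlier_flag.astype(int),
            "map_pos": truth.map_position,
            "in_block": truth.in_block.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_truth(path) -> SimTruth:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return SimTruth(
        locus_ids=list(df["locus"].astype(str)),
        ancestral_freq=df["ancestral_freq"].to_numpy(),
        pop_freq=df[["freq_pop1", "freq_pop2"]].to_numpy(),
        outlier_flag=df["outlier"].to_numpy().astype(bool),
        map_position=df["map_pos"].to_numpy(),
        in_block=df["in_block"].to_numpy().astype(bool),
    )


def write_hybrid_truth(truth: SimTruth, path) -> None:
    """Hybrid truth TSV: individual, true_Q."""
    if truth.true_Q is None:
        raise ValueError("truth carries no hybrid Q values")
    truth.true_Q.rename_axis("individual").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
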