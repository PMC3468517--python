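"""Population-structure statistics for dominant-marker data.

Covers the ordination and hierarchy side of the genome scan: pairwise
individual distances and classical (metric) multidimensional scaling,
multi-locus pairwise F_ST with permutation tests, a 4-level analysis of
molecular variance (races / populations within races / sites within
populations / within sites), and a maximum-likelihood hybrid index that
stands in for an admixture-clustering Q value, with the "<98% from the
nominal parental population" hybrid designation rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import dominant_freq
from .aflp_io import MISSING, AFLPDataset, PopulationHierarchy
from .dominant_freq import BetaPrior, fit_beta_prior, group_absence_counts

__all__ = [
    "DistanceMatrix",
    "FstResult",
    "AmovaResult",
    "HybridAssignment",
    "pairwise_distance",
    "classical_mds",
    "pairwise_fst",
    "amova",
    "hybrid_index",
    "classify_hybrids",
]


@dataclass
class DistanceMatrix:
    individual_ids: list[str]
    matrix: np.ndarray
    kind: str  # squared_euclidean | one_minus_relatedness | asymmetric_binary

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.individual_ids),) * 2:
            raise ValueError("distance matrix shape does not match IDs")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        self.matrix = m


@dataclass
class FstResult:
    pop_a: str
    pop_b: str
    fst: float
    p_value: float | None
    n_permutations: int
    n_loci: int


@dataclass
class HybridAssignment:
    individual: str
    Q: float  # admixture proportion toward population 1
    loglik: float
    identifiable: bool = True
    is_hybrid: bool | None = None
    nominal_population: str | None = None


def pairwise_distance(dataset: AFLPDataset, kind: str = "squared_euclidean") -> DistanceMatrix:
    """Pairwise individual distances with pairwise deletion of missing cells.

    * ``squared_euclidean``: sum over loci of (x - y)^2, rescaled by
      L / L_shared so individuals with missing data stay comparable.
    * ``one_minus_relatedness``: 1 minus the band-sharing (Dice) similarity
      2 a / (2 a + b + c) -- a simple relatedness proxy for dominant data.
    * ``asymmetric_binary``: Jaccard distance (b + c) / (a + b + c); shared
      band absences carry no information and are ignored.
    """
    if dataset.n_individuals < 2:
        raise ValueError("need at least two individuals")
    X = dataset.phenotypes.astype(float)
    X[dataset.phenotypes == MISSING] = np.nan
    obs = ~np.isnan(X)
    shared = obs.astype(float) @ obs.astype(float).T
    if np.any(shared == 0):
        raise ValueError("some individual pair shares no non-missing loci")
    P = np.nan_to_num(X)  # nan -> 0; masked by obs in the products below
    both_present = P @ P.T
    pres_vs_obs_a = P @ obs.astype(float).T  # present in i, observed in j
    pres_vs_obs_b = obs.astype(float) @ P.T
    mismatches = pres_vs_obs_a + pres_vs_obs_b - 2.0 * both_present
    if kind == "squared_euclidean":
        L = dataset.n_loci
        d = mismatches * (L / shared)
    elif kind == "one_minus_relatedness":
        denom = 2.0 * both_present + mismatches
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(denom > 0, 2.0 * both_present / denom, 1.0)
        d = 1.0 - sim
    elif kind == "asymmetric_binary":
        denom = both_present + mismatches
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(denom > 0, mismatches / denom, 0.0)
    else:
        raise ValueError(f"unknown distance kind {kind!r}")
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # exact symmetry against float noise
    return DistanceMatrix(list(dataset.individual_ids), d, kind)


def classical_mds(dm: DistanceMatrix, dims: int = 2):
    """Classical (Torgerson) MDS: double-centred eigendecomposition.

    For a ``squared_euclidean`` matrix the entries are already squared
    dissimilarities; other kinds are squared first.  Coordinates are
    eigenvalue-ordered; negative eigenvalues (non-Euclidean input) are
    dropped with a warning.  Returns (coords, eigenvalues).
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    d2 = dm.matrix if dm.kind == "squared_euclidean" else dm.matrix**2
    n = d2.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-10 * abs(evals[0])) if evals.size else 0.0
    n_pos = int((evals > tol).sum())
    if (evals < -tol).any():
        warnings.warn("non-Euclidean distances: negative eigenvalues dropped")
    if dims > n_pos:
        raise ValueError(f"requested {dims} dimensions but only {n_pos} positive eigenvalues")
    coords = evecs[:, :dims] * np.sqrt(evals[:dims])
    return coords, evals


# ---------------------------------------------------------------------------
# Multi-locus F_ST


def _fst_from_counts(k1, n1, k2, n2, method="bayes", priors=None):
    """Hudson-style ratio-of-sums F_ST from dominant absence counts.

    Per locus: numerator (p1 - p2)^2 - se1^2 - se2^2 (the sampling-variance
    correction uses the delta-method variance of the square-root estimator),
    denominator p1 (1 - p2) + p2 (1 - p1); F_ST = sum(num) / sum(den).
    """
    if priors is None:
        priors = (None, None)
    q1 = dominant_freq.estimate_q(k1, n1, method=method, prior=priors[0])
    q2 = dominant_freq.estimate_q(k2, n2, method=method, prior=priors[1])
    p1, p2 = 1.0 - q1, 1.0 - q2
    with np.errstate(invalid="ignore", divide="ignore"):
        v1 = (1.0 - k1 / n1) / (4.0 * n1)
        v2 = (1.0 - k2 / n2) / (4.0 * n2)
    num = (p1 - p2) ** 2 - v1 - v2
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    ok = np.isfinite(num) & np.isfinite(den)
    denom = float(den[ok].sum())
    if denom <= 0:
        return np.nan
    return float(num[ok].sum()) / denom


def pairwise_fst(
    freq_table: pd.DataFrame,
    dataset: AFLPDataset,
    hierarchy: PopulationHierarchy,
    pop_a: str,
    pop_b: str,
    n_perm: int = 0,
    method: str = "bayes",
    rng=None,
) -> FstResult:
    """Multi-locus F_ST between two populations with a permutation test.

    The point estimate is computed from the supplied frequency table
    (ratio-of-sums over loci); the permutation p-value reassigns individuals
    to the two populations at random and re-estimates frequencies with the
    same estimator.  p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    """
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    sub = freq_table[freq_table["population"].isin([pop_a, pop_b])]
    wide_p = sub.pivot(index="locus", columns="population", values="p_hat").dropna()
    if wide_p.empty:
        raise ValueError("no shared loci with estimates in both populations")
    wide_se = sub.pivot(index="locus", columns="population", values="se").reindex(wide_p.index)
    pa = wide_p[pop_a].to_numpy()
    pb = wide_p[pop_b].to_numpy()
    va = np.nan_to_num(wide_se[pop_a].to_numpy() ** 2)
    vb = np.nan_to_num(wide_se[pop_b].to_numpy() ** 2)
    num = (pa - pb) ** 2 - va - vb
    den = pa * (1 - pb) + pb * (1 - pa)
    fst_obs = float(num.sum() / den.sum())

    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(rng)
        inds_a = [i for i in hierarchy.individuals_in(pop_a) if i in dataset.individual_ids]
        inds_b = [i for i in hierarchy.individuals_in(pop_b) if i in dataset.individual_ids]
        ridx = np.array([dataset.individual_ids.index(i) for i in inds_a + inds_b])
        pheno = dataset.phenotypes[ridx]
        na = len(inds_a)
        absent = (pheno == 0).astype(np.float64)
        observed = (pheno != MISSING).astype(np.float64)
        # observed statistic recomputed with the permutation estimator so the
        # reference distribution is exchangeable with it
        k1, n1 = absent[:na].sum(0), observed[:na].sum(0)
        k2, n2 = absent[na:].sum(0), observed[na:].sum(0)
        priors = _perm_priors(method, k1, n1, k2, n2)
        obs_perm_stat = _fst_from_counts(k1, n1, k2, n2, method, priors)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pheno.shape[0])
            ka, na_ = absent[perm[:na]].sum(0), observed[perm[:na]].sum(0)
            kb, nb_ = absent[perm[na:]].sum(0), observed[perm[na:]].sum(0)
            priors_p = _perm_priors(method, ka, na_, kb, nb_)
            if _fst_from_counts(ka, na_, kb, nb_, method, priors_p) >= obs_perm_stat:
                count += 1
        p_value = (count + 1) / (n_perm + 1)
    return FstResult(pop_a, pop_b, fst_obs, p_value, n_perm, len(wide_p))


def _perm_priors(method, k1, n1, k2, n2):
    if method not in ("bayes", "lynch_milligan"):
        return (None, None)
    priors = []
    for k, n in ((k1, n1), (k2, n2)):
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (k / np.where(n > 0, n, np.nan))[n > 0]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                priors.append(fit_beta_prior(f))
        except ValueError:
            priors.append(BetaPrior(1.0, 1.0))
    return tuple(priors)


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    table: pd.DataFrame  # one row per level
    n_permutations: int

    def percents(self) -> pd.Series:
        return self.table.set_index("level")["percent"]


_LEVELS = ("among_races", "among_pops_within_races", "among_sites_within_pops", "within_sites")


def _group_ss(d2: np.ndarray, groups: np.ndarray) -> float:
    """Sum over groups of (sum of pairwise squared distances within group)/n."""
    total = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if idx.size > 1:
            total += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return total


def _amova_components(d2, site_codes, pop_codes, race_codes):
    """Sums of squares and variance components of the 4-level decomposition.

    SS are partitioned from the squared-distance matrix; variance components
    come from equating mean squares to their expectations with unbalanced
    nested-design coefficients (Searle-type formulas).  Negative components
    are reported as estimated; percentages are computed after truncation at
    zero.
    """
    N = d2.shape[0]
    ss_total = d2.sum() / (2.0 * N)
    w_site = _group_ss(d2, site_codes)
    w_pop = _group_ss(d2, pop_codes)
    w_race = _group_ss(d2, race_codes)
    ss_w = w_site
    ss_site = w_pop - w_site
    ss_pop = w_race - w_pop
    ss_race = ss_total - w_race

    sites, site_inv = np.unique(site_codes, return_inverse=True)
    pops, pop_inv = np.unique(pop_codes, return_inverse=True)
    races, race_inv = np.unique(race_codes, return_inverse=True)
    S, P, R = len(sites), len(pops), len(races)
    n_s = np.bincount(site_inv).astype(float)
    n_p = np.bincount(pop_inv).astype(float)
    n_r = np.bincount(race_inv).astype(float)
    site_pop = np.array([pop_inv[site_inv == s][0] for s in range(S)])
    site_race = np.array([race_inv[site_inv == s][0] for s in range(S)])
    pop_race = np.array([race_inv[pop_inv == p][0] for p in range(P)])

    df_w = N - S
    df_site = S - P
    df_pop = P - R
    df_race = R - 1

    K_p = np.bincount(site_pop, weights=n_s**2, minlength=P) / n_p  # sum n_s^2 / n_p
    K_r = np.bincount(site_race, weights=n_s**2, minlength=R) / n_r
    L_r = np.bincount(pop_race, weights=n_p**2, minlength=R) / n_r

    sigma_w = ss_w / df_w if df_w > 0 else np.nan
    if df_site > 0:
        coef_c = (N - K_p.sum()) / df_site
        sigma_c = (ss_site / df_site - sigma_w) / coef_c
    else:
        sigma_c = np.nan
    if df_pop > 0:
        c1 = (K_p.sum() - K_r.sum()) / df_pop
        c2 = (N - L_r.sum()) / df_pop
        sigma_b = (ss_pop / df_pop - sigma_w - c1 * (0.0 if np.isnan(sigma_c) else sigma_c)) / c2
    else:
        sigma_b = np.nan
    if df_race > 0:
        c3 = (K_r.sum() - (n_s**2).sum() / N) / df_race
        c4 = (L_r.sum() - (n_p**2).sum() / N) / df_race
        c5 = (N - (n_r**2).sum() / N) / df_race
        sigma_a = (
            ss_race / df_race
            - sigma_w
            - c3 * (0.0 if np.isnan(sigma_c) else sigma_c)
            - c4 * (0.0 if np.isnan(sigma_b) else sigma_b)
        ) / c5
    else:
        sigma_a = np.nan

    ss = dict(zip(_LEVELS, (ss_race, ss_pop, ss_site, ss_w)))
    dfs = dict(zip(_LEVELS, (df_race, df_pop, df_site, df_w)))
    comps = dict(zip(_LEVELS, (sigma_a, sigma_b, sigma_c, sigma_w)))
    return ss, dfs, comps


def amova(
    data,
    hierarchy: PopulationHierarchy,
    distance_kind: str = "squared_euclidean",
    n_perm: int = 0,
    rng=None,
) -> AmovaResult:
    """4-level AMOVA: races / populations within races / sites within
    populations / within sites.

    ``data`` may be an AFLPDataset (distances computed with
    ``distance_kind``) or a precomputed DistanceMatrix.  Permutation
    p-values use the exchangeable unit appropriate to each level: whole
    populations are permuted among races, whole sites among populations
    within their race, and individuals among sites within their population;
    each level's observed variance component is compared with its permuted
    distribution (p = (1 + #{perm >= obs}) / (n_perm + 1)).  A degenerate
    level (a single group) yields an undefined (NaN) component.
    """
    if isinstance(data, AFLPDataset):
        dm = pairwise_distance(data, distance_kind)
    elif isinstance(data, DistanceMatrix):
        dm = data
    else:
        raise TypeError("data must be an AFLPDataset or DistanceMatrix")
    d2 = dm.matrix if dm.kind == "squared_euclidean" else dm.matrix**2

    tab = hierarchy.table.set_index("individual").loc[dm.individual_ids]
    site_lab = tab["site"].to_numpy()
    pop_lab = tab["population"].to_numpy()
    race_lab = tab["race"].to_numpy()
    _, site_codes = np.unique(site_lab, return_inverse=True)
    _, pop_codes = np.unique(pop_lab, return_inverse=True)
    _, race_codes = np.unique(race_lab, return_inverse=True)
    if len(np.unique(race_codes)) < 2:
        warnings.warn("single race: race-level component undefined")

    ss, dfs, comps = _amova_components(d2, site_codes, pop_codes, race_codes)
    comp_vals = np.array([comps[l] for l in _LEVELS])
    trunc = np.where(np.isnan(comp_vals), 0.0, np.clip(comp_vals, 0.0, None))
    total_trunc = trunc.sum()
    percents = 100.0 * trunc / total_trunc if total_trunc > 0 else np.full(4, np.nan)

    total_var = np.nansum(np.clip(comp_vals, 0.0, None))
    sa, sb, sc, sw = [0.0 if np.isnan(v) else max(v, 0.0) for v in comp_vals]
    phi = {
        "among_races": sa / total_var if total_var > 0 else np.nan,  # Phi_RT
        "among_pops_within_races": sb / (sb + sc + sw) if (sb + sc + sw) > 0 else np.nan,
        "among_sites_within_pops": sc / (sc + sw) if (sc + sw) > 0 else np.nan,
        "within_sites": (sa + sb + sc) / total_var if total_var > 0 else np.nan,  # Phi_ST
    }

    p_values = {l: np.nan for l in _LEVELS}
    if n_perm > 0:
        rng = np.random.default_rng(rng)
        pops, pop_inv = np.unique(pop_codes, return_inverse=True)
        sites, site_inv = np.unique(site_codes, return_inverse=True)
        pop_race = np.array([race_codes[pop_inv == p][0] for p in range(len(pops))])
        site_pop = np.array([pop_codes[site_inv == s][0] for s in range(len(sites))])

        count_race = count_pop = count_site = 0
        for _ in range(n_perm):
            # races: permute whole populations among races
            perm_pop_race = pop_race[rng.permutation(len(pops))]
            race_perm = perm_pop_race[pop_inv]
            c = _amova_components(d2, site_codes, pop_codes, race_perm)[2]
            if c["among_races"] >= comps["among_races"] - 1e-12:
                count_race += 1
            # populations: permute whole sites among populations within race
            perm_site_pop = site_pop.copy()
            for r in np.unique(pop_race):
                s_in_r = np.flatnonzero(pop_race[site_pop] == r)
                perm_site_pop[s_in_r] = site_pop[s_in_r[rng.permutation(s_in_r.size)]]
            pop_perm = perm_site_pop[site_inv]
            c = _amova_components(d2, site_codes, pop_perm, race_codes)[2]
            if c["among_pops_within_races"] >= comps["among_pops_within_races"] - 1e-12:
                count_pop += 1
            # sites: permute individuals among sites within population
            site_perm = site_codes.copy()
            for p in range(len(pops)):
                i_in_p = np.flatnonzero(pop_codes == p)
                site_perm[i_in_p] = site_codes[i_in_p[rng.permutation(i_in_p.size)]]
            c = _amova_components(d2, site_perm, pop_codes, race_codes)[2]
            if c["among_sites_within_pops"] >= comps["among_sites_within_pops"] - 1e-12:
                count_site += 1
        p_values["among_races"] = (count_race + 1) / (n_perm + 1)
        p_values["among_pops_within_races"] = (count_pop + 1) / (n_perm + 1)
        p_values["among_sites_within_pops"] = (count_site + 1) / (n_perm + 1)

    table = pd.DataFrame(
        {
            "level": _LEVELS,
            "df": [dfs[l] for l in _LEVELS],
            "sum_of_squares": [ss[l] for l in _LEVELS],
            "variance_component": comp_vals,
            "percent": percents,
            "phi": [phi[l] for l in _LEVELS],
            "p_value": [p_values[l] for l in _LEVELS],
        }
    )
    return AmovaResult(table, n_perm)


# ---------------------------------------------------------------------------
# Hybrid index


def _mix_loglik(q, band, p1, p2):
    p_mix = np.clip(q * p1 + (1.0 - q) * p2, 1e-9, 1.0 - 1e-9)
    log_absent = 2.0 * np.log1p(-p_mix)
    log_present = np.log1p(-np.square(1.0 - p_mix))
    return float(np.where(band == 1, log_present, log_absent).sum())


def hybrid_index(
    dataset: AFLPDataset,
    freq_table: pd.DataFrame,
    pop1: str,
    pop2: str,
    individuals: list[str] | None = None,
    grid_step: float = 0.001,
) -> list[HybridAssignment]:
    """Maximum-likelihood admixture proportion Q toward ``pop1``.

    Loci are treated as independent; at admixture Q the presence-allele
    frequency is p_mix = Q p1 + (1 - Q) p2 and the band probability is
    1 - (1 - p_mix)^2.  The optimum is located on a dense Q grid and refined
    locally.  Parental frequencies should be estimated excluding putative
    hybrids.  Individuals whose likelihood is flat (p1 = p2 at every scored
    locus) are flagged unidentifiable.
    """
    t = freq_table.set_index(["locus", "population"])["p_hat"]
    p1 = np.array([t.get((l, pop1), np.nan) for l in dataset.locus_ids])
    p2 = np.array([t.get((l, pop2), np.nan) for l in dataset.locus_ids])
    usable = np.isfinite(p1) & np.isfinite(p2)
    if not usable.any():
        raise ValueError("no loci with parental frequency estimates")
    ids = individuals if individuals is not None else dataset.individual_ids
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    results = []
    for ind in ids:
        row = dataset.row(ind)
        ok = usable & (row != MISSING)
        if not ok.any():
            raise ValueError(f"individual {ind!r} has no scored loci with estimates")
        band = row[ok].astype(float)
        a1, a2 = p1[ok], p2[ok]
        p_mix = np.clip(np.outer(grid, a1 - a2) + a2, 1e-9, 1 - 1e-9)
        ll = (
            np.where(band == 1, np.log1p(-np.square(1 - p_mix)), 2 * np.log1p(-p_mix))
        ).sum(axis=1)
        if ll.max() - ll.min() < 1e-9:
            results.append(HybridAssignment(ind, np.nan, float(ll[0]), identifiable=False))
            continue
        best = int(np.argmax(ll))
        lo = max(grid[best] - grid_step, 0.0)
        hi = min(grid[best] + grid_step, 1.0)
        opt = minimize_scalar(
            lambda q: -_mix_loglik(q, band, a1, a2), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-6},
        )
        results.append(HybridAssignment(ind, float(opt.x), float(-opt.fun)))
    return results


def classify_hybrids(
    assignments: list[HybridAssignment],
    nominal: dict[str, str],
    pop1: str,
    threshold: float = 0.98,
) -> list[HybridAssignment]:
    """Apply the hybrid designation rule (strict "< threshold").

    ``nominal`` maps individual -> nominal parental population.  The
    assignment proportion toward the nominal parent is Q when the nominal
    parent is ``pop1`` and 1 - Q otherwise; an individual is a hybrid when
    that proportion is < threshold, i.e. at least (1 - threshold) of its
    genome is assigned to the opposite cluster.  Updates and returns the
    assignments.
    """
    for a in assignments:
        pop = nominal.get(a.individual)
        if pop is None:
            raise ValueError(f"no nominal population for {a.individual!r}")
        a.nominal_population = pop
        if not a.identifiable or not np.isfinite(a.Q):
            a.is_hybrid = None
            continue
        toward_nominal = a.Q if pop == pop1 else 1.0 - a.Q
        a.is_hybrid = bool(toward_nominal < threshold)
    return assignments
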