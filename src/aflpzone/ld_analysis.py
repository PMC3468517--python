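"""Gametic disequilibrium between pairs of dominant loci, and the
outlier-vs-neutral LD contrast controlled for parental allele-frequency
differences.

For two dominant loci the observable data are the four phenotype classes
(++, +-, -+, --), where "+" is band presence.  Writing A/B for the presence
alleles, a/b for the absence alleles and f_AB, f_Ab, f_aB, f_ab for the four
haplotype frequencies, HWE and random mating give class probabilities

    P(--) = f_ab**2
    P(-+) = q_A**2 - f_ab**2        q_A = f_aB + f_ab
    P(+-) = q_B**2 - f_ab**2        q_B = f_Ab + f_ab
    P(++) = 1 - q_A**2 - q_B**2 + f_ab**2

An EM algorithm maximises the multinomial likelihood over the haplotype
simplex; the disequilibrium coefficient is D = f_AB - p_A * p_B
(= f_AB * f_ab - f_Ab * f_aB), bounded by |D| <= 0.25.

In a hybrid zone, migration alone generates LD in proportion to the product
of the two loci's allele-frequency differences between the parental
populations, (p - q)(r - s).  The contrast therefore compares outlier locus
pairs against neutral pairs restricted to the same tail of that product
(beyond +/-0.75 by default), using one-tailed Welch t-tests on D polarised
by sign((p - q)(r - s)) so that parental-combination association is positive
regardless of band coding.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aflp_io import MISSING, AFLPDataset, filter_polymorphism

__all__ = [
    "LDEstimate",
    "AFDProduct",
    "TailComparison",
    "LDComparisonResult",
    "phenotype_counts",
    "closed_form_ld_dominant",
    "em_ld_dominant",
    "grid_ld_dominant",
    "max_pairwise_d",
    "pairwise_ld_matrix",
    "afd_product",
    "polarize",
    "compare_outlier_vs_neutral_ld",
]

logger = logging.getLogger(__name__)

# haplotype order used throughout: AB, Ab, aB, ab
_HAPS = ("AB", "Ab", "aB", "ab")
_HAS_A = np.array([1, 1, 0, 0])
_HAS_B = np.array([1, 0, 1, 0])

# unordered genotype enumeration (i <= j over the 4 haplotypes)
_GENO = [(i, j) for i in range(4) for j in range(i, 4)]
# phenotype class of each genotype in counts order (++, +-, -+, --)
def _class_of(i: int, j: int) -> int:
    pres1 = _HAS_A[i] or _HAS_A[j]
    pres2 = _HAS_B[i] or _HAS_B[j]
    return {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(pres1, pres2)]


_GENO_CLASS = np.array([_class_of(i, j) for i, j in _GENO])
# haplotype incidence per genotype (counts of each haplotype in the pair)
_GENO_HAPS = np.zeros((len(_GENO), 4))
for g, (i, j) in enumerate(_GENO):
    _GENO_HAPS[g, i] += 1
    _GENO_HAPS[g, j] += 1
_GENO_MULT = np.array([1.0 if i == j else 2.0 for i, j in _GENO])


@dataclass
class LDEstimate:
    """ML haplotype frequencies and D for one pair of dominant loci."""

    locus1: str
    locus2: str
    f_AB: float
    f_Ab: float
    f_aB: float
    f_ab: float
    n: int
    converged: bool = True
    iterations: int = 0
    loglik: float = np.nan
    D_polarized: float = np.nan

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([self.f_AB, self.f_Ab, self.f_aB, self.f_ab])

    @property
    def p_A(self) -> float:
        return self.f_AB + self.f_Ab

    @property
    def p_B(self) -> float:
        return self.f_AB + self.f_aB

    @property
    def D(self) -> float:
        return self.f_AB * self.f_ab - self.f_Ab * self.f_aB


@dataclass(frozen=True)
class AFDProduct:
    """(p - q)(r - s): product of parental presence-allele frequency
    differences for a locus pair, with the tail class at the given cutoff."""

    locus1: str
    locus2: str
    product: float
    class_label: str  # same_pop_fixed_like | opposite_pop_fixed_like | intermediate


def phenotype_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    """2x2 phenotype table (n_pp, n_pa, n_ap, n_aa); missing cells pairwise-deleted."""
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    n_pp = int(((x == 1) & (y == 1)).sum())
    n_pa = int(((x == 1) & (y == 0)).sum())
    n_ap = int(((x == 0) & (y == 1)).sum())
    n_aa = int(((x == 0) & (y == 0)).sum())
    return n_pp, n_pa, n_ap, n_aa


def _class_probs(f: np.ndarray) -> np.ndarray:
    q_a = f[2] + f[3]
    q_b = f[1] + f[3]
    return np.array(
        [
            1.0 - q_a**2 - q_b**2 + f[3] ** 2,
            q_b**2 - f[3] ** 2,
            q_a**2 - f[3] ** 2,
            f[3] ** 2,
        ]
    )


def _loglik(counts: np.ndarray, f: np.ndarray) -> float:
    probs = np.clip(_class_probs(f), 1e-300, None)
    return float(np.dot(counts, np.log(probs)))


def closed_form_ld_dominant(counts, locus1: str = "L1", locus2: str = "L2") -> LDEstimate | None:
    """Moment/ML identity for the haplotype frequencies.

    f_ab = sqrt(n_aa / n), q_A = sqrt((n_ap + n_aa)/n), q_B = sqrt((n_pa +
    n_aa)/n), with the remaining frequencies by subtraction.  This solves the
    likelihood equations exactly whenever the implied frequencies are all in
    [0, 1]; otherwise the MLE sits on the simplex boundary and ``None`` is
    returned to signal that the EM path is required.
    """
    n_pp, n_pa, n_ap, n_aa = counts
    n = n_pp + n_pa + n_ap + n_aa
    if n <= 0:
        raise ValueError("empty phenotype table")
    f_ab = np.sqrt(n_aa / n)
    q_a = np.sqrt((n_ap + n_aa) / n)
    q_b = np.sqrt((n_pa + n_aa) / n)
    f_aB = q_a - f_ab
    f_Ab = q_b - f_ab
    f_AB = 1.0 - q_a - q_b + f_ab
    f = np.array([f_AB, f_Ab, f_aB, f_ab])
    if np.any(f < 0) or np.any(f > 1):
        return None
    counts_arr = np.asarray(counts, dtype=float)
    return LDEstimate(
        locus1, locus2, *f, n=int(n), converged=True, iterations=0,
        loglik=_loglik(counts_arr, f),
    )


def em_ld_dominant(
    counts,
    locus1: str = "L1",
    locus2: str = "L2",
    tol: float = 1e-8,
    max_iter: int = 10_000,
    polish: bool = True,
) -> LDEstimate:
    """EM maximum-likelihood haplotype frequencies for two dominant loci.

    E-step: the 2n haplotypes of each phenotype class are distributed over
    the compatible genotypes in proportion to their current expected
    frequencies; M-step: renormalise the expected haplotype counts.
    Initialisation is at linkage equilibrium computed from the marginal
    square-root frequency estimates; convergence is a log-likelihood change
    below ``tol``.  With ``polish`` (default), the closed-form solution
    replaces the EM iterate when it is feasible and at least as likely --
    this returns exact boundary values (e.g. D = 0.25 for a fully associated
    table) instead of an asymptotic EM approach to them.
    """
    n_pp, n_pa, n_ap, n_aa = counts
    n = n_pp + n_pa + n_ap + n_aa
    if n <= 0:
        raise ValueError("empty phenotype table")
    counts_arr = np.asarray(counts, dtype=float)
    eps = 1e-9
    q_a = np.clip(np.sqrt((n_ap + n_aa) / n), eps, 1 - eps)
    q_b = np.clip(np.sqrt((n_pa + n_aa) / n), eps, 1 - eps)
    f = np.array(
        [(1 - q_a) * (1 - q_b), (1 - q_a) * q_b, q_a * (1 - q_b), q_a * q_b]
    )
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    ll = _loglik(counts_arr, f)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        geno_prob = _GENO_MULT * f[[g[0] for g in _GENO]] * f[[g[1] for g in _GENO]]
        class_tot = np.bincount(_GENO_CLASS, weights=geno_prob, minlength=4)
        with np.errstate(divide="ignore", invalid="ignore"):
            weight = np.where(
                class_tot[_GENO_CLASS] > 0,
                counts_arr[_GENO_CLASS] * geno_prob / class_tot[_GENO_CLASS],
                0.0,
            )
        hap_counts = _GENO_HAPS.T @ weight
        f_new = hap_counts / (2.0 * n)
        f_new = np.clip(f_new, 1e-15, None)
        f_new /= f_new.sum()
        ll_new = _loglik(counts_arr, f_new)
        f = f_new
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        logger.warning("EM did not converge for pair (%s, %s) after %d iterations",
                       locus1, locus2, max_iter)
    if polish:
        cf = closed_form_ld_dominant(counts, locus1, locus2)
        if cf is not None and cf.loglik >= ll - 1e-12:
            cf.converged = converged
            cf.iterations = it
            return cf
    return LDEstimate(
        locus1, locus2, *f, n=int(n), converged=converged, iterations=it, loglik=ll
    )


def grid_ld_dominant(counts, coarse: float = 0.01, fine: float = 0.001) -> LDEstimate:
    """Brute-force constrained MLE by grid search over the haplotype simplex.

    Independent oracle for the EM: a coarse grid over (q_A, q_B, f_ab) within
    the feasibility region locates the basin, then a local grid at the fine
    step resolves the optimum to ``fine``.  Parameterising by the two
    absence-allele frequencies and f_ab spans the simplex exactly.
    """
    counts_arr = np.asarray(counts, dtype=float)
    n = counts_arr.sum()
    if n <= 0:
        raise ValueError("empty phenotype table")

    def evaluate(qa, qb, fab):
        qa, qb, fab = np.broadcast_arrays(qa, qb, fab)
        f_ab = fab
        f_aB = qa - f_ab
        f_Ab = qb - f_ab
        f_AB = 1.0 - qa - qb + f_ab
        ok = (f_aB >= -1e-12) & (f_Ab >= -1e-12) & (f_AB >= -1e-12)
        p = np.stack(
            [
                1.0 - qa**2 - qb**2 + f_ab**2,
                qb**2 - f_ab**2,
                qa**2 - f_ab**2,
                f_ab**2,
            ]
        )
        p = np.clip(p, 1e-300, None)
        ll = np.tensordot(counts_arr, np.log(p), axes=(0, 0))
        ll = np.where(ok, ll, -np.inf)
        return ll

    grid = np.arange(0.0, 1.0 + 1e-12, coarse)
    qa, qb, fab = np.meshgrid(grid, grid, grid, indexing="ij", sparse=True)
    ll = evaluate(qa, qb, fab)
    idx = np.unravel_index(np.argmax(ll), ll.shape)
    best = np.array([grid[idx[0]], grid[idx[1]], grid[idx[2]]])

    span = np.arange(-coarse, coarse + 1e-12, fine)
    qa = np.clip(best[0] + span, 0, 1)[:, None, None]
    qb = np.clip(best[1] + span, 0, 1)[None, :, None]
    fab = np.clip(best[2] + span, 0, 1)[None, None, :]
    ll = evaluate(qa, qb, fab)
    idx = np.unravel_index(np.argmax(ll), ll.shape)
    qa_b = float(np.clip(best[0] + span[idx[0]], 0, 1))
    qb_b = float(np.clip(best[1] + span[idx[1]], 0, 1))
    fab_b = float(np.clip(best[2] + span[idx[2]], 0, 1))
    f = np.array(
        [1.0 - qa_b - qb_b + fab_b, qb_b - fab_b, qa_b - fab_b, fab_b]
    )
    f = np.clip(f, 0.0, 1.0)
    return LDEstimate(
        "L1", "L2", *f, n=int(n), converged=True, iterations=0,
        loglik=_loglik(counts_arr, f),
    )


def max_pairwise_d(step: float = 0.01) -> float:
    """Maximum of D = f_AB*f_ab - f_Ab*f_aB over the haplotype simplex.

    Evaluated by direct search on a grid containing the analytic optimum
    f_AB = f_ab = 1/2 (perfect coupling of two loci at frequency 1/2), where
    D attains its global maximum of 0.25.
    """
    grid = np.arange(0.0, 1.0 + 1e-12, step)
    best = -np.inf
    for f_ab in grid:
        f_AB = np.arange(0.0, 1.0 - f_ab + 1e-12, step)
        rem = 1.0 - f_ab - f_AB
        # interior f_Ab, f_aB only reduce D; D is maximised at f_Ab = f_aB = 0
        best = max(best, float(np.max(f_AB * f_ab)))
        d_with_rem = f_AB * f_ab - (rem / 2.0) ** 2
        best = max(best, float(np.max(d_with_rem)))
    return best


def pairwise_ld_matrix(
    dataset: AFLPDataset,
    loci: list[str] | None = None,
    individuals: list[str] | None = None,
    min_n: int = 10,
    **em_kwargs,
) -> list[LDEstimate]:
    """EM LD estimate for every unordered pair of the given loci.

    Missing cells are pairwise-deleted per pair; pairs with fewer than
    ``min_n`` jointly observed individuals, or monomorphic within the pair's
    observed table, are skipped with a log entry.
    """
    loci = list(loci) if loci is not None else dataset.locus_ids
    if len(loci) < 2:
        raise ValueError("need at least two loci after filtering")
    sub = dataset.subset(individuals=individuals) if individuals is not None else dataset
    cols = {l: sub.phenotypes[:, sub.locus_ids.index(l)] for l in loci}
    estimates = []
    for l1, l2 in itertools.combinations(loci, 2):
        counts = phenotype_counts(cols[l1], cols[l2])
        n = sum(counts)
        if n < min_n:
            logger.info("skipping pair (%s, %s): only %d joint observations", l1, l2, n)
            continue
        n_pp, n_pa, n_ap, n_aa = counts
        if (n_pa + n_aa) in (0, n) or (n_ap + n_aa) in (0, n):
            logger.info("skipping pair (%s, %s): monomorphic in joint table", l1, l2)
            continue
        estimates.append(em_ld_dominant(counts, l1, l2, **em_kwargs))
    return estimates


def afd_product(
    freq_table: pd.DataFrame,
    pop1: str,
    pop2: str,
    locus1: str,
    locus2: str,
    cutoff: float = 0.75,
) -> AFDProduct:
    """(p - q)(r - s) from parental presence-allele frequency estimates.

    p, r are the presence frequencies of the two loci in ``pop1``; q, s in
    ``pop2``.  A product beyond +cutoff marks a pair behaving like both loci
    fixed in the same population; beyond -cutoff, fixed in opposite
    populations.
    """
    t = freq_table.set_index(["locus", "population"])["p_hat"]
    try:
        p, q = t[(locus1, pop1)], t[(locus1, pop2)]
        r, s = t[(locus2, pop1)], t[(locus2, pop2)]
    except KeyError as exc:
        raise ValueError(f"missing frequency estimate for {exc.args[0]}") from None
    prod = float((p - q) * (r - s))
    if prod > cutoff:
        label = "same_pop_fixed_like"
    elif prod < -cutoff:
        label = "opposite_pop_fixed_like"
    else:
        label = "intermediate"
    return AFDProduct(locus1, locus2, prod, label)


def polarize(estimates: list[LDEstimate], products: dict[tuple[str, str], float]) -> None:
    """Attach D_polarized = D * sign((p-q)(r-s)) to each estimate in place.

    ``products`` maps unordered locus-ID pairs (both orders accepted) to the
    allele-frequency-difference product.
    """
    for est in estimates:
        key = (est.locus1, est.locus2)
        prod = products.get(key, products.get((key[1], key[0])))
        if prod is None:
            continue
        est.D_polarized = est.D * float(np.sign(prod)) if prod != 0 else 0.0


def outlier_vs_neutral_contrast(
    dataset: AFLPDataset,
    hybrid_individuals: list[str],
    freq_table: pd.DataFrame,
    pop1: str,
    pop2: str,
    outlier_set: set[str],
    cutoff: float = 0.75,
    polymorphism_threshold: float = 0.10,
    min_n: int = 10,
):
    """Full LD contrast: filter, select candidate pairs, estimate, compare.

    Loci are filtered for polymorphism within the hybrid sample (LD is
    unstable at low allele frequencies), then restricted to candidates that
    can reach the product cutoff: the outliers plus every neutral locus
    whose parental presence-frequency difference satisfies |p - q| >=
    cutoff.  LD is estimated by EM in the hybrid individuals for every
    candidate pair, products are computed from the parental frequency
    estimates, and the per-tail Welch comparison is returned along with the
    estimates and products.
    """
    filtered, _ = filter_polymorphism(dataset, hybrid_individuals, polymorphism_threshold)
    t = freq_table.set_index(["locus", "population"])["p_hat"]
    candidates = []
    for locus in filtered.locus_ids:
        if locus in outlier_set:
            candidates.append(locus)
            continue
        try:
            diff = abs(t[(locus, pop1)] - t[(locus, pop2)])
        except KeyError:
            continue
        if diff >= cutoff:
            candidates.append(locus)
    estimates = pairwise_ld_matrix(
        filtered, loci=candidates, individuals=hybrid_individuals, min_n=min_n
    )
    products = [
        afd_product(freq_table, pop1, pop2, e.locus1, e.locus2, cutoff) for e in estimates
    ]
    result = compare_outlier_vs_neutral_ld(estimates, products, outlier_set, cutoff)
    return result, estimates, products


@dataclass
class TailComparison:
    tail: str  # "positive" or "negative"
    cutoff: float
    mean_outlier: float
    mean_neutral: float
    t: float
    df: float
    p: float
    n_outlier_pairs: int
    n_neutral_pairs: int


@dataclass
class LDComparisonResult:
    positive: TailComparison | None
    negative: TailComparison | None

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(t) for t in (self.positive, self.negative) if t is not None]
        return pd.DataFrame(rows)


def compare_outlier_vs_neutral_ld(
    estimates: list[LDEstimate],
    products: list[AFDProduct],
    outlier_set: set[str],
    cutoff: float = 0.75,
) -> LDComparisonResult:
    """One-tailed Welch t-tests of outlier-pair vs neutral-pair LD per tail.

    Each tail of the (p - q)(r - s) distribution is tested separately
    (the LD-vs-product scatter is asymmetric): outlier x outlier pairs with
    product beyond the cutoff on that tail against neutral x neutral pairs
    beyond the same cutoff; mixed outlier x neutral pairs are excluded.  The
    alternative is mean(outlier LD) > mean(neutral LD) on polarised D.  A
    tail with fewer than two pairs in either group is reported as
    unavailable (None).
    """
    if not outlier_set:
        raise ValueError("outlier set is empty")
    prod_map = {(p.locus1, p.locus2): p.product for p in products}
    polarize(estimates, prod_map)

    def group(est: LDEstimate) -> str | None:
        o1, o2 = est.locus1 in outlier_set, est.locus2 in outlier_set
        if o1 and o2:
            return "outlier"
        if not o1 and not o2:
            return "neutral"
        return None

    tails = {}
    for sign, name in ((1, "positive"), (-1, "negative")):
        out_vals, neut_vals = [], []
        for est in estimates:
            prod = prod_map.get((est.locus1, est.locus2), prod_map.get((est.locus2, est.locus1)))
            if prod is None or not np.isfinite(est.D_polarized):
                continue
            if sign * prod <= cutoff:
                continue
            g = group(est)
            if g == "outlier":
                out_vals.append(est.D_polarized)
            elif g == "neutral":
                neut_vals.append(est.D_polarized)
        if len(out_vals) < 2 or len(neut_vals) < 2:
            logger.warning("tail %r unavailable: %d outlier / %d neutral pairs",
                           name, len(out_vals), len(neut_vals))
            tails[name] = None
            continue
        res = stats.ttest_ind(out_vals, neut_vals, equal_var=False, alternative="greater")
        tails[name] = TailComparison(
            tail=name,
            cutoff=cutoff,
            mean_outlier=float(np.mean(out_vals)),
            mean_neutral=float(np.mean(neut_vals)),
            t=float(res.statistic),
            df=float(res.df),
            p=float(res.pvalue),
            n_outlier_pairs=len(out_vals),
            n_neutral_pairs=len(neut_vals),
        )
    return LDComparisonResult(positive=tails["positive"], negative=tails["negative"])
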