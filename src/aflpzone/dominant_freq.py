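"""Allele-frequency estimation for dominant markers under Hardy-Weinberg.

A dominant locus exposes only the band phenotype: ``present`` covers both the
presence-homozygote and the heterozygote, while ``absent`` implies the
absence-homozygote.  Under HWE the band-absence probability is x = q**2 where
q is the absence-allele frequency, so q can be recovered from the fraction of
band-absent individuals.  Three estimators are provided:

* ``sqrt``           -- q_hat = sqrt(k/n), the plain HWE plug-in.
* ``lynch_milligan`` -- the bias-corrected square-root estimator,
  q_hat = sqrt(x) / (1 - Var(x)/(8 x^2)) with x = k/n; the concave square
  root under-estimates q on average and the correction inflates it back.
* ``bayes``          -- posterior mean of sqrt(x) under a Beta prior on the
  band-absence probability x, the non-uniform-prior Bayesian approach used
  for AFLP data: with prior Beta(a, b), the posterior of x given k absent
  out of n is Beta(a + k, b + n - k) and
  q_hat = B(a + k + 1/2, b + n - k) / B(a + k, b + n - k).
  The prior is fitted across loci by the method of moments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln

from .aflp_io import MISSING, AFLPDataset, PopulationHierarchy

__all__ = [
    "BetaPrior",
    "estimate_q_sqrt",
    "estimate_q_lynch_milligan",
    "fit_beta_prior",
    "estimate_q_bayes",
    "allele_freq_table",
]


@dataclass(frozen=True)
class BetaPrior:
    """Beta(a, b) prior on the band-absence probability x = q**2."""

    a: float
    b: float
    fitted_from: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta prior shapes must be positive")


UNIFORM_PRIOR = BetaPrior(1.0, 1.0)


def estimate_q_sqrt(k, n):
    """Plain HWE estimator q_hat = sqrt(k/n); vectorised over k, n."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("sample size n must be positive")
    out = np.sqrt(k / n)
    return float(out) if out.ndim == 0 else out


def estimate_q_lynch_milligan(k, n):
    """Bias-corrected square-root estimator; requires k >= 1.

    q_hat = sqrt(x) * (1 - Var(x)/(8 x^2))**-1 with x = k/n and
    Var(x) = x(1-x)/n, clipped to [sqrt(x), 1].  At x = 0 the correction is
    undefined; callers should fall back to the Bayesian estimator there.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("sample size n must be positive")
    if np.any(k < 1):
        raise ValueError("Lynch-Milligan estimator undefined for k = 0; use the Bayesian fallback")
    x = k / n
    var = x * (1.0 - x) / n
    q = np.sqrt(x) / (1.0 - var / (8.0 * x**2))
    out = np.clip(q, np.sqrt(x), 1.0)
    return float(out) if out.ndim == 0 else out


def fit_beta_prior(absence_phenotype_freqs) -> BetaPrior:
    """Method-of-moments Beta fit to the across-locus band-absence frequencies.

    Degenerate inputs (zero variance, or variance incompatible with a Beta)
    fall back to the uniform prior with a warning.
    """
    x = np.asarray(absence_phenotype_freqs, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError(f"need >= 10 loci to fit the prior, got {x.size}")
    if np.any((x < 0) | (x > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    m = float(np.mean(x))
    v = float(np.var(x))
    if v < 1e-12 or m <= 0 or m >= 1 or v >= m * (1.0 - m):
        warnings.warn("degenerate across-locus frequency distribution; using uniform prior")
        return BetaPrior(1.0, 1.0, fitted_from=int(x.size))
    common = m * (1.0 - m) / v - 1.0
    return BetaPrior(m * common, (1.0 - m) * common, fitted_from=int(x.size))


def estimate_q_bayes(k, n, prior: BetaPrior = UNIFORM_PRIOR):
    """Posterior mean of q = sqrt(x) under a Beta prior on x; vectorised.

    Accepts n = 0 (returns the prior mean of sqrt(x)).
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 0) or np.any(k > n):
        raise ValueError("need 0 <= k <= n")
    a = prior.a + k
    b = prior.b + n - k
    out = np.exp(betaln(a + 0.5, b) - betaln(a, b))
    return float(out) if out.ndim == 0 else out


def _bayes_posterior_sd(k, n, prior: BetaPrior):
    """Posterior standard deviation of q = sqrt(x)."""
    a = prior.a + np.asarray(k, dtype=float)
    b = prior.b + np.asarray(n, dtype=float) - np.asarray(k, dtype=float)
    mean_q = np.exp(betaln(a + 0.5, b) - betaln(a, b))
    mean_x = a / (a + b)
    return np.sqrt(np.maximum(mean_x - mean_q**2, 0.0))


def _sqrt_se(k, n):
    """Delta-method SE of sqrt(k/n): Var(q_hat) ~ (1 - x) / (4 n)."""
    x = np.asarray(k, dtype=float) / np.asarray(n, dtype=float)
    return np.sqrt((1.0 - x) / (4.0 * np.asarray(n, dtype=float)))


def group_absence_counts(dataset: AFLPDataset, individuals: list[str]):
    """(k, n) per locus: band-absent count and non-missing count."""
    ridx = [dataset.individual_ids.index(i) for i in individuals]
    sub = dataset.phenotypes[ridx]
    k = (sub == 0).sum(axis=0).astype(float)
    n = (sub != MISSING).sum(axis=0).astype(float)
    return k, n


def estimate_q(k, n, method: str = "bayes", prior: BetaPrior | None = None):
    """Vectorised dispatcher used by the table builder and permutation tests.

    For ``lynch_milligan``, loci with k = 0 fall back to the Bayesian
    estimator (the bias correction is undefined at a fixed band).
    """
    k = np.atleast_1d(np.asarray(k, dtype=float))
    n = np.atleast_1d(np.asarray(n, dtype=float))
    q = np.full(k.shape, np.nan)
    ok = n > 0
    if method == "sqrt":
        q[ok] = np.sqrt(k[ok] / n[ok])
    elif method == "lynch_milligan":
        if prior is None:
            prior = UNIFORM_PRIOR
        lm = ok & (k >= 1)
        if lm.any():
            q[lm] = estimate_q_lynch_milligan(k[lm], n[lm])
        fb = ok & (k < 1)
        if fb.any():
            q[fb] = estimate_q_bayes(k[fb], n[fb], prior)
    elif method == "bayes":
        if prior is None:
            prior = UNIFORM_PRIOR
        q[ok] = estimate_q_bayes(k[ok], n[ok], prior)
    else:
        raise ValueError(f"unknown method {method!r}")
    return q


def allele_freq_table(
    dataset: AFLPDataset,
    hierarchy: PopulationHierarchy,
    grouping: str = "population",
    method: str = "bayes",
    exclude: list[str] | None = None,
) -> pd.DataFrame:
    """Per-locus, per-group presence/absence allele frequency estimates.

    Returns a DataFrame with columns locus, population, n, k, q_hat, p_hat,
    se, method.  ``exclude`` removes individuals (e.g. putative hybrids)
    before estimation.  For the Bayesian and Lynch-Milligan methods a Beta
    prior is fitted per group from that group's across-locus band-absence
    frequencies.  Groups with zero non-missing individuals at a locus get a
    NaN estimate (flagged by n = 0).
    """
    if grouping not in ("population", "site", "race"):
        raise ValueError("grouping must be 'population', 'site' or 'race'")
    excluded = set(exclude or ())
    frames = []
    for label in hierarchy.labels(grouping):
        inds = [
            i
            for i in hierarchy.individuals_in(label, grouping)
            if i not in excluded and i in dataset.individual_ids
        ]
        if not inds:
            continue
        k, n = group_absence_counts(dataset, inds)
        prior = None
        if method in ("bayes", "lynch_milligan"):
            with np.errstate(invalid="ignore"):
                freqs = (k / np.where(n > 0, n, np.nan))[n > 0]
            try:
                prior = fit_beta_prior(freqs)
            except ValueError:
                prior = UNIFORM_PRIOR
        q = estimate_q(k, n, method=method, prior=prior)
        if method == "bayes":
            se = _bayes_posterior_sd(k, np.maximum(n, 0), prior)
            se[n == 0] = np.nan
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                se = _sqrt_se(k, np.where(n > 0, n, np.nan))
        frames.append(
            pd.DataFrame(
                {
                    "locus": dataset.locus_ids,
                    "population": label,
                    "n": n.astype(int),
                    "k": k.astype(int),
                    "q_hat": q,
                    "p_hat": 1.0 - q,
                    "se": se,
                    "method": method,
                }
            )
        )
    if not frames:
        raise ValueError("no individuals left after exclusions")
    return pd.concat(frames, ignore_index=True)
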