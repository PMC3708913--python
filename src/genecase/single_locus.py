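"""Single-locus case-control statistics.

Hardy-Weinberg goodness of fit, Pearson chi-square association on
genotype and allele tables, crude odds ratios under additive / dominant /
recessive codings with Woolf (log-OR Wald) confidence intervals,
covariate-adjusted odds ratios by logistic regression, a two-proportion
power approximation, and baseline-characteristic comparisons.

The "additive model" OR (crude and adjusted) is the per-allele logistic
regression coefficient on the 0/1/2 minor-allele dose; dominant and
recessive ORs come from the collapsed 2x2 tables.  No multiple-testing
correction is applied anywhere: raw p-values are reported.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import MISSING, CohortTable, GenotypeCountTable, LocusSpec, allele_frequency

GENETIC_MODELS = ("additive", "dominant", "recessive")

Z_95 = stats.norm.ppf(0.975)


@dataclasses.dataclass
class HWEResult:
    locus: LocusSpec | None
    group: str
    chi2: float
    df: int
    p: float
    monomorphic: bool = False


@dataclasses.dataclass
class AssocResult:
    """Odds ratio with 95% CI and Wald p under one genetic model."""

    locus: LocusSpec
    model: str
    or_crude: float | None = None
    ci_crude: tuple[float, float] | None = None
    p_crude: float | None = None
    or_adjusted: float | None = None
    ci_adjusted: tuple[float, float] | None = None
    p_adjusted: float | None = None
    converged: bool = True


def hwe_test(counts: Sequence[int], locus: LocusSpec | None = None, group: str = "") -> HWEResult:
    """Pearson goodness-of-fit test of Hardy-Weinberg proportions (1 df).

    Expected genotype counts come from the sample allele frequency; no
    continuity correction.  A monomorphic locus is flagged and returns
    chi2 = 0, p = 1.
    """
    n0, n1, n2 = counts
    n = n0 + n1 + n2
    if n <= 0:
        raise ValueError("hwe_test on empty counts")
    q = allele_frequency(counts)
    p = 1.0 - q
    if q == 0.0 or q == 1.0:
        return HWEResult(locus, group, 0.0, 1, 1.0, monomorphic=True)
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    chi2 = float((((np.array(counts) - expected) ** 2) / expected).sum())
    return HWEResult(locus, group, chi2, 1, float(stats.chi2.sf(chi2, 1)))


def _pearson(table: np.ndarray) -> tuple[float, int, float]:
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square on a table with a zero margin")
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 1).any():
        raise ValueError("expected cell count below 1; chi-square invalid")
    return float(chi2), int(df), float(p)


def genotype_chi2(table: GenotypeCountTable) -> tuple[float, int, float]:
    """Pearson chi-square on the 3x2 genotype table (2 df)."""
    return _pearson(table.as_array())


def allele_table(table: GenotypeCountTable) -> np.ndarray:
    """2x2 allele counts: rows (cases, controls), cols (minor, major)."""
    out = []
    for n0, n1, n2 in (table.case_counts, table.control_counts):
        out.append([n1 + 2 * n2, 2 * n0 + n1])
    return np.array(out, dtype=float)


def allele_chi2(table: GenotypeCountTable) -> tuple[float, int, float]:
    """Pearson chi-square on the 2x2 allele table (1 df)."""
    return _pearson(allele_table(table))


def _collapse_2x2(table: GenotypeCountTable, model: str) -> np.ndarray:
    """Exposed/unexposed 2x2, rows (cases, controls), cols (exposed, ref)."""
    rows = []
    for n0, n1, n2 in (table.case_counts, table.control_counts):
        if model == "dominant":
            rows.append([n1 + n2, n0])
        elif model == "recessive":
            rows.append([n2, n0 + n1])
        else:
            raise ValueError(f"unknown genetic model {model!r}")
    return np.array(rows, dtype=float)


def odds_ratio_2x2(a: float, b: float, c: float, d: float,
                   continuity: bool = False) -> tuple[float, tuple[float, float], float]:
    """OR = ad/bc with Woolf 95% CI and two-sided Wald p.

    ``continuity`` applies the Haldane-Anscombe +0.5 to every cell, only
    meant for tables with a zero cell.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        if not continuity:
            raise ValueError("zero cell in 2x2; enable continuity correction")
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = np.log(a * d / (b * c))
    se = np.sqrt((1.0 / cells).sum())
    ci = (float(np.exp(log_or - Z_95 * se)), float(np.exp(log_or + Z_95 * se)))
    p = float(2 * stats.norm.sf(abs(log_or) / se))
    return float(np.exp(log_or)), ci, p


def crude_or(table: GenotypeCountTable, model: str, continuity: bool = False) -> AssocResult:
    """Unadjusted OR for one locus under one genetic model.

    Dominant collapses carriers (het + minor-hom) against major-hom and
    recessive collapses minor-hom against the rest, each scored as a
    2x2 with a Woolf CI.  The additive model is the per-allele logistic
    regression on the 0/1/2 dose (the genotype counts determine that
    fit exactly); the allele-count 2x2 approximates it but drifts by a
    rounding unit at some loci.
    """
    if model == "additive":
        dose = np.concatenate([np.repeat([0.0, 1.0, 2.0], row)
                               for row in (table.case_counts, table.control_counts)])
        y = np.concatenate([np.ones(table.n_cases), np.zeros(table.n_controls)])
        fit = logistic_fit(np.column_stack([np.ones_like(dose), dose]), y)
        b, se = fit.coef[1], float(np.sqrt(fit.cov[1, 1]))
        return AssocResult(
            table.locus, model,
            or_crude=float(np.exp(b)),
            ci_crude=(float(np.exp(b - Z_95 * se)), float(np.exp(b + Z_95 * se))),
            p_crude=float(2 * stats.norm.sf(abs(b) / se)),
            converged=fit.converged)
    t = _collapse_2x2(table, model)
    or_, ci, p = odds_ratio_2x2(t[0, 0], t[0, 1], t[1, 0], t[1, 1], continuity=continuity)
    return AssocResult(table.locus, model, or_crude=or_, ci_crude=ci, p_crude=p)


# ---------------------------------------------------------------------------
# logistic regression (IRLS)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LogisticFit:
    coef: np.ndarray
    cov: np.ndarray
    converged: bool
    loglik: float
    n_iter: int


def logistic_fit(design: np.ndarray, outcome: np.ndarray,
                 weights: np.ndarray | None = None,
                 tol: float = 1e-8, max_iter: int = 50,
                 separation_bound: float = 15.0) -> LogisticFit:
    """Maximum-likelihood logistic regression by iteratively reweighted
    least squares.

    Converges when the largest coefficient change drops below ``tol``.
    A coefficient wandering beyond ``separation_bound`` in absolute
    value marks (quasi-)separation and the fit is flagged non-converged
    rather than silently returned.  ``weights`` are per-row frequency
    weights (used by the haplotype GLM expansion); the covariance is the
    inverse observed information of the weighted likelihood.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design / outcome shape mismatch")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if not (0 < y.mean() < 1):
        raise ValueError("outcome must contain both classes")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(X.shape[1])
    converged = False
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        wls = w * mu * (1 - mu)
        # guard against exactly saturated rows
        wls = np.maximum(wls, 1e-12)
        info = X.T @ (wls[:, None] * X)
        score = X.T @ (w * (y - mu))
        delta = np.linalg.solve(info, score)
        beta = beta + delta
        if np.abs(beta).max() > separation_bound:
            converged = False
            break
        if np.abs(delta).max() < tol:
            converged = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    loglik = float(np.sum(w * (y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300))))
    wls = np.maximum(w * mu * (1 - mu), 1e-12)
    cov = np.linalg.inv(X.T @ (wls[:, None] * X))
    return LogisticFit(beta, cov, converged, loglik, it)


def genetic_term(dose: np.ndarray, model: str) -> np.ndarray:
    """Numeric predictor for a genetic model from a 0/1/2 dose vector."""
    if model == "additive":
        return dose.astype(float)
    if model == "dominant":
        return (dose >= 1).astype(float)
    if model == "recessive":
        return (dose == 2).astype(float)
    raise ValueError(f"unknown genetic model {model!r}")


def adjusted_or(cohort: CohortTable, locus: LocusSpec | str, model: str,
                covariates: Sequence[str]) -> AssocResult:
    """Covariate-adjusted OR from logistic regression.

    Subjects with a missing dose or a missing covariate at this locus
    are dropped (available-case).  The OR, Woolf-type CI and Wald p come
    from the genetic coefficient.
    """
    if isinstance(locus, str):
        locus = cohort.locus(locus)
    dose = cohort.table[locus.name].to_numpy(dtype=int)
    cov_mat = cohort.table[list(covariates)].to_numpy(dtype=float) if covariates else \
        np.empty((len(cohort), 0))
    keep = (dose != MISSING) & ~np.isnan(cov_mat).any(axis=1)
    term = genetic_term(dose[keep], model)
    for j, name in enumerate(covariates):
        if np.ptp(cov_mat[keep, j]) == 0:
            raise ValueError(f"covariate {name!r} is constant")
    X = np.column_stack([np.ones(keep.sum()), term, cov_mat[keep]])
    fit = logistic_fit(X, cohort.status[keep])
    b, se = fit.coef[1], float(np.sqrt(fit.cov[1, 1]))
    return AssocResult(
        locus, model,
        or_adjusted=float(np.exp(b)),
        ci_adjusted=(float(np.exp(b - Z_95 * se)), float(np.exp(b + Z_95 * se))),
        p_adjusted=float(2 * stats.norm.sf(abs(b) / se)),
        converged=fit.converged,
    )


def locus_association(cohort: CohortTable, locus: LocusSpec | str, model: str,
                      covariates: Sequence[str] = ()) -> AssocResult:
    """Crude and (optionally) adjusted OR for one locus and model."""
    from .data import count_genotypes

    if isinstance(locus, str):
        locus = cohort.locus(locus)
    res = crude_or(count_genotypes(cohort, locus), model)
    if covariates:
        adj = adjusted_or(cohort, locus, model, covariates)
        res.or_adjusted = adj.or_adjusted
        res.ci_adjusted = adj.ci_adjusted
        res.p_adjusted = adj.p_adjusted
        res.converged = adj.converged
    return res


# ---------------------------------------------------------------------------
# power and baseline comparison
# ---------------------------------------------------------------------------

def two_proportion_power(p1: float, p2: float, n1: int, n2: int,
                         alpha: float = 0.05) -> float:
    """Power of the two-sided two-proportion z-test, normal approximation.

    Pooled SE under the null, unpooled SE under the alternative:
    power = Phi((|p1-p2| - z_{1-a/2} * SE0) / SE1).
    """
    for p in (p1, p2):
        if not 0 < p < 1:
            raise ValueError("proportions must lie strictly in (0, 1)")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    z = stats.norm.ppf(1 - alpha / 2)
    pbar = (p1 * n1 + p2 * n2) / (n1 + n2)
    se0 = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    se1 = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    return float(stats.norm.cdf((abs(p1 - p2) - z * se0) / se1))


def compare_baseline(cohort: CohortTable, variable: str,
                     equal_var: bool = True) -> tuple[float, float]:
    """Case-control comparison of one baseline characteristic.

    Continuous variables (age) use the unpaired two-sample t-test;
    binary variables use the Pearson chi-square on the 2x2 table.
    Returns (statistic, p).
    """
    values = cohort.table[variable].to_numpy(dtype=float)
    status = cohort.status
    keep = ~np.isnan(values)
    values, status = values[keep], status[keep]
    if np.ptp(values) == 0:
        raise ValueError(f"variable {variable!r} is constant")
    uniq = np.unique(values)
    if set(uniq) <= {0.0, 1.0}:
        table = np.array([
            [(values[status == g] == 1).sum(), (values[status == g] == 0).sum()]
            for g in (1, 0)
        ], dtype=float)
        chi2, _, p = _pearson(table)
        return chi2, p
    t, p = stats.ttest_ind(values[status == 1], values[status == 0], equal_var=equal_var)
    return float(t), float(p)
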