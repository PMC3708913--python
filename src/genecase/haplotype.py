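"""EM haplotype inference, permutation score tests, and haplotype GLM.

Unphased multilocus genotypes leave the diplotype ambiguous whenever two
or more loci are heterozygous.  Haplotype frequencies are estimated by
the standard EM algorithm over the 2^L candidate haplotypes (suitable
for the small within-gene panels used here): the E-step distributes each
subject over its genotype-compatible haplotype pairs with probability
proportional to f_a * f_b (doubled for heterozygous pairs), the M-step
recounts expected haplotype copies.

Association uses two complementary tools.  The score test contrasts the
posterior-expected haplotype dose with residuals from a covariates-only
logistic null model, with significance from permuting the trait (and
covariates) jointly.  The haplotype GLM estimates per-copy odds ratios
by expectation substitution: each subject is expanded into its
compatible diplotypes weighted by the EM posterior, an
additive-in-haplotype-dose logistic model is fitted by weighted IRLS,
and a cluster sandwich variance accounts for the weight reuse across a
subject's pseudo-observations.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
from scipy import stats

from .data import MISSING, CohortTable, LocusSpec
from .single_locus import Z_95, logistic_fit

_EM_TOL = 1e-8
_EM_MAX_ITER = 500
_PRUNE_TOL = 1e-12


@dataclasses.dataclass
class EMResult:
    """Haplotype frequencies and per-subject phase posteriors."""

    loci: tuple[LocusSpec, ...]
    haplotypes: tuple[str, ...]          # allele strings, e.g. "C-A-A"
    freqs: np.ndarray                    # aligned with `haplotypes`
    loglik: float
    loglik_history: np.ndarray
    n_iter: int
    subject_index: np.ndarray            # rows of the cohort with complete genotypes
    # per included subject: arrays of (hap_a, hap_b, posterior)
    pair_a: list[np.ndarray] = dataclasses.field(repr=False, default_factory=list)
    pair_b: list[np.ndarray] = dataclasses.field(repr=False, default_factory=list)
    posterior: list[np.ndarray] = dataclasses.field(repr=False, default_factory=list)

    def freq_of(self, hap: str) -> float:
        return float(self.freqs[self.haplotypes.index(hap)])

    def nonrare(self, threshold: float = _PRUNE_TOL) -> dict[str, float]:
        return {h: float(f) for h, f in zip(self.haplotypes, self.freqs) if f >= threshold}

    def expected_dose(self) -> np.ndarray:
        """(n_subjects x n_haplotypes) posterior-expected haplotype dose."""
        H = len(self.haplotypes)
        out = np.zeros((len(self.subject_index), H))
        for i, (a, b, w) in enumerate(zip(self.pair_a, self.pair_b, self.posterior)):
            np.add.at(out[i], a, w)
            np.add.at(out[i], b, w)
        return out


def _hap_labels(loci: Sequence[LocusSpec]) -> tuple[list[tuple[int, ...]], list[str]]:
    """All 2^L haplotypes as minor-allele indicator tuples and allele strings."""
    combos = list(itertools.product((0, 1), repeat=len(loci)))
    labels = [
        "-".join(l.minor_allele if bit else l.major_allele for bit, l in zip(c, loci))
        for c in combos
    ]
    return combos, labels


def _compatible_pairs(genotype: tuple[int, ...], hap_index: dict[tuple[int, ...], int]
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Unordered haplotype pairs (a <= b) consistent with a dose vector."""
    per_locus = []
    for g in genotype:
        if g == 0:
            per_locus.append([(0, 0)])
        elif g == 2:
            per_locus.append([(1, 1)])
        else:
            per_locus.append([(0, 1), (1, 0)])
    pairs = set()
    for combo in itertools.product(*per_locus):
        a = tuple(c[0] for c in combo)
        b = tuple(c[1] for c in combo)
        ia, ib = hap_index[a], hap_index[b]
        pairs.add((min(ia, ib), max(ia, ib)))
    pairs = sorted(pairs)
    return (np.array([p[0] for p in pairs], dtype=int),
            np.array([p[1] for p in pairs], dtype=int))


def em_haplotypes(cohort: CohortTable, loci: Sequence[str], group: str = "pooled") -> EMResult:
    """EM haplotype frequency estimation from unphased genotypes.

    ``group`` restricts to ``"cases"`` / ``"controls"`` or uses the
    pooled sample.  Subjects missing any genotype at the loci are
    excluded.  Iterates to a log-likelihood change below 1e-8 (at most
    500 iterations) from a uniform start; the log-likelihood is checked
    to be non-decreasing on every run.
    """
    locus_specs = tuple(cohort.locus(n) for n in loci)
    if len(locus_specs) > 10:
        raise ValueError("EM enumeration limited to 10 loci (2^L haplotypes)")
    doses = cohort.doses(loci)
    mask = (doses != MISSING).all(axis=1)
    if group == "cases":
        mask &= cohort.status == 1
    elif group == "controls":
        mask &= cohort.status == 0
    elif group != "pooled":
        raise ValueError(f"unknown group {group!r}")
    subject_index = np.flatnonzero(mask)
    if len(subject_index) == 0:
        raise ValueError("no subjects with complete genotypes at the requested loci")
    doses = doses[mask]

    combos, labels = _hap_labels(locus_specs)
    hap_index = {c: i for i, c in enumerate(combos)}
    H = len(combos)

    geno_tuples = [tuple(row) for row in doses]
    uniq = sorted(set(geno_tuples))
    geno_id = {g: i for i, g in enumerate(uniq)}
    counts = np.zeros(len(uniq))
    for g in geno_tuples:
        counts[geno_id[g]] += 1

    # flatten (genotype, compatible pair) combinations for vectorised EM
    flat_a, flat_b, flat_gid = [], [], []
    pairs_by_gid = []
    for g in uniq:
        a, b = _compatible_pairs(g, hap_index)
        pairs_by_gid.append((a, b))
        flat_a.append(a)
        flat_b.append(b)
        flat_gid.append(np.full(len(a), geno_id[g]))
    flat_a = np.concatenate(flat_a)
    flat_b = np.concatenate(flat_b)
    flat_gid = np.concatenate(flat_gid)
    mult = np.where(flat_a == flat_b, 1.0, 2.0)

    freqs = np.full(H, 1.0 / H)
    history = []
    n = counts.sum()
    for it in range(1, _EM_MAX_ITER + 1):
        w = mult * freqs[flat_a] * freqs[flat_b]
        denom = np.bincount(flat_gid, weights=w, minlength=len(uniq))
        loglik = float(np.sum(counts * np.log(denom + 1e-300)))
        if history and loglik < history[-1] - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        converged = bool(history) and loglik - history[-1] < _EM_TOL
        history.append(loglik)
        if converged:
            break
        post = w / denom[flat_gid]
        weight = post * counts[flat_gid]
        hap_counts = (np.bincount(flat_a, weights=weight, minlength=H)
                      + np.bincount(flat_b, weights=weight, minlength=H))
        freqs = hap_counts / (2.0 * n)

    freqs = np.where(freqs < _PRUNE_TOL, 0.0, freqs)
    freqs = freqs / freqs.sum()

    pair_a, pair_b, posterior = [], [], []
    for g in geno_tuples:
        a, b = pairs_by_gid[geno_id[g]]
        w = np.where(a == b, 1.0, 2.0) * freqs[a] * freqs[b]
        total = w.sum()
        if total <= 0:  # pruned into impossibility; fall back to uniform
            w = np.ones_like(w)
            total = w.sum()
        pair_a.append(a)
        pair_b.append(b)
        posterior.append(w / total)

    return EMResult(locus_specs, tuple(labels), freqs, history[-1],
                    np.array(history), it, subject_index, pair_a, pair_b, posterior)


# ---------------------------------------------------------------------------
# score test with permutation p-values
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HapScoreResult:
    haplotypes: tuple[str, ...]          # haplotypes with testable variance
    z: np.ndarray
    p_sim: np.ndarray
    global_stat: float
    global_df: int
    global_p_sim: float
    n_permutations: int
    excluded: tuple[str, ...]            # too rare for a stable score variance
    em: EMResult


def haplotype_score_test(cohort: CohortTable, loci: Sequence[str],
                         covariates: Sequence[str] = (), n_perm: int = 10_000,
                         seed: int = 0, min_freq: float = 1e-4) -> HapScoreResult:
    """Haplotype score statistics with permutation ("simulated") p-values.

    For haplotype h the score is u_h = sum_i (y_i - yhat_i) E[d_ih],
    with yhat from the covariates-only logistic null model and E[d_ih]
    the EM posterior-expected dose.  The variance is the efficient score
    variance (information of the dose adjusted for the null design).
    p_sim permutes the trait and covariates jointly n_perm times and
    applies the add-one estimator (1 + #{|z*| >= |z|}) / (n_perm + 1);
    the global statistic is the quadratic form of the score vector.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    em = em_haplotypes(cohort, loci, group="pooled")
    X = em.expected_dose()
    y = cohort.status[em.subject_index].astype(float)
    n = len(y)

    cov_mat = (cohort.table[list(covariates)].to_numpy(dtype=float)[em.subject_index]
               if covariates else np.empty((n, 0)))
    keep = ~np.isnan(cov_mat).any(axis=1)
    X, y, cov_mat = X[keep], y[keep], cov_mat[keep]
    G = np.column_stack([np.ones(len(y)), cov_mat])
    fit = logistic_fit(G, y)
    mu = 1.0 / (1.0 + np.exp(-(G @ fit.coef)))
    r = y - mu
    w = mu * (1 - mu)

    testable = em.freqs >= min_freq
    Xt = X[:, testable]
    XtW = Xt * w[:, None]
    GtWG = G.T @ (G * w[:, None])
    V = Xt.T @ XtW - (XtW.T @ G) @ np.linalg.solve(GtWG, G.T @ XtW)
    var = np.diag(V).copy()
    ok = var > 1e-8
    u = Xt.T @ r
    z = u[ok] / np.sqrt(var[ok])

    # global quadratic form on the testable scores (V is rank-deficient by 1
    # because doses sum to 2; use the pseudo-inverse spectrum)
    evals, evecs = np.linalg.eigh(V)
    rank_keep = evals > max(evals.max(), 1.0) * 1e-10
    P = evecs[:, rank_keep] / np.sqrt(evals[rank_keep])
    global_stat = float(((P.T @ u) ** 2).sum())
    global_df = int(rank_keep.sum())

    rng = np.random.default_rng(seed)
    n_obs = len(y)
    z_exceed = np.zeros(ok.sum())
    global_exceed = 0
    chunk = max(1, min(n_perm, int(4e7 // max(n_obs, 1))))
    done = 0
    abs_z = np.abs(z)
    while done < n_perm:
        b = min(chunk, n_perm - done)
        R = np.empty((n_obs, b))
        for j in range(b):
            R[:, j] = r[rng.permutation(n_obs)]
        U = Xt.T @ R
        Zs = np.abs(U[ok] / np.sqrt(var[ok])[:, None])
        z_exceed += (Zs >= abs_z[:, None]).sum(axis=1)
        global_exceed += int((((P.T @ U) ** 2).sum(axis=0) >= global_stat).sum())
        done += b

    p_sim = (1.0 + z_exceed) / (n_perm + 1.0)
    names = tuple(np.array(em.haplotypes)[testable][ok])
    excl = [h for h, f in zip(em.haplotypes, em.freqs) if f > _PRUNE_TOL and f < min_freq]
    excl += list(np.array(em.haplotypes)[testable][~ok])
    return HapScoreResult(names, z, p_sim, global_stat, global_df,
                          (1.0 + global_exceed) / (n_perm + 1.0), n_perm,
                          tuple(excl), em)


# ---------------------------------------------------------------------------
# haplotype GLM (expectation substitution)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class HapGLMResult:
    reference: str
    haplotypes: tuple[str, ...]          # non-reference modelled haplotypes
    odds_ratio: np.ndarray
    ci: np.ndarray                       # (H x 2)
    p: np.ndarray
    pooled_rare: tuple[str, ...]
    converged: bool
    em: EMResult

    def or_of(self, hap: str) -> tuple[float, tuple[float, float], float]:
        i = self.haplotypes.index(hap)
        return float(self.odds_ratio[i]), (float(self.ci[i, 0]), float(self.ci[i, 1])), float(self.p[i])


def haplotype_glm(cohort: CohortTable, loci: Sequence[str],
                  covariates: Sequence[str] = (), reference: str | None = None,
                  min_freq: float = 0.01, joint: bool = True,
                  max_outer: int = 50) -> HapGLMResult:
    """Per-copy haplotype odds ratios from a weighted logistic GLM.

    Each subject is expanded into its genotype-compatible diplotypes;
    haplotype doses enter additively with the most frequent haplotype as
    reference unless overridden, and haplotypes below ``min_freq`` are
    pooled into a single "rare" column.  By default (``joint=True``) the
    phase posteriors and haplotype frequencies are re-estimated jointly
    with the risk model: the E-step weights each diplotype by
    f_a * f_b * P(y | diplotype, beta), which is essential when common
    haplotypes leave multi-heterozygotes highly ambiguous (one-pass
    expectation substitution attenuates the effect estimates badly in
    that regime).  ``joint=False`` gives the one-pass variant with
    pooled-EM posteriors.  Standard errors use the cluster (by subject)
    sandwich estimator.
    """
    em = em_haplotypes(cohort, loci, group="pooled")
    freqs = em.freqs.copy()
    if reference is None:
        reference = em.haplotypes[int(np.argmax(freqs))]
    ref_idx = em.haplotypes.index(reference)
    if freqs[ref_idx] < min_freq:
        raise ValueError(f"reference haplotype {reference} has frequency below {min_freq}")
    H = len(em.haplotypes)
    common = [i for i in range(H) if freqs[i] >= min_freq and i != ref_idx]
    rare = [i for i in range(H) if _PRUNE_TOL < freqs[i] < min_freq]
    pooled_rare = tuple(em.haplotypes[i] for i in rare)

    y_full = cohort.status[em.subject_index].astype(float)
    cov_mat = (cohort.table[list(covariates)].to_numpy(dtype=float)[em.subject_index]
               if covariates else np.empty((len(y_full), 0)))
    keep = np.flatnonzero(~np.isnan(cov_mat).any(axis=1))

    # flatten the (subject, compatible diplotype) expansion
    subj = np.concatenate([np.full(len(em.pair_a[i]), k) for k, i in enumerate(keep)])
    A = np.concatenate([em.pair_a[i] for i in keep])
    B = np.concatenate([em.pair_b[i] for i in keep])
    w = np.concatenate([em.posterior[i] for i in keep])
    mult = np.where(A == B, 1.0, 2.0)
    n_subj = len(keep)
    y = y_full[keep][subj]

    full_dose = np.zeros((len(A), H))
    full_dose[np.arange(len(A)), A] += 1.0
    np.add.at(full_dose, (np.arange(len(A)), B), 1.0)
    dose = full_dose[:, common]
    if rare:
        dose = np.column_stack([dose, full_dose[:, rare].sum(axis=1)])

    X = np.column_stack([np.ones(len(subj)), dose, cov_mat[keep][subj]])
    # drop zero-variance columns (e.g. rare column never realised)
    keep_cols = np.array([np.ptp(X[:, j]) > 0 or j == 0 for j in range(X.shape[1])])
    Xk = X[:, keep_cols]

    beta = None
    for _ in range(max_outer):
        fit = logistic_fit(Xk, y, weights=w, separation_bound=30.0)
        if not joint or (beta is not None and np.abs(fit.coef - beta).max() < 1e-7):
            beta = fit.coef
            break
        beta = fit.coef
        mu = 1.0 / (1.0 + np.exp(-(Xk @ beta)))
        lik = mult * freqs[A] * freqs[B] * np.where(y == 1, mu, 1 - mu)
        denom = np.bincount(subj, weights=lik, minlength=n_subj)
        w = lik / denom[subj]
        counts = (np.bincount(A, weights=w, minlength=H)
                  + np.bincount(B, weights=w, minlength=H))
        freqs = counts / (2.0 * n_subj)

    mu = 1.0 / (1.0 + np.exp(-(Xk @ fit.coef)))
    score_rows = Xk * (w * (y - mu))[:, None]
    per_subj = np.zeros((n_subj, int(keep_cols.sum())))
    np.add.at(per_subj, subj, score_rows)
    bread = fit.cov
    meat = per_subj.T @ per_subj
    sandwich = bread @ meat @ bread
    se = np.sqrt(np.diag(sandwich))

    # map back to the haplotype columns
    hap_names = [em.haplotypes[i] for i in common] + (["rare"] if rare else [])
    full_idx = np.flatnonzero(keep_cols)
    ors, cis, ps = [], [], []
    kept_names = []
    for j, name in enumerate(hap_names, start=1):
        if j not in full_idx:
            continue
        pos = int(np.where(full_idx == j)[0][0])
        b_, s_ = fit.coef[pos], se[pos]
        kept_names.append(name)
        ors.append(np.exp(b_))
        cis.append((np.exp(b_ - Z_95 * s_), np.exp(b_ + Z_95 * s_)))
        ps.append(2 * stats.norm.sf(abs(b_) / s_))
    return HapGLMResult(reference, tuple(kept_names), np.array(ors), np.array(cis),
                        np.array(ps), pooled_rare, fit.converged, em)
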