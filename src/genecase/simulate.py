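"""Synthetic two-gene case-control cohorts.

Emulates the statistical structure of the lung-cancer study population:
two unlinked genes (three *RAGE* SNPs, two *APE1* SNPs), haplotypes
drawn under Hardy-Weinberg within gene and linkage equilibrium between
genes, disease risk from a logistic model with per-copy haplotype
effects and an optional planted two-locus interaction, and binary
covariates drawn retrospectively with status-specific prevalences.
Case/control totals are fixed exactly by rejection sampling.  The true
diplotypes are kept in a side channel so phase-inference accuracy can be
validated; the analysis pipeline never reads it.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from . import datasets
from .data import COVARIATE_COLUMNS, CohortTable, LocusSpec


@dataclasses.dataclass
class SimConfig:
    """Generating parameters of a synthetic cohort.

    ``hap_log_or`` gives per-copy log odds ratios keyed by haplotype
    string (e.g. ``"C-A-A"``); ``interaction_log_or`` applies to the
    indicator of carrying a minor allele at both interaction loci.
    Defaults reproduce the study's control haplotype frequencies,
    covariate prevalences, and sample sizes, with all effects zero.
    """

    n_cases: int = datasets.N_CASES
    n_controls: int = datasets.N_CONTROLS
    rage_hap_freqs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: datasets.control_hap_freqs("RAGE"))
    ape1_hap_freqs: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: datasets.control_hap_freqs("APE1"))
    covariate_prevalences: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(datasets.COVARIATE_PREVALENCES))
    age_mean: tuple[float, float] = datasets.AGE_MEAN
    age_sd: tuple[float, float] = datasets.AGE_SD
    beta0: float = -2.0
    hap_log_or: Mapping[str, float] = dataclasses.field(default_factory=dict)
    interaction_log_or: float = 0.0
    interaction_loci: tuple[str, str] = ("rs2070600", "rs1130409")
    panel: tuple[LocusSpec, ...] = datasets.LUNG_PANEL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        for name, freqs in (("RAGE", self.rage_hap_freqs), ("APE1", self.ape1_hap_freqs)):
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} haplotype frequencies sum to {total}, not 1")
            if any(f < 0 for f in freqs.values()):
                raise ValueError(f"{name} haplotype frequencies must be nonnegative")
        unknown = set(self.hap_log_or) - set(self.rage_hap_freqs) - set(self.ape1_hap_freqs)
        if unknown:
            raise ValueError(f"hap_log_or names unknown haplotypes: {sorted(unknown)}")

    def null(self) -> "SimConfig":
        """Copy with every genetic effect removed."""
        return dataclasses.replace(self, hap_log_or={}, interaction_log_or=0.0)


def _hap_dose_matrix(haps: list[str], loci: list[LocusSpec]) -> np.ndarray:
    """(n_haplotypes x n_loci) minor-allele indicator per haplotype."""
    out = np.zeros((len(haps), len(loci)), dtype=int)
    for i, hap in enumerate(haps):
        alleles = hap.split("-")
        if len(alleles) != len(loci):
            raise ValueError(f"haplotype {hap!r} does not match {len(loci)} loci")
        for j, (allele, locus) in enumerate(zip(alleles, loci)):
            if allele == locus.minor_allele:
                out[i, j] = 1
            elif allele != locus.major_allele:
                raise ValueError(f"haplotype {hap!r}: allele {allele!r} invalid at {locus.name}")
    return out


def simulate_cohort(config: SimConfig, max_batches: int = 500) -> CohortTable:
    """Draw a cohort with exactly the configured case/control totals.

    Candidate subjects are generated in batches; disease status is a
    Bernoulli draw from the logistic risk model and subjects are kept
    until both quotas are filled (rejection sampling, so the genotype
    distributions within each status group are exact conditionals).
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    gene_blocks = []
    for gene, freqs in (("RAGE", config.rage_hap_freqs), ("APE1", config.ape1_hap_freqs)):
        loci = [l for l in panel if l.gene == gene]
        haps = list(freqs.keys())
        gene_blocks.append((
            haps,
            np.array([freqs[h] for h in haps]),
            _hap_dose_matrix(haps, loci),
            np.array([config.hap_log_or.get(h, 0.0) for h in haps]),
            loci,
        ))
    locus_order = [l.name for block in gene_blocks for l in block[4]]
    ix_a = locus_order.index(config.interaction_loci[0])
    ix_b = locus_order.index(config.interaction_loci[1])

    need = {1: config.n_cases, 0: config.n_controls}
    kept_doses: dict[int, list[np.ndarray]] = {0: [], 1: []}
    kept_phase: dict[int, list[np.ndarray]] = {0: [], 1: []}
    batch = 4 * (config.n_cases + config.n_controls)
    for _ in range(max_batches):
        if need[0] <= 0 and need[1] <= 0:
            break
        logit = np.full(batch, config.beta0)
        dose_parts, phase_parts = [], []
        for haps, probs, dose_mat, log_or, _loci in gene_blocks:
            pair = rng.choice(len(haps), size=(batch, 2), p=probs)
            dose_parts.append(dose_mat[pair[:, 0]] + dose_mat[pair[:, 1]])
            phase_parts.append(pair)
            logit += log_or[pair[:, 0]] + log_or[pair[:, 1]]
        doses = np.hstack(dose_parts)
        if config.interaction_log_or != 0.0:
            logit += config.interaction_log_or * ((doses[:, ix_a] >= 1) & (doses[:, ix_b] >= 1))
        p = 1.0 / (1.0 + np.exp(-logit))
        status = rng.random(batch) < p
        for grp in (1, 0):
            if need[grp] <= 0:
                continue
            idx = np.flatnonzero(status == grp)[: need[grp]]
            kept_doses[grp].append(doses[idx])
            kept_phase[grp].append(np.hstack([pp[idx] for pp in phase_parts]))
            need[grp] -= len(idx)
    if need[0] > 0 or need[1] > 0:
        raise RuntimeError(
            f"rejection sampling exhausted after {max_batches} batches "
            f"(still need {need[1]} cases, {need[0]} controls); "
            "check beta0 / effect sizes")

    status = np.concatenate([np.ones(config.n_cases, dtype=int),
                             np.zeros(config.n_controls, dtype=int)])
    doses = np.vstack([np.vstack(kept_doses[1]), np.vstack(kept_doses[0])])
    phase_idx = np.vstack([np.vstack(kept_phase[1]), np.vstack(kept_phase[0])])
    n = len(status)

    cols: dict = {"id": [f"S{i:05d}" for i in range(n)], "status": status}
    for cov in COVARIATE_COLUMNS:
        if cov == "age":
            mean = np.where(status == 1, config.age_mean[1], config.age_mean[0])
            sd = np.where(status == 1, config.age_sd[1], config.age_sd[0])
            cols[cov] = np.round(mean + sd * rng.standard_normal(n), 1)
        else:
            prev_ctl, prev_case = config.covariate_prevalences[cov]
            prev = np.where(status == 1, prev_case, prev_ctl)
            cols[cov] = (rng.random(n) < prev).astype(float)
    # doses column-ordered by gene blocks == panel order for the default panel
    for j, name in enumerate(locus_order):
        cols[name] = doses[:, j]
    table = pd.DataFrame(cols)[["id", "status", *COVARIATE_COLUMNS, *locus_order]]

    rage_haps = gene_blocks[0][0]
    ape1_haps = gene_blocks[1][0]
    phase = pd.DataFrame({
        "rage_hap_a": [rage_haps[i] for i in phase_idx[:, 0]],
        "rage_hap_b": [rage_haps[i] for i in phase_idx[:, 1]],
        "ape1_hap_a": [ape1_haps[i] for i in phase_idx[:, 2]],
        "ape1_hap_b": [ape1_haps[i] for i in phase_idx[:, 3]],
    })
    ordered_panel = tuple(l for block in gene_blocks for l in block[4])
    return CohortTable(table, ordered_panel, phase=phase)


def simulate_null(config: SimConfig, max_batches: int = 500) -> CohortTable:
    """Cohort with status independent of genotype (all effects zero)."""
    return simulate_cohort(config.null(), max_batches=max_batches)
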