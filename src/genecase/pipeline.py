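"""End-to-end analysis pipeline: simulate/load -> baseline -> single-locus
-> per-gene haplotypes -> MDR -> power, with one master seed.

Every stochastic stage receives a child seed derived deterministically
from the master seed, so a run is reproducible byte-for-byte from its
config.  Output tables mirror the standard reporting layout of a
candidate-gene case-control study: baseline characteristics, per-locus
genotype/allele statistics with ORs under three genetic models, per-gene
haplotype frequencies with simulated p-values and GLM ORs, and the MDR
model summary.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .data import CohortTable, count_genotypes, allele_frequency, read_cohort, write_cohort
from .haplotype import em_haplotypes, haplotype_glm, haplotype_score_test
from .mdr import mdr_permutation_test, mdr_search
from .simulate import SimConfig, simulate_cohort
from .single_locus import (GENETIC_MODELS, allele_chi2, compare_baseline,
                           genotype_chi2, hwe_test, locus_association,
                           two_proportion_power)

log = logging.getLogger("genecase")

DEFAULT_COVARIATES = ("age", "sex", "smoking", "drinking")
BINARY_BASELINE = ("sex", "smoking", "drinking", "copd", "family_history")


@dataclasses.dataclass
class RunConfig:
    """Parameters of one full analysis run."""

    input_path: str | None = None        # native TSV; None -> simulate
    input_format: str = "tsv"
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    models: tuple[str, ...] = GENETIC_MODELS
    genes: Mapping[str, tuple[str, ...]] = dataclasses.field(
        default_factory=lambda: {"RAGE": datasets.RAGE_LOCI, "APE1": datasets.APE1_LOCI})
    n_perm_haplo: int = 1000
    min_hap_freq: float = 0.01
    mdr_k: tuple[int, int] = (1, 5)
    mdr_folds: int = 10
    n_perm_mdr: int = 200
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "genecase_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        cfg = cls(sim=sim, **{k: v for k, v in raw.items()})
        return cfg


def child_seeds(master: int, n: int) -> list[int]:
    """Deterministic per-stage seeds (< 2^31) derived from the master seed."""
    seq = np.random.SeedSequence(master)
    return [int(s) % (2 ** 31) for s in seq.generate_state(n)]


def _fmt(x, nd=4) -> str:
    if x is None:
        return "NA"
    return f"{x:.{nd}f}"


def baseline_table(cohort: CohortTable) -> pd.DataFrame:
    rows = []
    tbl = cohort.table
    status = cohort.status
    age = tbl["age"].to_numpy(dtype=float)
    if np.isfinite(age).any():
        stat, p = compare_baseline(cohort, "age")
        rows.append({"characteristic": "age",
                     "cases": f"{np.nanmean(age[status == 1]):.2f} ({np.nanstd(age[status == 1], ddof=1):.2f})",
                     "controls": f"{np.nanmean(age[status == 0]):.2f} ({np.nanstd(age[status == 0], ddof=1):.2f})",
                     "statistic": round(stat, 4), "p": round(p, 4)})
    for var in BINARY_BASELINE:
        v = tbl[var].to_numpy(dtype=float)
        if not np.isfinite(v).any():
            continue
        stat, p = compare_baseline(cohort, var)
        rows.append({"characteristic": var,
                     "cases": f"{100 * np.nanmean(v[status == 1]):.2f}%",
                     "controls": f"{100 * np.nanmean(v[status == 0]):.2f}%",
                     "statistic": round(stat, 4), "p": round(p, 4)})
    return pd.DataFrame(rows)


def single_locus_table(cohort: CohortTable, models: Sequence[str],
                       covariates: Sequence[str]) -> pd.DataFrame:
    rows = []
    adjustable = [c for c in covariates
                  if np.isfinite(cohort.table[c].to_numpy(dtype=float)).all()]
    for locus in cohort.panel:
        counts = count_genotypes(cohort, locus)
        g_chi2, _, g_p = genotype_chi2(counts)
        a_chi2, _, a_p = allele_chi2(counts)
        hwe_ca = hwe_test(counts.case_counts, locus, "cases")
        hwe_co = hwe_test(counts.control_counts, locus, "controls")
        for model in models:
            res = locus_association(cohort, locus, model, adjustable)
            rows.append({
                "locus": locus.name, "gene": locus.gene, "model": model,
                "case_counts": "/".join(map(str, counts.case_counts)),
                "control_counts": "/".join(map(str, counts.control_counts)),
                "maf_cases": round(allele_frequency(counts.case_counts), 4),
                "maf_controls": round(allele_frequency(counts.control_counts), 4),
                "p_genotype": round(g_p, 4), "p_allele": round(a_p, 4),
                "hwe_p_cases": round(hwe_ca.p, 4), "hwe_p_controls": round(hwe_co.p, 4),
                "or_crude": _fmt(res.or_crude),
                "ci_crude": f"{res.ci_crude[0]:.4f}-{res.ci_crude[1]:.4f}",
                "p_crude": _fmt(res.p_crude),
                "or_adjusted": _fmt(res.or_adjusted),
                "ci_adjusted": ("NA" if res.ci_adjusted is None else
                                f"{res.ci_adjusted[0]:.4f}-{res.ci_adjusted[1]:.4f}"),
                "p_adjusted": _fmt(res.p_adjusted),
            })
    return pd.DataFrame(rows)


def haplotype_table(cohort: CohortTable, genes: Mapping[str, Sequence[str]],
                    covariates: Sequence[str], n_perm: int, min_freq: float,
                    seed: int) -> pd.DataFrame:
    rows = []
    adjustable = [c for c in covariates
                  if np.isfinite(cohort.table[c].to_numpy(dtype=float)).all()]
    seeds = child_seeds(seed, len(genes))
    for (gene, loci), s in zip(genes.items(), seeds):
        em_cases = em_haplotypes(cohort, loci, group="cases").nonrare()
        em_controls = em_haplotypes(cohort, loci, group="controls").nonrare()
        score = haplotype_score_test(cohort, loci, adjustable, n_perm=max(n_perm, 100), seed=s)
        crude = haplotype_glm(cohort, loci, covariates=(), min_freq=min_freq)
        adj = (haplotype_glm(cohort, loci, covariates=adjustable, min_freq=min_freq)
               if adjustable else None)
        p_by_hap = dict(zip(score.haplotypes, score.p_sim))
        all_haps = sorted(set(em_cases) | set(em_controls),
                          key=lambda h: -(em_cases.get(h, 0) + em_controls.get(h, 0)))
        for hap in all_haps:
            row = {"gene": gene, "haplotype": hap,
                   "freq_cases": round(em_cases.get(hap, 0.0), 4),
                   "freq_controls": round(em_controls.get(hap, 0.0), 4),
                   "p_sim": _fmt(p_by_hap.get(hap))}
            if hap == crude.reference:
                row.update({"or_crude": "reference", "ci_crude": "", "or_adjusted": "reference",
                            "ci_adjusted": ""})
            else:
                for tag, res in (("crude", crude), ("adjusted", adj)):
                    if res is not None and hap in res.haplotypes:
                        o, ci, _ = res.or_of(hap)
                        row[f"or_{tag}"] = f"{o:.4f}"
                        row[f"ci_{tag}"] = f"{ci[0]:.4f}-{ci[1]:.4f}"
                    else:
                        row[f"or_{tag}"] = "NA"
                        row[f"ci_{tag}"] = "NA"
            rows.append(row)
        rows.append({"gene": gene, "haplotype": "(global score)",
                     "freq_cases": "", "freq_controls": "",
                     "p_sim": _fmt(score.global_p_sim),
                     "or_crude": "", "ci_crude": "", "or_adjusted": "", "ci_adjusted": ""})
    return pd.DataFrame(rows)


def mdr_table(cohort: CohortTable, k_range: tuple[int, int], n_folds: int,
              n_perm: int, seed: int) -> pd.DataFrame:
    seeds = child_seeds(seed, 2)
    models, best = mdr_search(cohort, k_range[0], k_range[1], n_folds=n_folds, seed=seeds[0])
    perm_seeds = child_seeds(seeds[1], len(models))
    rows = []
    for m, s in zip(models, perm_seeds):
        p = mdr_permutation_test(cohort, m, n_perm=max(n_perm, 100),
                                 n_folds=n_folds, seed=s)
        rows.append({"best_combination": ", ".join(m.loci),
                     "testing_ba": round(m.testing_ba, 4),
                     "training_ba": round(m.training_ba, 4),
                     "cvc": f"{m.cvc}/{m.n_folds}",
                     "p_perm": round(p, 4),
                     "overall_best": "*" if m.loci == best.loci else ""})
    return pd.DataFrame(rows)


def power_table(cohort: CohortTable, alpha: float) -> pd.DataFrame:
    rows = []
    n1, n2 = 2 * cohort.n_cases, 2 * cohort.n_controls
    for locus in cohort.panel:
        counts = count_genotypes(cohort, locus)
        p1 = allele_frequency(counts.case_counts)
        p2 = allele_frequency(counts.control_counts)
        try:
            pw = two_proportion_power(p1, p2, n1, n2, alpha)
        except ValueError:
            pw = float("nan")
        rows.append({"comparison": f"{locus.name} allele frequency",
                     "p_cases": round(p1, 5), "p_controls": round(p2, 5),
                     "n_case_alleles": n1, "n_control_alleles": n2,
                     "power_percent": round(100 * pw, 1)})
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict[str, Path]:
    """Run the full pipeline; returns paths of the written tables.

    Any stage failure aborts the run with the stage named and removes
    partial outputs.  Re-running with an identical config reproduces
    byte-identical tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(config.seed, 4)
    written: dict[str, Path] = {}
    log_lines = [f"seed={config.seed}", f"child_seeds={seeds}"]

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            for p in written.values():
                p.unlink(missing_ok=True)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log_lines.append(f"stage={name} wall_s={time.perf_counter() - t0:.2f}")
        return result

    if config.input_path is not None:
        cohort = stage("load", lambda: read_cohort(config.input_path,
                                                   config.sim.panel, config.input_format))
    else:
        cohort = stage("simulate", lambda: simulate_cohort(
            dataclasses.replace(config.sim, seed=seeds[0])))
        cohort_path = out / "cohort.tsv"
        write_cohort(cohort, cohort_path)
        written["cohort"] = cohort_path

    tables = {
        "table1": lambda: baseline_table(cohort),
        "table2": lambda: single_locus_table(cohort, config.models, config.covariates),
        "table3": lambda: haplotype_table(cohort, config.genes, config.covariates,
                                          config.n_perm_haplo, config.min_hap_freq,
                                          seeds[1]),
        "table4": lambda: mdr_table(cohort, config.mdr_k, config.mdr_folds,
                                    config.n_perm_mdr, seeds[2]),
        "power": lambda: power_table(cohort, config.alpha),
    }
    for name, fn in tables.items():
        df = stage(name, fn)
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written[name] = path

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    written["log"] = out / "run.log"
    return written
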