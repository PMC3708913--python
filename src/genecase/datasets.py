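"""Published summary data of the RAGE/APE1 lung-cancer case-control study.

A hospital-based Han Chinese cohort of 819 lung-cancer patients and 803
cancer-free controls genotyped at three *RAGE* SNPs (rs1800625,
rs1800624, rs2070600) and two *APE1* SNPs (rs1760944, rs1130409).  The
individual-level data were never deposited; what is public are the
marginal genotype counts per locus, the baseline covariate summary, and
the per-gene haplotype frequency estimates.  These summaries drive two
things: exact reconstruction of every single-locus statistic (marginal
counts determine them completely) and the defaults of the synthetic
cohort simulator.
"""

from __future__ import annotations

from .data import GenotypeCountTable, LocusSpec

N_CASES = 819
N_CONTROLS = 803

#: study panel; minor allele is the second allele of the rs-X/Y naming
LUNG_PANEL: tuple[LocusSpec, ...] = (
    LocusSpec("rs1800625", "RAGE", "T", "C"),
    LocusSpec("rs1800624", "RAGE", "T", "A"),
    LocusSpec("rs2070600", "RAGE", "G", "A"),
    LocusSpec("rs1760944", "APE1", "G", "T"),
    LocusSpec("rs1130409", "APE1", "G", "T"),
)

RAGE_LOCI = ("rs1800625", "rs1800624", "rs2070600")
APE1_LOCI = ("rs1760944", "rs1130409")

#: per-locus genotype counts (major-hom, het, minor-hom), cases then controls
GENOTYPE_COUNTS: tuple[GenotypeCountTable, ...] = (
    GenotypeCountTable(LUNG_PANEL[0], (447, 303, 69), (485, 289, 29)),
    GenotypeCountTable(LUNG_PANEL[1], (471, 289, 59), (472, 287, 44)),
    GenotypeCountTable(LUNG_PANEL[2], (321, 382, 116), (352, 377, 74)),
    GenotypeCountTable(LUNG_PANEL[3], (321, 384, 114), (336, 369, 98)),
    GenotypeCountTable(LUNG_PANEL[4], (498, 273, 48), (531, 247, 25)),
)

#: binary covariate prevalences as (control, case) proportions
COVARIATE_PREVALENCES: dict[str, tuple[float, float]] = {
    "sex": (0.6476, 0.6484),  # proportion male
    "smoking": (0.0797, 0.3626),
    "drinking": (0.0809, 0.1685),
    "copd": (0.0473, 0.1453),
    "family_history": (0.1083, 0.1136),
}

#: age mean/SD as (control, case)
AGE_MEAN = (57.04, 57.35)
AGE_SD = (9.72, 10.51)

#: RAGE haplotype frequencies (rs1800625-rs1800624-rs2070600), (case, control).
#: The published control column sums to 0.9571; the unlisted eighth
#: haplotype T-A-A carries the remainder in the simulator defaults.
RAGE_HAP_FREQS: dict[str, tuple[float, float]] = {
    "T-T-G": (0.3023, 0.3295),
    "T-A-G": (0.1174, 0.1196),
    "C-T-G": (0.1735, 0.1915),
    "C-A-G": (0.1019, 0.0911),
    "C-A-A": (0.0772, 0.0399),
    "T-T-A": (0.1312, 0.1255),
    "C-T-A": (0.0706, 0.0600),
}

#: APE1 haplotype frequencies (rs1760944-rs1130409), (case, control)
APE1_HAP_FREQS: dict[str, tuple[float, float]] = {
    "G-G": (0.4324, 0.4587),
    "T-G": (0.2853, 0.2594),
    "G-T": (0.1881, 0.2017),
    "T-T": (0.0942, 0.0802),
}


def control_hap_freqs(gene: str) -> dict[str, float]:
    """Control-group haplotype frequency map for a gene, renormalised.

    Any probability mass the published table leaves unassigned goes to
    the missing haplotype (T-A-A for RAGE).
    """
    if gene == "RAGE":
        freqs = {h: c for h, (_, c) in RAGE_HAP_FREQS.items()}
        freqs["T-A-A"] = round(1.0 - sum(freqs.values()), 10)
    elif gene == "APE1":
        freqs = {h: c for h, (_, c) in APE1_HAP_FREQS.items()}
    else:
        raise ValueError(f"unknown gene {gene!r}")
    total = sum(freqs.values())
    return {h: f / total for h, f in freqs.items()}
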