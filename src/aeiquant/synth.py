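"""Synthetic qPCR cohort generator.

Generates patients (two independently drawn three-locus haplotypes each),
plate-level Ct data for the expression assay (target gene plus three
housekeepers, three pipetting replicates each) and for the allelic
discrimination assays (FAM/VIC dual-probe wells, five pipetting replicates
on both cDNA and genomic DNA), together with a per-patient truth record.

The generative model inverts the analysis formulas: a well containing
quantity ``q`` of template amplified by a probe of efficiency ``E`` crosses
threshold at

    Ct = intercept - ln(q) / ln(E) + Normal(0, replicate_ct_sd)

where ``intercept`` is the Ct of one unit of template.  With E = 2 every
halving of template costs exactly one cycle, so the allelic-ratio formula
2^-(FAM Ct - VIC Ct) recovers the true FAM:VIC quantity ratio.

Per-patient baseline expression of the target gene is log-normal
(log2 scale, standard deviation ``expression_log2_sd``), which at the
default spread reproduces the >200-fold between-patient variation seen in
cartilage.  Heterozygotes at the causal transcript SNP carry a true
minor:major cDNA ratio of ``true_aei_ratio`` (default 0.36, a minor-allele
deficit); genomic DNA is always 1:1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigurationError
from .types import SNP_PANEL, CtMeasurement, Patient, SnpDef, normalise_genotype

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "TruthRecord",
    "haplotype_freqs_from_ld",
    "default_haplotype_freqs",
    "simulate_genotypes",
    "simulate_ct_data",
    "simulate_cohort",
]

Haplotype = tuple[str, ...]

#: Panel order used for haplotypes throughout.
PANEL_ORDER = ("rs2615977", "rs1676486", "rs9659030")

# Signed pairwise disequilibrium (minor-allele coding) and three-way term
# reproducing the study's MAFs and pairwise r^2 (0.03 / 0.08 / 0.09) with
# all eight haplotype frequencies non-negative.
_D12_R2, _D13_R2, _D23_R2 = 0.03, 0.08, 0.09
_D12_SIGN, _D13_SIGN, _D23_SIGN = -1.0, 1.0, 1.0
_D123 = -0.0124


def haplotype_freqs_from_ld(
    mafs: Sequence[float],
    d12: float,
    d13: float,
    d23: float,
    d123: float = 0.0,
    snps: Sequence[SnpDef] | None = None,
) -> dict[Haplotype, float]:
    """Three-locus haplotype frequencies from marginal MAFs, the three
    signed pairwise disequilibria (minor-allele coding) and a three-way
    disequilibrium term.

    Uses the sign expansion f(u) = m1 m2 m3 + m3 D12 e1 e2 + m2 D13 e1 e3
    + m1 D23 e2 e3 + D123 e1 e2 e3 with e = +1 for the minor allele and
    -1 for the major, m the corresponding marginal frequency.
    """
    if snps is None:
        snps = [SNP_PANEL[s] for s in PANEL_ORDER]
    p = np.asarray(mafs, dtype=float)
    q = 1.0 - p
    pair_d = {(0, 1): d12, (0, 2): d13, (1, 2): d23}
    freqs: dict[Haplotype, float] = {}
    for u in np.ndindex(2, 2, 2):
        e = [1.0 if ui else -1.0 for ui in u]
        m = [p[i] if u[i] else q[i] for i in range(3)]
        val = m[0] * m[1] * m[2]
        val += m[2] * pair_d[(0, 1)] * e[0] * e[1]
        val += m[1] * pair_d[(0, 2)] * e[0] * e[2]
        val += m[0] * pair_d[(1, 2)] * e[1] * e[2]
        val += d123 * e[0] * e[1] * e[2]
        hap = tuple(
            snps[i].minor_allele if u[i] else snps[i].major_allele
            for i in range(3)
        )
        freqs[hap] = val
    total = sum(freqs.values())
    if min(freqs.values()) < -1e-12 or abs(total - 1.0) > 1e-9:
        raise ConfigurationError(
            "requested MAF/LD combination implies negative haplotype "
            "frequencies; adjust d123 or the pairwise terms"
        )
    return {h: max(v, 0.0) for h, v in freqs.items()}


def default_haplotype_freqs() -> dict[Haplotype, float]:
    """Default 8-haplotype distribution matching the study panel's MAFs
    and pairwise r-squared values."""
    snps = [SNP_PANEL[s] for s in PANEL_ORDER]
    p = np.array([s.maf for s in snps])
    q = 1.0 - p

    def d_from_r2(i: int, j: int, r2: float, sign: float) -> float:
        return sign * math.sqrt(r2 * p[i] * q[i] * p[j] * q[j])

    return haplotype_freqs_from_ld(
        p,
        d_from_r2(0, 1, _D12_R2, _D12_SIGN),
        d_from_r2(0, 2, _D13_R2, _D13_SIGN),
        d_from_r2(1, 2, _D23_R2, _D23_SIGN),
        _D123,
        snps,
    )


@dataclass
class SimulationConfig:
    """Every generative parameter of the synthetic cohort.

    Parameters
    ----------
    seed
        Master seed; identical configs produce bit-identical cohorts.
    n_patients
        Cohort size.
    joint_mix
        Fraction of knee (vs hip) joint replacements.
    haplotype_freqs
        Probability of each three-locus haplotype over
        (rs2615977, rs1676486, rs9659030); must sum to 1.  Defaults to the
        distribution implied by the study's MAFs and pairwise LD.
    true_aei_ratio
        True minor:major cDNA molecule ratio at the causal transcript SNP
        (0.36 = a 64% deficit of the minor allele).
    causal_snp
        SNP whose heterozygosity switches the allelic deficit on.
    assay_true_ratios
        Optional per-assay override of the true cDNA ratio, used to emulate
        position-dependent imbalance along the transcript.
    expression_log2_sd
        Between-patient spread (log2 scale) of baseline target expression.
    replicate_ct_sd
        Pipetting-replicate Ct noise (cycles).
    probe_efficiency
        Per-cycle amplification base, in (1, 2]; 2 is perfect doubling.
    channel_noise_correlation
        Correlation of the FAM and VIC noise terms within one well
        (default 0: independent channels).
    n_expr_replicates, n_aei_replicates
        Pipetting replicates for the expression assay (3) and for each
        template of the allelic assays (5).
    housekeeper_cts
        Baseline Ct of each housekeeper gene.
    """

    seed: int = 0
    n_patients: int = 30
    joint_mix: float = 0.5
    haplotype_freqs: Mapping[Haplotype, float] = field(
        default_factory=default_haplotype_freqs
    )
    snp_ids: tuple[str, ...] = PANEL_ORDER
    true_aei_ratio: float = 0.36
    causal_snp: str = "rs1676486"
    assay_true_ratios: Mapping[str, float] = field(default_factory=dict)
    aei_snps: tuple[str, ...] = ("rs1676486", "rs9659030")
    expression_log2_sd: float = 4.0
    replicate_ct_sd: float = 0.1
    probe_efficiency: float = 2.0
    channel_noise_correlation: float = 0.0
    n_expr_replicates: int = 3
    n_aei_replicates: int = 5
    housekeeper_cts: Mapping[str, float] = field(
        default_factory=lambda: {"HPRT1": 24.0, "GAPDH": 18.0, "18S": 10.0}
    )
    target_label: str = "COL11A1"
    target_baseline_ct: float = 26.0
    fam_intercept: float = 25.0
    vic_intercept: float = 25.0
    include_expression: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        freqs = list(self.haplotype_freqs.values())
        if any(f < 0 for f in freqs):
            raise ConfigurationError("haplotype frequencies must be >= 0")
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise ConfigurationError("haplotype frequencies must sum to 1")
        if self.true_aei_ratio <= 0:
            raise ConfigurationError("true_aei_ratio must be > 0")
        if any(r <= 0 for r in self.assay_true_ratios.values()):
            raise ConfigurationError("assay true ratios must be > 0")
        if self.expression_log2_sd < 0 or self.replicate_ct_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if not 1.0 < self.probe_efficiency <= 2.0:
            raise ConfigurationError("probe_efficiency must lie in (1, 2]")
        if not 0.0 <= self.channel_noise_correlation <= 1.0:
            raise ConfigurationError(
                "channel_noise_correlation must lie in [0, 1]"
            )
        if not 0.0 <= self.joint_mix <= 1.0:
            raise ConfigurationError("joint_mix must lie in [0, 1]")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.n_expr_replicates < 1 or self.n_aei_replicates < 1:
            raise ConfigurationError("replicate counts must be >= 1")

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)

    def true_ratio_for(self, assay: str, patient: Patient) -> float:
        """Effective true cDNA minor:major ratio for one assay on one
        patient: the per-assay override if set, else ``true_aei_ratio``
        when the patient is heterozygous at the causal SNP, else 1."""
        if assay in self.assay_true_ratios:
            return float(self.assay_true_ratios[assay])
        if patient.is_heterozygous(self.causal_snp):
            return self.true_aei_ratio
        return 1.0


@dataclass
class TruthRecord:
    """Generating truth for one patient (never visible to the analyses)."""

    patient_id: str
    log2_expression: float
    haplotypes: tuple[Haplotype, Haplotype]
    assay_ratios: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    patients: list[Patient]
    ct_table: list[CtMeasurement]
    truth: dict[str, TruthRecord]

    def validate(self) -> None:
        for p in self.patients:
            if p.patient_id not in self.truth:
                raise ConfigurationError(f"no truth record for {p.patient_id}")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _simulate_phased(
    config: SimulationConfig,
) -> tuple[list[Patient], dict[str, tuple[Haplotype, Haplotype]]]:
    rng = _rng(config, 0)
    haps = list(config.haplotype_freqs.keys())
    probs = np.array([config.haplotype_freqs[h] for h in haps], dtype=float)
    probs = probs / probs.sum()
    width = max(3, len(str(config.n_patients)))
    patients: list[Patient] = []
    phased: dict[str, tuple[Haplotype, Haplotype]] = {}
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        h1, h2 = (haps[j] for j in rng.choice(len(haps), size=2, p=probs))
        genotypes = {
            snp: normalise_genotype((h1[k], h2[k]))
            for k, snp in enumerate(config.snp_ids)
        }
        sex = "F" if rng.random() < 0.5 else "M"
        age = float(rng.integers(55, 86))
        joint = "knee" if rng.random() < config.joint_mix else "hip"
        patients.append(Patient(pid, sex, age, joint, genotypes))
        phased[pid] = (h1, h2)
    return patients, phased


def simulate_genotypes(config: SimulationConfig) -> list[Patient]:
    """Draw ``n_patients`` patients as two independent three-locus
    haplotypes each; the genotype at each SNP is the unordered allele pair
    (phase is not exposed on the Patient)."""
    config.validate()
    return _simulate_phased(config)[0]


def _ct(quantity: float, intercept: float, ln_e: float) -> float:
    return intercept - math.log(quantity) / ln_e


def simulate_ct_data(
    patients: Sequence[Patient],
    config: SimulationConfig,
    haplotypes: Optional[Mapping[str, tuple[Haplotype, Haplotype]]] = None,
) -> SyntheticCohort:
    """Generate all plate wells for the given patients.

    Expression wells (cDNA only): the target gene and each housekeeper,
    ``n_expr_replicates`` each.  Allelic wells: for every patient
    heterozygous at an AEI SNP, FAM and VIC Cts for ``n_aei_replicates``
    wells on both cDNA and gDNA.  The FAM probe reads the minor allele,
    VIC the major, so a true ratio of 0.36 is a minor-allele deficit.
    """
    if not patients:
        raise ConfigurationError("patients must be non-empty")
    config.validate()
    rng = _rng(config, 1)
    ln_e = math.log(config.probe_efficiency)
    sd = config.replicate_ct_sd
    rho = config.channel_noise_correlation
    wells: list[CtMeasurement] = []
    truth: dict[str, TruthRecord] = {}

    def noise_pair() -> tuple[float, float]:
        if sd == 0.0:
            return 0.0, 0.0
        if rho == 0.0:
            z = rng.normal(0.0, sd, size=2)
            return float(z[0]), float(z[1])
        shared = rng.normal(0.0, 1.0)
        own = rng.normal(0.0, 1.0, size=2)
        a, b = math.sqrt(rho), math.sqrt(1.0 - rho)
        return sd * (a * shared + b * own[0]), sd * (a * shared + b * own[1])

    for patient in patients:
        x = float(rng.normal(0.0, config.expression_log2_sd))
        quantity = 2.0**x
        pid = patient.patient_id
        if config.include_expression:
            target_ct0 = _ct(quantity, config.target_baseline_ct, ln_e)
            for rep in range(1, config.n_expr_replicates + 1):
                wells.append(CtMeasurement(
                    pid, "cDNA", "expression", config.target_label, rep,
                    target_ct0 + (rng.normal(0.0, sd) if sd else 0.0),
                ))
            for gene, base in config.housekeeper_cts.items():
                for rep in range(1, config.n_expr_replicates + 1):
                    wells.append(CtMeasurement(
                        pid, "cDNA", "expression", gene, rep,
                        base + (rng.normal(0.0, sd) if sd else 0.0),
                    ))
        assay_ratios: dict[str, float] = {}
        for snp in config.aei_snps:
            if not patient.is_heterozygous(snp):
                continue
            r = config.true_ratio_for(snp, patient)
            assay_ratios[snp] = r
            # cDNA: major-allele quantity tracks patient expression,
            # minor = r x major; gDNA: both alleles at unit quantity.
            for template, q_minor, q_major in (
                ("cDNA", r * quantity, quantity),
                ("gDNA", 1.0, 1.0),
            ):
                fam0 = _ct(q_minor, config.fam_intercept, ln_e)
                vic0 = _ct(q_major, config.vic_intercept, ln_e)
                for rep in range(1, config.n_aei_replicates + 1):
                    nf, nv = noise_pair()
                    wells.append(CtMeasurement(
                        pid, template, snp, "FAM", rep, fam0 + nf))
                    wells.append(CtMeasurement(
                        pid, template, snp, "VIC", rep, vic0 + nv))
        truth[pid] = TruthRecord(
            pid, x,
            tuple(haplotypes[pid]) if haplotypes else ((), ()),
            assay_ratios,
        )
    cohort = SyntheticCohort(list(patients), wells, truth)
    cohort.validate()
    return cohort


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full cohort: phased genotypes plus plate data, with phase retained
    in the truth records."""
    patients, phased = _simulate_phased(config)
    return simulate_ct_data(patients, config, phased)
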