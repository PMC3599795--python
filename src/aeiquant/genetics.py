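"""Population-genetic and association computations.

Case-control allelic association on a 2x2 allele-count table: odds ratio,
Wald 95% confidence interval on the log odds ratio, and the allelic
(per-chromosome) Pearson chi-square test with 1 df.  Hardy-Weinberg
expectations, pairwise linkage disequilibrium (D, D', r^2) from haplotype
frequencies, and an EM estimator of two-locus haplotype frequencies from
unphased genotypes (the double-heterozygote phase ambiguity is the only
latent variable).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError
from .types import SNP_PANEL, Patient, SnpDef, get_snp

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "LdResult",
    "HweProfile",
    "allelic_association",
    "counts_from_frequency",
    "hwe_profile",
    "ld_from_haplotypes",
    "em_haplotype_freqs",
    "pairwise_ld",
    "AllelicAssociation",
    "AssociationResults",
]


@dataclass(frozen=True)
class AssociationResult:
    """Allelic case-control association on a 2x2 allele-count table."""

    n_cases: int
    n_controls: int
    case_allele_counts: tuple[int, int]  # (risk, other)
    control_allele_counts: tuple[int, int]
    case_freq: float
    control_freq: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi_square: float
    p_value: float


@dataclass(frozen=True)
class LdResult:
    """Pairwise linkage disequilibrium between two biallelic loci."""

    snp_a: str
    snp_b: str
    haplotype_freqs: tuple[float, float, float, float]  # AB, Ab, aB, ab
    d: float
    d_prime: float
    r_squared: float
    em_iterations: int = 0
    em_converged: bool = True
    defined: bool = True  # False when a locus is monomorphic
    log_likelihood: Optional[float] = None


@dataclass(frozen=True)
class HweProfile:
    """Hardy-Weinberg expectations at allele frequency p."""

    allele_freq: float
    genotype_freqs: tuple[float, float, float]  # (hom p, het, hom q)
    expected_heterozygosity: float


def counts_from_frequency(freq: float, n_individuals: int) -> tuple[int, int]:
    """Reconstruct (risk, other) allele counts from a printed allele
    frequency and a diploid sample size: round(freq x 2N)."""
    total = 2 * n_individuals
    risk = round(freq * total)
    return risk, total - risk


def allelic_association(
    case_counts: Sequence[int],
    control_counts: Sequence[int],
    n_cases: Optional[int] = None,
    n_controls: Optional[int] = None,
) -> AssociationResult:
    """Allelic odds ratio, Wald 95% CI and chi-square test.

    ``case_counts``/``control_counts`` are (risk-allele, other-allele)
    chromosome counts.  A zero cell triggers the Haldane-Anscombe
    continuity correction (+0.5 to every cell) with a warning.
    """
    a, b = (int(x) for x in case_counts)
    c, d = (int(x) for x in control_counts)
    if min(a, b, c, d) < 0:
        raise ValueError("allele counts must be non-negative")
    cells = [a, b, c, d]
    if 0 in cells:
        logger.warning(
            "zero cell in 2x2 table %s; applying +0.5 continuity correction",
            cells,
        )
        aa, bb, cc, dd = (x + 0.5 for x in cells)
    else:
        aa, bb, cc, dd = (float(x) for x in cells)
    odds_ratio = (aa / bb) / (cc / dd)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = math.log(odds_ratio)
    ci_low = math.exp(log_or - 1.96 * se)
    ci_high = math.exp(log_or + 1.96 * se)
    table = np.array([[a, b], [c, d]], dtype=float)
    if 0 in cells:
        table += 0.5
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return AssociationResult(
        n_cases if n_cases is not None else (a + b) // 2,
        n_controls if n_controls is not None else (c + d) // 2,
        (a, b), (c, d),
        a / (a + b), c / (c + d),
        odds_ratio, ci_low, ci_high, float(chi2), float(p),
    )


def hwe_profile(p: float) -> HweProfile:
    """Expected genotype frequencies (p^2, 2pq, q^2) at allele freq p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency must lie in [0, 1], got {p}")
    q = 1.0 - p
    return HweProfile(p, (p * p, 2 * p * q, q * q), 2 * p * q)


def ld_from_haplotypes(
    hap_freqs: Sequence[float],
    snp_a: str = "A",
    snp_b: str = "B",
    em_iterations: int = 0,
    em_converged: bool = True,
    log_likelihood: Optional[float] = None,
) -> LdResult:
    """D, D' and r^2 from the four two-locus haplotype frequencies
    (order: AB, Ab, aB, ab).

    A monomorphic locus makes every LD measure undefined; the result is
    returned flagged with ``defined=False`` and NaN statistics.
    """
    f = np.asarray(hap_freqs, dtype=float)
    if f.shape != (4,) or np.any(f < -1e-12):
        raise ValueError("need 4 non-negative haplotype frequencies")
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("haplotype frequencies must sum to 1")
    p_a = f[0] + f[1]
    p_b = f[0] + f[2]
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    denom = p_a * q_a * p_b * q_b
    if denom <= 0:
        logger.warning("monomorphic locus: LD undefined")
        return LdResult(
            snp_a, snp_b, tuple(f), float("nan"), float("nan"),
            float("nan"), em_iterations, em_converged, False,
            log_likelihood,
        )
    d = f[0] - p_a * p_b
    if d > 0:
        d_max = min(p_a * q_b, q_a * p_b)
    else:
        d_max = min(p_a * p_b, q_a * q_b)
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r_squared = d * d / denom
    return LdResult(
        snp_a, snp_b, tuple(f), float(d), float(d_prime), float(r_squared),
        em_iterations, em_converged, True, log_likelihood,
    )


GenotypePair = tuple[tuple[str, str], tuple[str, str]]


def _code_locus(
    genotypes: Sequence[tuple[str, str]], allele_order: Optional[Sequence[str]]
) -> list[int]:
    """Count of the reference allele (first of allele_order) per individual."""
    observed = sorted({a for g in genotypes for a in g})
    if allele_order is None:
        allele_order = observed
    if not set(observed) <= set(allele_order):
        raise ValueError(
            f"alleles {observed} not all in declared order {allele_order}"
        )
    ref = allele_order[0]
    return [sum(a == ref for a in g) for g in genotypes]


def em_haplotype_freqs(
    genotype_pairs: Iterable[GenotypePair],
    snp_a: str = "A",
    snp_b: str = "B",
    alleles_a: Optional[Sequence[str]] = None,
    alleles_b: Optional[Sequence[str]] = None,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> LdResult:
    """EM estimate of two-locus haplotype frequencies from unphased
    genotypes, then D'/r^2.

    Only double heterozygotes are phase-ambiguous; everyone else
    contributes haplotype counts directly, so with no double heterozygote
    the estimate equals direct counting.  Convergence: max frequency
    change < ``tol`` or ``max_iter`` iterations (non-convergence is
    flagged, the best estimate returned).
    """
    pairs = [p for p in genotype_pairs if p[0] is not None and p[1] is not None]
    if len(pairs) < 2:
        raise InsufficientDataError(
            f"EM needs >= 2 genotyped individuals, got {len(pairs)}"
        )
    ga = _code_locus([p[0] for p in pairs], alleles_a)
    gb = _code_locus([p[1] for p in pairs], alleles_b)
    # genotype table: n[i][j] = individuals with i copies of allele A,
    # j copies of allele B (i, j in 0..2)
    n = np.zeros((3, 3))
    for i, j in zip(ga, gb):
        n[i, j] += 1
    n_hap = 2.0 * len(pairs)

    # fixed haplotype contributions from phase-unambiguous genotypes;
    # haplotype order: AB, Ab, aB, ab
    fixed = np.zeros(4)
    fixed[0] = 2 * n[2, 2] + n[2, 1] + n[1, 2]
    fixed[1] = 2 * n[2, 0] + n[2, 1] + n[1, 0]
    fixed[2] = 2 * n[0, 2] + n[0, 1] + n[1, 2]
    fixed[3] = 2 * n[0, 0] + n[0, 1] + n[1, 0]
    n_dh = n[1, 1]  # double heterozygotes: AB/ab or Ab/aB

    f = np.full(4, 0.25)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: split double heterozygotes between the two phasings
        p_cis = 2.0 * f[0] * f[3]
        p_trans = 2.0 * f[1] * f[2]
        total = p_cis + p_trans
        w = p_cis / total if total > 0 else 0.5
        counts = fixed + n_dh * np.array([w, 1 - w, 1 - w, w])
        new_f = counts / n_hap
        delta = np.max(np.abs(new_f - f))
        f = new_f
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    ll = em_log_likelihood(n, f)
    return ld_from_haplotypes(
        f, snp_a, snp_b, em_iterations=it, em_converged=converged,
        log_likelihood=ll,
    )


def em_log_likelihood(n: np.ndarray, f: Sequence[float]) -> float:
    """Observed-data multinomial log-likelihood of a 3x3 genotype table
    under random union of haplotypes with frequencies ``f`` (AB,Ab,aB,ab)."""
    f = np.asarray(f, dtype=float)
    # genotype prob for (i copies of A, j copies of B)
    hap_a = np.array([1, 1, 0, 0])  # copies of allele A per haplotype
    hap_b = np.array([1, 0, 1, 0])
    probs = np.zeros((3, 3))
    for h1 in range(4):
        for h2 in range(4):
            i = hap_a[h1] + hap_a[h2]
            j = hap_b[h1] + hap_b[h2]
            probs[i, j] += f[h1] * f[h2]
    with np.errstate(divide="ignore"):
        logp = np.where(n > 0, np.log(np.maximum(probs, 1e-300)), 0.0)
    return float(np.sum(n * logp))


def pairwise_ld(
    patients: Sequence[Patient],
    snp_a: str,
    snp_b: str,
    panel: Mapping[str, SnpDef] = SNP_PANEL,
) -> LdResult:
    """Table-1-style pairwise D'/r^2 between two panel SNPs from unphased
    patient genotypes (EM over the double-heterozygote ambiguity).
    Allele coding: minor allele of each SNP is allele 'A'."""
    sa, sb = get_snp(snp_a, panel), get_snp(snp_b, panel)
    pairs = [
        (p.genotype(snp_a), p.genotype(snp_b))
        for p in patients
        if p.genotype(snp_a) is not None and p.genotype(snp_b) is not None
    ]
    return em_haplotype_freqs(
        pairs, snp_a, snp_b,
        alleles_a=(sa.minor_allele, sa.major_allele),
        alleles_b=(sb.minor_allele, sb.major_allele),
    )


class AllelicAssociation:
    """Case-control allelic association model on allele counts.

    Build from explicit (risk, other) chromosome counts, or from printed
    allele frequencies and diploid cohort sizes via
    :meth:`from_frequencies`.
    """

    def __init__(
        self,
        case_counts: Sequence[int],
        control_counts: Sequence[int],
        n_cases: Optional[int] = None,
        n_controls: Optional[int] = None,
    ) -> None:
        self.case_counts = tuple(int(x) for x in case_counts)
        self.control_counts = tuple(int(x) for x in control_counts)
        self.n_cases = n_cases
        self.n_controls = n_controls

    @classmethod
    def from_frequencies(
        cls,
        case_freq: float,
        n_cases: int,
        control_freq: float,
        n_controls: int,
    ) -> "AllelicAssociation":
        return cls(
            counts_from_frequency(case_freq, n_cases),
            counts_from_frequency(control_freq, n_controls),
            n_cases, n_controls,
        )

    def fit(self) -> "AssociationResults":
        return AssociationResults(self, allelic_association(
            self.case_counts, self.control_counts,
            self.n_cases, self.n_controls,
        ))


@dataclass
class AssociationResults:
    model: AllelicAssociation
    result: AssociationResult

    def summary(self) -> str:
        r = self.result
        return "\n".join([
            "Allelic case-control association",
            f"  cases:    {r.case_allele_counts[0]}/"
            f"{sum(r.case_allele_counts)} risk alleles "
            f"(freq {r.case_freq:.4f}, n = {r.n_cases})",
            f"  controls: {r.control_allele_counts[0]}/"
            f"{sum(r.control_allele_counts)} risk alleles "
            f"(freq {r.control_freq:.4f}, n = {r.n_controls})",
            f"  odds ratio: {r.odds_ratio:.3f} "
            f"(95% CI {r.ci_low:.3f}-{r.ci_high:.3f})",
            f"  allelic chi-square: {r.chi_square:.3f}, "
            f"p = {r.p_value:.3g}",
        ])
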