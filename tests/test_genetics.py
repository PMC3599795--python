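"""Association, Hardy-Weinberg, LD and EM haplotype estimation."""
import math

import numpy as np
import pytest

from aeiquant import (
    AllelicAssociation,
    InsufficientDataError,
    SimulationConfig,
    allelic_association,
    counts_from_frequency,
    em_haplotype_freqs,
    hwe_profile,
    ld_from_haplotypes,
    pairwise_ld,
    simulate_cohort,
)
from aeiquant.genetics import em_log_likelihood
from aeiquant.synth import PANEL_ORDER
from aeiquant.types import SNP_PANEL


def test_association_worked_example_from_printed_frequencies():
    """7,410 cases at T-freq 0.201 vs 11,009 controls at 0.1905 gives
    OR 1.069 (95% CI 1.015-1.127) to three decimals."""
    model = AllelicAssociation.from_frequencies(0.201, 7410, 0.1905, 11009)
    assert model.case_counts == (2979, 11841)
    assert model.control_counts == (4194, 17824)
    r = model.fit().result
    assert round(r.odds_ratio, 3) == 1.069
    assert round(r.ci_low, 3) == 1.015
    assert round(r.ci_high, 3) == 1.127
    assert r.ci_low <= r.odds_ratio <= r.ci_high
    assert r.case_freq == pytest.approx(2979 / 14820, abs=1e-12)


def test_hand_arithmetic_odds_ratio():
    r = allelic_association((10, 90), (20, 80))
    assert r.odds_ratio == pytest.approx((10 / 90) / (20 / 80), abs=1e-12)
    assert r.odds_ratio == pytest.approx(0.4444, abs=5e-5)


def test_identical_frequencies_give_unit_odds_ratio():
    r = allelic_association((50, 150), (100, 300))
    assert r.odds_ratio == pytest.approx(1.0, abs=1e-12)


def test_zero_cell_triggers_continuity_correction(caplog):
    with caplog.at_level("WARNING"):
        r = allelic_association((0, 100), (10, 90))
    assert "continuity correction" in caplog.text
    assert r.odds_ratio == pytest.approx(
        (0.5 / 100.5) / (10.5 / 90.5), abs=1e-12)
    assert math.isfinite(r.ci_low) and math.isfinite(r.ci_high)


def test_swapping_rows_inverts_odds_ratio_and_mirrors_ci():
    a = allelic_association((2979, 11841), (4194, 17824))
    b = allelic_association((4194, 17824), (2979, 11841))
    assert b.odds_ratio == pytest.approx(1 / a.odds_ratio, rel=1e-12)
    assert b.ci_low == pytest.approx(1 / a.ci_high, rel=1e-12)
    assert b.ci_high == pytest.approx(1 / a.ci_low, rel=1e-12)
    assert b.chi_square == pytest.approx(a.chi_square, rel=1e-12)


def test_wald_ci_coverage_at_study_scale():
    """1000 simulated tables at the study's cohort sizes and true OR
    1.069: the 95% Wald CI covers truth in 95% +/- 2%."""
    rng = np.random.default_rng(31)
    p0 = 0.1905
    odds1 = (p0 / (1 - p0)) * 1.069
    p1 = odds1 / (1 + odds1)
    true_or = 1.069
    n_case, n_control = 2 * 7410, 2 * 11009
    covered = 0
    n_sim = 1000
    for _ in range(n_sim):
        a = rng.binomial(n_case, p1)
        c = rng.binomial(n_control, p0)
        r = allelic_association((a, n_case - a), (c, n_control - c))
        covered += r.ci_low <= true_or <= r.ci_high
    assert abs(covered / n_sim - 0.95) < 0.02


@pytest.mark.parametrize("p,expected", [
    (0.5, (0.25, 0.5, 0.25)),
    (0.0, (0.0, 0.0, 1.0)),
    (0.202, (0.040804, 2 * 0.202 * 0.798, 0.798**2)),
])
def test_hwe_expected_genotype_frequencies(p, expected):
    prof = hwe_profile(p)
    assert prof.genotype_freqs == pytest.approx(expected, abs=1e-9)
    assert sum(prof.genotype_freqs) == pytest.approx(1.0, abs=1e-12)
    assert prof.expected_heterozygosity == pytest.approx(
        expected[1], abs=1e-12)


def test_hwe_rejects_out_of_range_frequency():
    with pytest.raises(ValueError):
        hwe_profile(1.2)


def test_perfect_ld_from_haplotype_frequencies():
    r = ld_from_haplotypes((0.5, 0.0, 0.0, 0.5))
    assert r.d_prime == pytest.approx(1.0, abs=1e-12)
    assert r.r_squared == pytest.approx(1.0, abs=1e-12)


def test_independent_loci_have_zero_ld():
    pa, pb = 0.3, 0.6
    freqs = (pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb))
    r = ld_from_haplotypes(freqs)
    assert r.d == pytest.approx(0.0, abs=1e-12)
    assert r.r_squared == pytest.approx(0.0, abs=1e-12)


def test_hand_arithmetic_ld():
    """freqs (0.4, 0.2, 0.1, 0.3): D = 0.4 - 0.6*0.5 = 0.10,
    r^2 = 0.01 / (0.6*0.4*0.5*0.5) = 1/6."""
    r = ld_from_haplotypes((0.4, 0.2, 0.1, 0.3))
    assert r.d == pytest.approx(0.10, abs=1e-12)
    assert r.r_squared == pytest.approx(1 / 6, abs=1e-9)
    # D > 0: D_max = min(pA*qB, qA*pB) = min(0.3, 0.2) = 0.2
    assert r.d_prime == pytest.approx(0.5, abs=1e-12)


def test_monomorphic_locus_flagged_undefined():
    r = ld_from_haplotypes((0.7, 0.3, 0.0, 0.0))  # locus B monomorphic? no:
    # pB = 0.7; locus A monomorphic (pA = 1)
    assert not r.defined
    assert math.isnan(r.r_squared)


def _pairs(genotype_counts):
    """Expand {(gA, gB): n} into a genotype-pair list."""
    out = []
    for (ga, gb), n in genotype_counts.items():
        out.extend([(ga, gb)] * n)
    return out


def test_em_equals_direct_counting_without_double_heterozygotes():
    pairs = _pairs({
        (("A", "A"), ("B", "B")): 10,
        (("A", "A"), ("B", "b")): 6,
        (("A", "a"), ("B", "B")): 4,
        (("a", "a"), ("b", "b")): 5,
    })
    r = em_haplotype_freqs(pairs, alleles_a=("A", "a"), alleles_b=("B", "b"))
    # direct gamete counting: 2*25 = 50 haplotypes
    counts = np.array([
        2 * 10 + 6 + 4,  # AB
        6,               # Ab
        4,               # aB
        2 * 5,           # ab
    ], dtype=float)
    assert np.allclose(r.haplotype_freqs, counts / 50, atol=1e-6)
    assert r.em_converged


def test_identically_typed_loci_give_perfect_correlation():
    pairs = _pairs({
        (("A", "A"), ("B", "B")): 8,
        (("A", "a"), ("B", "b")): 4,   # double het, but only one phasing
        (("a", "a"), ("b", "b")): 8,   # is consistent with the rest
    })
    r = em_haplotype_freqs(pairs, alleles_a=("A", "a"), alleles_b=("B", "b"))
    assert r.r_squared == pytest.approx(1.0, abs=1e-6)
    assert r.d_prime == pytest.approx(1.0, abs=1e-6)


def test_em_log_likelihood_nondecreasing_over_iterations():
    rng = np.random.default_rng(44)
    cohort_pairs = []
    # draw from a distribution with real phase ambiguity
    freqs = np.array([0.4, 0.1, 0.2, 0.3])
    haps = [("A", "B"), ("A", "b"), ("a", "B"), ("a", "b")]
    for _ in range(60):
        h1, h2 = (haps[i] for i in rng.choice(4, size=2, p=freqs))
        cohort_pairs.append((tuple(sorted((h1[0], h2[0]))),
                             tuple(sorted((h1[1], h2[1])))))
    lls = []
    for k in range(1, 12):
        r = em_haplotype_freqs(
            cohort_pairs, alleles_a=("A", "a"), alleles_b=("B", "b"),
            max_iter=k, tol=0.0,
        )
        lls.append(r.log_likelihood)
    assert all(b >= a - 1e-10 for a, b in zip(lls, lls[1:]))


def test_em_recovers_generating_haplotype_frequencies():
    """Phased synthetic truth, scrambled to genotypes: EM frequencies are
    within 3 binomial SEs of the generating two-locus frequencies."""
    n = 5000
    cohort = simulate_cohort(SimulationConfig(
        seed=21, n_patients=n, aei_snps=(), include_expression=False,
    ))
    snp_a, snp_b = "rs2615977", "rs1676486"
    ia, ib = PANEL_ORDER.index(snp_a), PANEL_ORDER.index(snp_b)
    # truth two-locus haplotype counts (minor-allele coding, AB..ab)
    minors = (SNP_PANEL[snp_a].minor_allele, SNP_PANEL[snp_b].minor_allele)
    truth_counts = np.zeros(4)
    for rec in cohort.truth.values():
        for h in rec.haplotypes:
            i = 0 if h[ia] == minors[0] else 1
            j = 0 if h[ib] == minors[1] else 1
            truth_counts[2 * i + j] += 1
    truth_freqs = truth_counts / (2 * n)
    est = pairwise_ld(cohort.patients, snp_a, snp_b)
    for f_est, f_true in zip(est.haplotype_freqs, truth_freqs):
        se = math.sqrt(max(f_true * (1 - f_true), 1e-6) / (2 * n))
        assert abs(f_est - f_true) < 3 * se


def test_em_agrees_with_direct_route_on_unambiguous_data():
    pairs = _pairs({
        (("A", "A"), ("B", "B")): 30,
        (("a", "a"), ("b", "b")): 20,
        (("A", "a"), ("B", "B")): 10,
    })
    em = em_haplotype_freqs(pairs, alleles_a=("A", "a"),
                            alleles_b=("B", "b"))
    direct = ld_from_haplotypes(em.haplotype_freqs)
    assert em.d_prime == pytest.approx(direct.d_prime, abs=1e-6)
    assert em.r_squared == pytest.approx(direct.r_squared, abs=1e-6)


def test_em_needs_two_individuals():
    with pytest.raises(InsufficientDataError):
        em_haplotype_freqs([(("A", "a"), ("B", "b"))])


def test_counts_from_frequency_round_trip():
    risk, other = counts_from_frequency(0.201, 7410)
    assert (risk, other) == (2979, 11841)
    assert risk + other == 2 * 7410


def test_association_summary_mentions_key_quantities():
    s = AllelicAssociation.from_frequencies(
        0.201, 7410, 0.1905, 11009).fit().summary()
    assert "1.069" in s and "1.015" in s and "1.127" in s
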