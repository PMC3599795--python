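"""Shared fixtures: small deterministic cohorts built by the simulator."""
from __future__ import annotations

import pytest

from aeiquant import Patient, SimulationConfig, simulate_ct_data


def make_het_patients(n: int, snp_id: str = "rs1676486") -> list[Patient]:
    """n patients heterozygous at ``snp_id`` (C/T by default), homozygous
    major elsewhere."""
    genos = {
        "rs2615977": ("T", "T"),
        "rs1676486": ("C", "C"),
        "rs9659030": ("A", "A"),
    }
    het = {"rs2615977": ("G", "T"), "rs1676486": ("C", "T"),
           "rs9659030": ("A", "G")}
    out = []
    for i in range(n):
        g = dict(genos)
        g[snp_id] = het[snp_id]
        out.append(Patient(f"H{i + 1:03d}", genotypes=g))
    return out


def make_het_cohort(n: int = 22, seed: int = 0, **overrides):
    """AEI-only cohort of ``n`` rs1676486 heterozygotes."""
    defaults = dict(
        seed=seed, n_patients=n, include_expression=False,
        aei_snps=("rs1676486",),
    )
    defaults.update(overrides)
    config = SimulationConfig(**defaults)
    return simulate_ct_data(make_het_patients(n), config), config


@pytest.fixture
def het_cohort():
    """22 rs1676486 heterozygotes at the study's assay conditions
    (true ratio 0.36, Ct SD 0.1, 5+5 replicates)."""
    cohort, _ = make_het_cohort(22, seed=0)
    return cohort


@pytest.fixture
def full_cohort():
    """A 30-patient cohort with expression and AEI plates."""
    from aeiquant import simulate_cohort

    return simulate_cohort(SimulationConfig(seed=7, n_patients=30))
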