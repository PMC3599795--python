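"""Relative quantification by the 2^-dCt method with multi-housekeeper
normalisation, and genotype-stratified nonparametric comparison.

The target gene's mean Ct is referenced against the grand mean of all
pooled housekeeper Ct values (three genes x three pipetting replicates =
nine values per patient): dCt = mean(target) - mean(housekeepers), and
relative expression = 2^-dCt.  Stratified comparisons use Kruskal-Wallis
across three genotype classes and the two-sided Mann-Whitney U test for
two classes (carrier groupings, or when a genotype class is absent).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .stats import kruskal_wallis, mann_whitney_u
from .types import SNP_PANEL, CtMeasurement, Patient, SnpDef, get_snp

logger = logging.getLogger(__name__)

DEFAULT_TARGET = "COL11A1"
DEFAULT_HOUSEKEEPERS = ("HPRT1", "GAPDH", "18S")

THREE_GENOTYPE = "three-genotype"
CARRIER = "carrier-vs-noncarrier"


@dataclass(frozen=True)
class ExpressionResult:
    """Per-patient relative expression of the target gene."""

    patient_id: str
    target_mean_ct: float
    housekeeper_mean_ct: float
    delta_ct: float
    rel_expr: float
    n_target_replicates: int
    n_housekeeper_values: int


@dataclass(frozen=True)
class StratifiedComparison:
    """One genotype-stratified comparison of relative expression."""

    snp_id: str
    grouping: str
    group_labels: tuple[str, ...]
    group_sizes: tuple[int, ...]
    group_values: tuple[tuple[float, ...], ...]
    statistic: float
    p_value: float
    test_name: str  # {mann-whitney, kruskal-wallis}


def relative_expression(
    ct: Sequence[CtMeasurement],
    patient_id: str,
    target_label: str = DEFAULT_TARGET,
    housekeeper_labels: Sequence[str] = DEFAULT_HOUSEKEEPERS,
) -> ExpressionResult:
    """2^-dCt relative expression for one patient.

    Uses all determined cDNA wells; the housekeeper reference is the one
    grand arithmetic mean of every pooled housekeeper Ct value.
    """
    target = [
        m.ct for m in ct
        if m.patient_id == patient_id and m.template == "cDNA"
        and m.channel == target_label and m.determined
    ]
    housekeepers = [
        m.ct for m in ct
        if m.patient_id == patient_id and m.template == "cDNA"
        and m.channel in housekeeper_labels and m.determined
    ]
    if not target:
        raise InsufficientDataError(
            f"{patient_id}: no usable {target_label} wells"
        )
    if not housekeepers:
        raise InsufficientDataError(
            f"{patient_id}: no usable housekeeper wells"
        )
    target_mean = float(np.mean(target))
    hk_mean = float(np.mean(housekeepers))
    delta = target_mean - hk_mean
    return ExpressionResult(
        patient_id, target_mean, hk_mean, delta, float(2.0 ** (-delta)),
        len(target), len(housekeepers),
    )


def _genotype_label(patient: Patient, snp: SnpDef) -> Optional[str]:
    g = patient.genotype(snp.snp_id)
    if g is None:
        return None
    # order major allele first for readable class labels (CC, CT, TT)
    ordered = sorted(g, key=lambda a: a != snp.major_allele)
    return "".join(ordered)


def stratify_by_genotype(
    results: Sequence[ExpressionResult],
    patients: Sequence[Patient],
    snp_id: str,
    grouping: str = THREE_GENOTYPE,
    panel: Mapping[str, SnpDef] = SNP_PANEL,
) -> StratifiedComparison:
    """Compare relative expression between genotype classes at one SNP.

    ``grouping="three-genotype"`` tests across the genotype classes present
    (Kruskal-Wallis; Mann-Whitney when only two are non-empty);
    ``grouping="carrier-vs-noncarrier"`` pools minor-allele carriers
    against major-allele homozygotes (Mann-Whitney).  Patients with a
    missing genotype are dropped with a warning.
    """
    if grouping not in (THREE_GENOTYPE, CARRIER):
        raise ValueError(f"unknown grouping {grouping!r}")
    snp = get_snp(snp_id, panel)
    by_id = {p.patient_id: p for p in patients}
    groups: dict[str, list[float]] = {}
    for res in results:
        patient = by_id.get(res.patient_id)
        label = _genotype_label(patient, snp) if patient else None
        if label is None:
            logger.warning(
                "%s: missing genotype at %s; dropped from stratification",
                res.patient_id, snp_id,
            )
            continue
        if grouping == CARRIER:
            hom_major = snp.major_allele * 2
            label = (
                hom_major if label == hom_major
                else f"{snp.minor_allele}-carrier"
            )
        groups.setdefault(label, []).append(res.rel_expr)
    labels = sorted(groups)
    values = [groups[k] for k in labels]
    if len(labels) < 2:
        raise InsufficientDataError(
            f"{snp_id}: need >= 2 non-empty genotype groups, got {len(labels)}"
        )
    if len(labels) == 2:
        test = mann_whitney_u(values[0], values[1])
        test_name = "mann-whitney"
    else:
        test = kruskal_wallis(values)
        test_name = "kruskal-wallis"
    return StratifiedComparison(
        snp_id, grouping, tuple(labels),
        tuple(len(v) for v in values),
        tuple(tuple(v) for v in values),
        test.statistic, test.p_value, test_name,
    )


class RelativeExpressionModel:
    """2^-dCt relative-expression model over a cohort's cDNA plate data.

    Parameters
    ----------
    ct
        All Ct measurements (only cDNA wells of the configured channels
        are used).
    patients
        Cohort metadata; required for genotype stratification.
    target_label, housekeeper_labels
        Channel labels of the target gene and reference genes.
    """

    def __init__(
        self,
        ct: Sequence[CtMeasurement],
        patients: Optional[Sequence[Patient]] = None,
        target_label: str = DEFAULT_TARGET,
        housekeeper_labels: Sequence[str] = DEFAULT_HOUSEKEEPERS,
        panel: Mapping[str, SnpDef] = SNP_PANEL,
    ) -> None:
        self.ct = list(ct)
        self.patients = list(patients) if patients is not None else None
        self.target_label = target_label
        self.housekeeper_labels = tuple(housekeeper_labels)
        self.panel = panel

    @classmethod
    def from_csv(
        cls, ct_path, patients_path=None, **kwargs
    ) -> "RelativeExpressionModel":
        from . import io

        ct = io.read_ct_table(ct_path)
        patients = (
            io.read_patient_table(patients_path) if patients_path else None
        )
        return cls(ct, patients, **kwargs)

    def fit(self) -> "RelativeExpressionResults":
        ids: list[str] = []
        for m in self.ct:
            if (
                m.template == "cDNA" and m.channel == self.target_label
                and m.patient_id not in ids
            ):
                ids.append(m.patient_id)
        results = []
        for pid in ids:
            try:
                results.append(relative_expression(
                    self.ct, pid, self.target_label, self.housekeeper_labels
                ))
            except InsufficientDataError as exc:
                logger.warning("skipping %s: %s", pid, exc)
        if not results:
            raise InsufficientDataError("no patient had usable wells")
        return RelativeExpressionResults(self, results)


@dataclass
class RelativeExpressionResults:
    """Fitted per-patient relative expression with stratification helpers."""

    model: RelativeExpressionModel
    results: list[ExpressionResult] = field(default_factory=list)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results])

    def stratify(
        self, snp_id: str, grouping: str = THREE_GENOTYPE
    ) -> StratifiedComparison:
        if self.model.patients is None:
            raise InsufficientDataError(
                "stratification requires patient metadata"
            )
        return stratify_by_genotype(
            self.results, self.model.patients, snp_id, grouping,
            self.model.panel,
        )

    def summary(self) -> str:
        df = self.frame
        lines = [
            "Relative expression (2^-dCt vs pooled housekeepers)",
            f"  target: {self.model.target_label}; housekeepers: "
            f"{', '.join(self.model.housekeeper_labels)}",
            f"  patients analysed: {len(df)}",
            f"  rel_expr range: {df.rel_expr.min():.4g} .. "
            f"{df.rel_expr.max():.4g} "
            f"({df.rel_expr.max() / df.rel_expr.min():.3g}-fold)",
        ]
        return "\n".join(lines)

    def plot(self, snp_id: str, grouping: str = THREE_GENOTYPE, ax=None):
        """Columnar scatter of rel_expr by genotype class at one SNP."""
        import matplotlib.pyplot as plt

        comp = self.stratify(snp_id, grouping)
        if ax is None:
            _, ax = plt.subplots()
        for i, (label, vals) in enumerate(
            zip(comp.group_labels, comp.group_values)
        ):
            x = np.full(len(vals), i, dtype=float)
            x += np.linspace(-0.15, 0.15, len(vals))
            ax.semilogy(x, vals, "o", label=f"{label} (n={len(vals)})")
            ax.hlines(np.mean(vals), i - 0.25, i + 0.25, color="k")
        ax.set_xticks(range(len(comp.group_labels)), comp.group_labels)
        ax.set_ylabel("relative expression (2^-dCt)")
        ax.set_title(
            f"{snp_id}: {comp.test_name} p = {comp.p_value:.3g}"
        )
        return ax
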