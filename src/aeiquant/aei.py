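"""Allelic expression imbalance (AEI) from dual-probe qPCR.

One allelic-discrimination well yields two Cts, one per allele-specific
probe (FAM and VIC).  The raw allelic ratio of a well is

    ratio = 2^-(FAM Ct) / 2^-(VIC Ct) = 2^(VIC Ct - FAM Ct)

Each sample's genomic DNA carries the two alleles 1:1, so the mean gDNA
ratio of that sample defines its 1:1 reference; dividing the mean cDNA
ratio by it yields the corrected allelic ratio, which cancels any
probe-specific offset (dye chemistry, probe efficiency intercepts).
A corrected ratio of 0.36 with the minor allele on FAM means only 0.36
minor-allele cDNA molecules per major-allele molecule.

Per-sample significance compares the raw cDNA well ratios against the raw
gDNA well ratios (two-sided Mann-Whitney, exact at five-plus-five
replicates); the cohort test compares per-patient mean cDNA ratios against
per-patient mean gDNA ratios.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .io import select_heterozygotes
from .stats import mann_whitney_u
from .types import SNP_PANEL, CtMeasurement, Patient, SnpDef

logger = logging.getLogger(__name__)

__all__ = [
    "well_ratio",
    "patient_aei",
    "cohort_aei",
    "AllelicRatioResult",
    "CohortAeiResult",
    "AllelicImbalanceModel",
    "AllelicImbalanceResults",
]


def well_ratio(fam_ct: Optional[float], vic_ct: Optional[float]) -> Optional[float]:
    """Raw allelic ratio of one well: 2^(VIC Ct - FAM Ct).

    Returns None when either Ct is undetermined; such wells are excluded
    upstream.
    """
    if fam_ct is None or vic_ct is None:
        return None
    return 2.0 ** (vic_ct - fam_ct)


def _mean(values: Sequence[float], log_scale: bool) -> float:
    if log_scale:
        return float(np.exp(np.mean(np.log(values))))
    return float(np.mean(values))


@dataclass(frozen=True)
class AllelicRatioResult:
    """Per-patient allelic ratios for one assay.

    ``corrected_ratio`` is the mean cDNA well ratio divided by the
    sample's mean gDNA well ratio; ``corrected_sem`` the standard error
    over the per-well corrected ratios; ``p_value`` the two-sided
    Mann-Whitney comparison of raw cDNA vs raw gDNA well ratios.
    """

    patient_id: str
    assay: str
    cdna_well_ratios: tuple[float, ...]
    gdna_well_ratios: tuple[float, ...]
    gdna_mean_ratio: float
    corrected_ratio: float
    corrected_sem: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass(frozen=True)
class CohortAeiResult:
    """Cohort-level AEI summary for one assay."""

    assay: str
    n_patients: int
    mean_corrected_ratio: float
    cohort_p_value: float
    per_patient: tuple[AllelicRatioResult, ...]


def _paired_ratios(
    ct: Sequence[CtMeasurement], patient_id: str, assay: str, template: str
) -> list[float]:
    by_rep: dict[int, dict[str, float]] = {}
    for m in ct:
        if (
            m.patient_id == patient_id and m.assay == assay
            and m.template == template and m.determined
            and m.channel in ("FAM", "VIC")
        ):
            by_rep.setdefault(m.replicate, {})[m.channel] = m.ct  # type: ignore[assignment]
    ratios = []
    for rep in sorted(by_rep):
        pair = by_rep[rep]
        r = well_ratio(pair.get("FAM"), pair.get("VIC"))
        if r is not None:
            ratios.append(r)
    return ratios


def patient_aei(
    ct: Sequence[CtMeasurement],
    patient_id: str,
    assay: str,
    min_replicates: int = 2,
    log_scale: bool = False,
) -> AllelicRatioResult:
    """Corrected allelic ratio and per-sample test for one patient/assay.

    FAM and VIC Cts sharing a replicate index form one well; wells with
    an undetermined channel are dropped.  Requires at least
    ``min_replicates`` usable wells per template.  ``log_scale`` switches
    both averaging steps to geometric means (sensitivity analysis).
    """
    cdna = _paired_ratios(ct, patient_id, assay, "cDNA")
    gdna = _paired_ratios(ct, patient_id, assay, "gDNA")
    for name, ratios in (("cDNA", cdna), ("gDNA", gdna)):
        if len(ratios) < min_replicates:
            raise InsufficientDataError(
                f"{patient_id}/{assay}: {len(ratios)} usable {name} wells, "
                f"need >= {min_replicates}"
            )
    gdna_mean = _mean(gdna, log_scale)
    corrected_wells = np.asarray(cdna) / gdna_mean
    corrected = _mean(cdna, log_scale) / gdna_mean
    sem = float(
        np.std(corrected_wells, ddof=1) / math.sqrt(len(corrected_wells))
    )
    test = mann_whitney_u(cdna, gdna)
    return AllelicRatioResult(
        patient_id, assay, tuple(cdna), tuple(gdna), gdna_mean,
        corrected, sem, test.p_value,
    )


def cohort_aei(
    per_patient: Sequence[AllelicRatioResult], log_scale: bool = False
) -> CohortAeiResult:
    """Cohort-level AEI: mean corrected ratio across patients and the
    two-sided Mann-Whitney test of per-patient mean cDNA ratios against
    per-patient mean gDNA ratios."""
    if len(per_patient) < 2:
        raise InsufficientDataError(
            f"cohort test needs >= 2 patients, got {len(per_patient)}"
        )
    assays = {r.assay for r in per_patient}
    if len(assays) != 1:
        raise ValueError(f"mixed assays in cohort: {sorted(assays)}")
    cdna_means = [_mean(r.cdna_well_ratios, log_scale) for r in per_patient]
    gdna_means = [_mean(r.gdna_well_ratios, log_scale) for r in per_patient]
    mean_corrected = _mean([r.corrected_ratio for r in per_patient], log_scale)
    test = mann_whitney_u(cdna_means, gdna_means)
    return CohortAeiResult(
        per_patient[0].assay, len(per_patient), mean_corrected,
        test.p_value, tuple(per_patient),
    )


class AllelicImbalanceModel:
    """AEI model for one allelic-discrimination assay over a cohort.

    Parameters
    ----------
    ct
        All Ct measurements; only FAM/VIC wells of ``assay`` are used.
    patients, snp_id
        When given, analysis is restricted to heterozygotes at ``snp_id``
        (only they are informative); otherwise every patient with wells
        for the assay is analysed.
    min_replicates
        Minimum usable wells per template per patient.
    log_scale
        Use geometric instead of arithmetic means throughout.
    """

    def __init__(
        self,
        ct: Sequence[CtMeasurement],
        patients: Optional[Sequence[Patient]] = None,
        assay: str = "rs1676486",
        snp_id: Optional[str] = None,
        min_replicates: int = 2,
        log_scale: bool = False,
        panel: Mapping[str, SnpDef] = SNP_PANEL,
    ) -> None:
        self.ct = list(ct)
        self.patients = list(patients) if patients is not None else None
        self.assay = assay
        self.snp_id = snp_id or (assay if assay in panel else None)
        self.min_replicates = min_replicates
        self.log_scale = log_scale
        self.panel = panel

    @classmethod
    def from_csv(cls, ct_path, patients_path=None, **kwargs):
        from . import io

        ct = io.read_ct_table(ct_path)
        patients = (
            io.read_patient_table(patients_path) if patients_path else None
        )
        return cls(ct, patients, **kwargs)

    def _informative_ids(self) -> list[str]:
        if self.patients is not None and self.snp_id is not None:
            hets = select_heterozygotes(self.patients, self.snp_id, self.panel)
            return [p.patient_id for p in hets]
        ids: list[str] = []
        for m in self.ct:
            if m.assay == self.assay and m.patient_id not in ids:
                ids.append(m.patient_id)
        return ids

    def fit(self) -> "AllelicImbalanceResults":
        results: list[AllelicRatioResult] = []
        for pid in self._informative_ids():
            try:
                results.append(patient_aei(
                    self.ct, pid, self.assay, self.min_replicates,
                    self.log_scale,
                ))
            except InsufficientDataError as exc:
                logger.warning("skipping %s: %s", pid, exc)
        if not results:
            raise InsufficientDataError(
                f"no informative patient with usable {self.assay} wells"
            )
        cohort = (
            cohort_aei(results, self.log_scale) if len(results) >= 2 else None
        )
        return AllelicImbalanceResults(self, results, cohort)


@dataclass
class AllelicImbalanceResults:
    """Fitted per-patient and cohort AEI results for one assay."""

    model: AllelicImbalanceModel
    per_patient: list[AllelicRatioResult] = field(default_factory=list)
    cohort: Optional[CohortAeiResult] = None

    @property
    def frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": r.patient_id,
                "assay": r.assay,
                "n_cdna_wells": len(r.cdna_well_ratios),
                "n_gdna_wells": len(r.gdna_well_ratios),
                "gdna_mean_ratio": r.gdna_mean_ratio,
                "corrected_ratio": r.corrected_ratio,
                "corrected_sem": r.corrected_sem,
                "p_value": r.p_value,
                "significant": r.significant,
            }
            for r in self.per_patient
        ]
        return pd.DataFrame(rows)

    @property
    def n_significant(self) -> int:
        return sum(r.significant for r in self.per_patient)

    def summary(self) -> str:
        lines = [
            f"Allelic expression imbalance - assay {self.model.assay}",
            f"  heterozygous patients analysed: {len(self.per_patient)}",
            f"  per-sample tests significant at 0.05: "
            f"{self.n_significant}/{len(self.per_patient)}",
        ]
        if self.cohort is not None:
            lines += [
                f"  mean corrected allelic ratio: "
                f"{self.cohort.mean_corrected_ratio:.3f}",
                f"  cohort Mann-Whitney p: {self.cohort.cohort_p_value:.3g}",
            ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Per-patient corrected ratios with SEM bars, gDNA reference at 1."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = np.arange(len(self.per_patient))
        ys = [r.corrected_ratio for r in self.per_patient]
        es = [r.corrected_sem for r in self.per_patient]
        ax.errorbar(xs, ys, yerr=es, fmt="o", capsize=3)
        ax.axhline(1.0, color="grey", ls="--", lw=1)
        ax.set_xticks(xs, [r.patient_id for r in self.per_patient],
                      rotation=90)
        ax.set_ylabel("corrected allelic ratio")
        ax.set_title(f"AEI at {self.model.assay}")
        return ax
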