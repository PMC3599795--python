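"""Readers and writers for the tabular pipeline formats.

All files are comma-separated UTF-8 with a mandatory header row and "."
decimals; floats are written at 6 significant digits.  Undetermined Ct
wells round-trip as the literal ``Undetermined``.
"""
from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import FormatError
from .types import (
    SNP_PANEL,
    CtMeasurement,
    Patient,
    SnpDef,
    get_snp,
    normalise_genotype,
)

logger = logging.getLogger(__name__)

PATIENT_COLUMNS = ("patient_id", "sex", "age", "joint")
CT_COLUMNS = ("patient_id", "template", "assay", "channel", "replicate", "ct")


def _fmt(x: Optional[float]) -> str:
    return "" if x is None else f"{x:.6g}"


def _geno_columns(panel: Mapping[str, SnpDef]) -> list[str]:
    return [f"geno_{snp}" for snp in panel]


def read_patient_table(
    path: str | Path, panel: Mapping[str, SnpDef] = SNP_PANEL
) -> list[Patient]:
    """Read patients.csv.

    Genotype columns are named ``geno_<snp_id>``; a genotype cell is the
    two allele letters in either order (e.g. ``CT``), empty for missing.
    A cell whose alleles are not in the SNP's declared allele set is
    recorded as missing with a logged warning.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        required = list(PATIENT_COLUMNS) + _geno_columns(panel)
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        patients: list[Patient] = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=2):
            pid = row["patient_id"]
            if not pid:
                raise FormatError(f"{path}:{i}: empty patient_id")
            if pid in seen:
                raise FormatError(f"{path}:{i}: duplicate patient_id {pid!r}")
            seen.add(pid)
            age = float(row["age"]) if row.get("age") else None
            genotypes = {}
            for snp_id, snp in panel.items():
                cell = (row.get(f"geno_{snp_id}") or "").strip()
                if not cell:
                    genotypes[snp_id] = None
                    continue
                alleles = tuple(cell.replace("/", ""))
                if len(alleles) != 2:
                    logger.warning(
                        "%s:%d: unparseable genotype %r at %s; recorded "
                        "as missing", path, i, cell, snp_id,
                    )
                    genotypes[snp_id] = None
                    continue
                if not set(alleles) <= snp.alleles:
                    raise FormatError(
                        f"{path}:{i}: genotype {cell!r} invalid for "
                        f"{snp_id} (alleles {sorted(snp.alleles)})"
                    )
                genotypes[snp_id] = normalise_genotype(alleles)  # type: ignore[arg-type]
            patients.append(Patient(
                pid, row.get("sex") or "unknown", age,
                row.get("joint") or "unknown", genotypes,
            ))
    return patients


def write_patient_table(
    patients: Sequence[Patient],
    path: str | Path,
    panel: Mapping[str, SnpDef] = SNP_PANEL,
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(PATIENT_COLUMNS) + _geno_columns(panel))
        for p in patients:
            genos = [
                "".join(p.genotypes.get(snp) or ()) for snp in panel
            ]
            writer.writerow(
                [p.patient_id, p.sex, _fmt(p.age), p.joint] + genos
            )


def read_ct_table(path: str | Path) -> list[CtMeasurement]:
    """Read ct.csv; ``Undetermined`` or empty Ct cells become undetermined
    wells.  Duplicate (patient, template, assay, channel, replicate)
    tuples are a format error."""
    path = Path(path)
    out: list[CtMeasurement] = []
    seen: set[tuple] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CT_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        for i, row in enumerate(reader, start=2):
            raw_ct = (row["ct"] or "").strip()
            if raw_ct == "" or raw_ct.lower() == "undetermined":
                ct: Optional[float] = None
            else:
                try:
                    ct = float(raw_ct)
                except ValueError:
                    raise FormatError(f"{path}:{i}: unparseable ct {raw_ct!r}")
            try:
                m = CtMeasurement(
                    row["patient_id"], row["template"], row["assay"],
                    row["channel"], int(row["replicate"]), ct,
                )
            except (FormatError, ValueError) as exc:
                raise FormatError(f"{path}:{i}: {exc}") from None
            if m.key in seen:
                raise FormatError(f"{path}:{i}: duplicate well {m.key}")
            seen.add(m.key)
            out.append(m)
    return out


def write_ct_table(
    measurements: Iterable[CtMeasurement], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CT_COLUMNS)
        for m in measurements:
            writer.writerow([
                m.patient_id, m.template, m.assay, m.channel, m.replicate,
                "Undetermined" if m.ct is None else _fmt(m.ct),
            ])


def write_truth_table(truth, path: str | Path) -> None:
    """Write the simulator's per-patient truth records (test use only)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["patient_id", "log2_expression", "haplotype_1", "haplotype_2",
             "assay_ratios"]
        )
        for rec in truth.values():
            h1, h2 = rec.haplotypes
            ratios = ";".join(
                f"{k}={v:.6g}" for k, v in sorted(rec.assay_ratios.items())
            )
            writer.writerow([
                rec.patient_id, _fmt(rec.log2_expression),
                "".join(h1), "".join(h2), ratios,
            ])


def select_heterozygotes(
    patients: Sequence[Patient],
    snp_id: str,
    panel: Mapping[str, SnpDef] = SNP_PANEL,
) -> list[Patient]:
    """Pure filter: exactly the patients with two distinct alleles at
    ``snp_id``, original order preserved."""
    get_snp(snp_id, panel)  # raises UnknownSnpError
    return [p for p in patients if p.is_heterozygous(snp_id)]
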