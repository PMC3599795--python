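"""Core domain types: SNP definitions, patients, and Ct measurements.

The atomic observation of the whole pipeline is a single well/channel
cycle-threshold (Ct) reading.  Patients carry unphased genotypes at the
SNPs of the panel; genotypes are unordered allele pairs because RFLP
calls carry no phase.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import FormatError, UnknownSnpError

#: An unordered, unphased genotype: a sorted pair of allele symbols,
#: or None when the call is missing.
Genotype = Optional[tuple[str, str]]

TEMPLATES = ("cDNA", "gDNA")


@dataclass(frozen=True)
class SnpDef:
    """Definition of a biallelic SNP: identity, alleles and minor-allele
    frequency (MAF)."""

    snp_id: str
    major_allele: str
    minor_allele: str
    maf: float

    def __post_init__(self) -> None:
        if self.major_allele == self.minor_allele:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: MAF must be in [0, 0.5]")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.major_allele, self.minor_allele))


#: The three COL11A1 SNPs of the study: the OA-associated intronic SNP,
#: the LDH-associated coding SNP, and the 3'UTR SNP used as a second
#: transcript marker.  Alleles listed major/minor.
SNP_PANEL: Mapping[str, SnpDef] = {
    "rs2615977": SnpDef("rs2615977", "T", "G", 0.239),
    "rs1676486": SnpDef("rs1676486", "C", "T", 0.202),
    "rs9659030": SnpDef("rs9659030", "A", "G", 0.173),
}


def normalise_genotype(alleles: tuple[str, str]) -> Genotype:
    """Canonical unordered representation of an allele pair."""
    a, b = alleles
    return (a, b) if a <= b else (b, a)


def get_snp(snp_id: str, panel: Mapping[str, SnpDef] = SNP_PANEL) -> SnpDef:
    try:
        return panel[snp_id]
    except KeyError:
        raise UnknownSnpError(snp_id) from None


@dataclass
class Patient:
    """Patient metadata plus unphased genotypes at the panel SNPs."""

    patient_id: str
    sex: str = "unknown"  # {F, M, unknown}
    age: Optional[float] = None
    joint: str = "knee"  # {hip, knee}
    genotypes: dict[str, Genotype] = field(default_factory=dict)

    def genotype(self, snp_id: str) -> Genotype:
        return self.genotypes.get(snp_id)

    def is_heterozygous(self, snp_id: str) -> bool:
        g = self.genotypes.get(snp_id)
        return g is not None and g[0] != g[1]


@dataclass(frozen=True)
class CtMeasurement:
    """One well/channel Ct reading.

    ``ct`` is None when the instrument reported the well as undetermined;
    such wells are excluded from every downstream mean and test.
    """

    patient_id: str
    template: str  # {cDNA, gDNA}
    assay: str
    channel: str  # FAM / VIC / gene label
    replicate: int
    ct: Optional[float]

    def __post_init__(self) -> None:
        if self.template not in TEMPLATES:
            raise FormatError(
                f"template must be one of {TEMPLATES}, got {self.template!r}"
            )
        if self.replicate < 1:
            raise FormatError("replicate index must be >= 1")
        if self.ct is not None and not 0.0 < self.ct < 50.0:
            raise FormatError(f"determined Ct must lie in (0, 50), got {self.ct}")

    @property
    def key(self) -> tuple[str, str, str, str, int]:
        """Uniqueness key: one reading per (patient, template, assay,
        channel, replicate)."""
        return (self.patient_id, self.template, self.assay, self.channel,
                self.replicate)

    @property
    def determined(self) -> bool:
        return self.ct is not None
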