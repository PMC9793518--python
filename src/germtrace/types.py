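"""Shared domain types for dosage panels, segments, cohorts and HLA typings.

Coordinate conventions: variants are 1-based (VCF), copy-number segments are
0-based half-open (BED). A variant at position ``p`` lies inside segment
``[start, end)`` iff ``start <= p - 1 < end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

VALID_BASES = frozenset("ACGT")

#: HLA genes handled by the pipeline, keyed by class.
HLA_CLASS_I = ("A", "B", "C")
HLA_CLASS_II = ("DRB1", "DQB1")
HLA_GENES = HLA_CLASS_I + HLA_CLASS_II


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so mixed-build inputs compare equal."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a biallelic SNP (1-based position, single-base alleles)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(
                f"alleles must be single bases in ACGT: {self.ref}/{self.alt}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref}) at {self.chrom}:{self.pos}")

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class DosageRecord:
    """One imputed SNP: MAF, imputation-quality score and per-sample dosages."""

    key: VariantKey
    maf: float
    quality: float
    dosages: np.ndarray
    rsid: Optional[str] = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"MAF out of [0, 0.5] at {self.key}: {self.maf}")
        if not 0.0 <= self.quality <= 1.0:
            raise ValueError(f"quality out of [0, 1] at {self.key}: {self.quality}")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError(f"dosage out of [0, 2] at {self.key}")


class DosagePanel:
    """Ordered collection of :class:`DosageRecord` over a fixed sample list."""

    def __init__(self, samples: list[str], records: list[DosageRecord]):
        self.samples = list(samples)
        self.records = list(records)
        for rec in self.records:
            if rec.dosages.shape != (len(self.samples),):
                raise ValueError(
                    f"record {rec.key} has {rec.dosages.shape} dosages for "
                    f"{len(self.samples)} samples"
                )

    @property
    def n_variants(self) -> int:
        return len(self.records)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def keys(self) -> list[VariantKey]:
        return [rec.key for rec in self.records]

    def key_index(self) -> dict[VariantKey, int]:
        return {rec.key: i for i, rec in enumerate(self.records)}

    def dosage_matrix(self) -> np.ndarray:
        """(n_variants, n_samples) dosage array."""
        if not self.records:
            return np.empty((0, len(self.samples)))
        return np.vstack([rec.dosages for rec in self.records])

    def maf(self) -> np.ndarray:
        return np.array([rec.maf for rec in self.records])

    def quality(self) -> np.ndarray:
        return np.array([rec.quality for rec in self.records])

    def sample_column(self, sample_id: str) -> np.ndarray:
        j = self.samples.index(sample_id)
        return self.dosage_matrix()[:, j]


@dataclass(frozen=True)
class SegmentRecord:
    """Copy-number segment on BED-style 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"segment end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos_1based: int) -> bool:
        return self.start <= pos_1based - 1 < self.end


#: Decade bands used for the ordinal age covariate.
AGE_BANDS = ("31-40", "41-50", "51-60", "61-70", "71-80", "81-90")


def age_band_midpoint(band: str) -> float:
    lo, hi = band.split("-")
    return (float(lo) + float(hi)) / 2.0


@dataclass
class CohortRecord:
    """One patient: outcome indicator, follow-up time and covariates."""

    patient_id: str
    event: bool
    time: float  # days to event or last follow-up
    grade: Optional[int] = None
    size_cm: Optional[float] = None
    age_group: Optional[str] = None
    european_ancestry: Optional[bool] = None
    prs_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"time must be > 0 for {self.patient_id}")
        if self.grade is not None and self.grade not in (1, 2, 3):
            raise ValueError(f"grade must be in 1..3 for {self.patient_id}: {self.grade}")


def hla_gene_class(gene: str) -> str:
    """``I`` for A/B/C, ``II`` for DRB1/DQB1."""
    if gene in HLA_CLASS_I:
        return "I"
    if gene in HLA_CLASS_II:
        return "II"
    raise ValueError(f"unknown HLA gene: {gene}")


@dataclass
class HLARecord:
    """Per-sample, per-gene unordered allele pair with optional posterior."""

    sample_id: str
    gene: str
    allele1: str
    allele2: str
    posterior: Optional[float] = None

    def __post_init__(self) -> None:
        hla_gene_class(self.gene)  # validates gene
        if self.posterior is not None and not 0.0 <= self.posterior <= 1.0:
            raise ValueError(
                f"posterior out of [0,1] for {self.sample_id}/{self.gene}: {self.posterior}"
            )


@dataclass(frozen=True)
class PRSSite:
    """One scoring-file row: variant identity, effect allele and weight."""

    effect_allele: str
    beta: float
    other_allele: Optional[str] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None
    rsid: Optional[str] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ValueError(f"non-finite effect weight for site {self.identity()}")
        if self.chrom is None and self.rsid is None:
            raise ValueError("site needs coordinates or an rsID")

    def identity(self) -> str:
        if self.chrom is not None and self.pos is not None:
            return f"{self.chrom}:{self.pos}"
        return self.rsid or "?"


@dataclass
class PRSModel:
    """A polygenic score: an identifier plus its effect-weight sites."""

    model_id: str
    sites: list[PRSSite]

    @property
    def n_sites(self) -> int:
        return len(self.sites)
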