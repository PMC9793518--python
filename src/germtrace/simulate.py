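"""Synthetic inputs with the statistical structure the analyses assume.

Generates HWE genotypes over a truncated-Beta MAF spectrum, paired noisy
dosage panels whose error grows with rarity, low coverage and copy-number
loss, toy copy-number profiles, HLA truth/call pairs with class-dependent
error, and proportional-hazards survival cohorts. Everything is reproducible
under a fixed seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np

from .types import (
    AGE_BANDS,
    CohortRecord,
    DosagePanel,
    DosageRecord,
    HLARecord,
    SegmentRecord,
    VariantKey,
    age_band_midpoint,
)

#: Default toy genome: 2 chromosomes x 5 Mb, desk-scale runtime.
DEFAULT_GENOME: dict[str, int] = {"1": 5_000_000, "2": 5_000_000}

_BASES = np.array(list("ACGT"))


@dataclass
class DosageSimConfig:
    """Knobs for the dosage-panel generator.

    ``error_scale`` multiplies a noise SD that decreases with MAF, decreases
    with coverage and doubles in copy-loss regions; these are free knobs, not
    calibrated claims.
    """

    n_variants: int = 1000
    n_samples: int = 4
    maf_beta_a: float = 0.4
    maf_beta_b: float = 1.2
    maf_min: float = 0.0005
    maf_max: float = 0.5
    coverage_per_sample: float = 0.7
    blood_coverage: float = 1.0
    error_scale: float = 0.1
    quality_decay: float = 2.0
    cn_profile: Optional[dict[str, list[SegmentRecord]]] = None
    genome: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.coverage_per_sample <= 0 or self.blood_coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.error_scale < 0:
            raise ValueError("error_scale must be >= 0")
        if not (0 <= self.maf_min <= self.maf_max <= 0.5):
            raise ValueError("MAF bounds must satisfy 0 <= min <= max <= 0.5")


@dataclass
class TruthTable:
    """Ground-truth genotypes: integer {0,1,2} counts of the alt allele."""

    samples: list[str]
    keys: list[VariantKey]
    maf: np.ndarray
    genotypes: np.ndarray  # (n_variants, n_samples)


def _draw_maf(rng: np.random.Generator, cfg: DosageSimConfig, n: int) -> np.ndarray:
    """Rejection-sample a Beta(a,b) spectrum truncated to [maf_min, maf_max]."""
    if cfg.maf_min == cfg.maf_max:  # degenerate spectrum: fixed MAF
        return np.full(n, cfg.maf_min)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.beta(cfg.maf_beta_a, cfg.maf_beta_b, size=2 * (n - filled)) * 0.5
        keep = draw[(draw >= cfg.maf_min) & (draw <= cfg.maf_max)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def simulate_true_genotypes(cfg: DosageSimConfig) -> TruthTable:
    """Draw MAFs from the spectrum and genotypes under Hardy-Weinberg.

    Genotype probabilities are (1-q)^2, 2q(1-q), q^2 with q the alt-allele
    frequency (the MAF; the alt allele is taken as the minor allele).
    """
    rng = np.random.default_rng(cfg.seed)
    maf = _draw_maf(rng, cfg, cfg.n_variants)

    chroms = list(cfg.genome)
    lengths = np.array([cfg.genome[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=cfg.n_variants, p=lengths / lengths.sum())
    pos = (rng.random(cfg.n_variants) * lengths[chrom_idx]).astype(int) + 1

    ref_idx = rng.integers(0, 4, size=cfg.n_variants)
    alt_shift = rng.integers(1, 4, size=cfg.n_variants)
    alt_idx = (ref_idx + alt_shift) % 4

    order = np.lexsort((pos, chrom_idx))
    keys: list[VariantKey] = []
    seen: set[tuple[int, int]] = set()
    for i in order:
        # nudge duplicated positions to keep keys unique
        p = int(pos[i])
        while (int(chrom_idx[i]), p) in seen:
            p += 1
        seen.add((int(chrom_idx[i]), p))
        pos[i] = p
        keys.append(
            VariantKey(chroms[chrom_idx[i]], p, str(_BASES[ref_idx[i]]), str(_BASES[alt_idx[i]]))
        )
    maf = maf[order]

    q = maf[:, None]
    u = rng.random((cfg.n_variants, len(range(cfg.n_samples))))
    p_hom_ref = (1 - q) ** 2
    p_het = 2 * q * (1 - q)
    genotypes = np.where(u < p_hom_ref, 0, np.where(u < p_hom_ref + p_het, 1, 2))

    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]
    return TruthTable(samples=samples, keys=keys, maf=maf, genotypes=genotypes.astype(int))


def _maf_error_factor(maf: np.ndarray) -> np.ndarray:
    # decreasing in MAF, equals 1 at MAF = 0.5
    return np.sqrt((0.05 + 0.5) / (0.05 + maf))


def _coverage_error_factor(coverage: float) -> float:
    # decreasing in coverage, equals 1 at 1x
    return float(1.0 / np.sqrt(coverage))


_CN_LOSS_FACTOR = 2.0


def _cn_state_factor(segments: list[SegmentRecord], keys: list[VariantKey]) -> np.ndarray:
    """Per-variant noise multiplier: loss segments inflate error, others do not."""
    factor = np.ones(len(keys))
    loss = [s for s in segments if s.log2_ratio < -0.3]
    for i, key in enumerate(keys):
        for seg in loss:
            if seg.chrom == key.chrom and seg.contains(key.pos):
                factor[i] = _CN_LOSS_FACTOR
                break
    return factor


def simulate_imputed_dosages(
    truth: TruthTable, cfg: DosageSimConfig
) -> tuple[DosagePanel, DosagePanel]:
    """Corrupt the truth into paired (blood-like, tissue-like) dosage panels.

    Noise is Gaussian on the dosage scale with per-variant SD
    ``error_scale * f(maf) * g(coverage) * h(cn_state)`` and clipping to
    [0, 2]; the per-variant quality score decays with the realized mean
    absolute noise, so it is 1 when ``error_scale`` is 0.
    """
    if cfg.cn_profile:
        for sample_id, segs in cfg.cn_profile.items():
            for seg in segs:
                if seg.chrom not in cfg.genome:
                    raise ValueError(
                        f"cn_profile for {sample_id} references chromosome "
                        f"{seg.chrom} absent from the genome"
                    )
    rng = np.random.default_rng(cfg.seed + 1)
    n_var, n_smp = truth.genotypes.shape
    f_maf = _maf_error_factor(truth.maf)

    panels = []
    for kind, coverage in (("blood", cfg.blood_coverage), ("tissue", cfg.coverage_per_sample)):
        g_cov = _coverage_error_factor(coverage)
        sd = cfg.error_scale * f_maf[:, None] * g_cov * np.ones((n_var, n_smp))
        if kind == "tissue" and cfg.cn_profile:
            for j, sample_id in enumerate(truth.samples):
                segs = cfg.cn_profile.get(sample_id)
                if segs:
                    sd[:, j] *= _cn_state_factor(segs, truth.keys)
        noise = rng.standard_normal((n_var, n_smp)) * sd
        dosages = np.clip(truth.genotypes + noise, 0.0, 2.0)
        realized = np.abs(dosages - truth.genotypes).mean(axis=1)
        quality = np.exp(-cfg.quality_decay * realized)
        records = [
            DosageRecord(
                key=truth.keys[i],
                maf=float(truth.maf[i]),
                quality=float(quality[i]),
                dosages=dosages[i],
            )
            for i in range(n_var)
        ]
        panels.append(DosagePanel(truth.samples, records))
    return panels[0], panels[1]


GAIN_LOG2 = 0.58
LOSS_LOG2 = -1.0


def simulate_cn_profile(
    fraction_gain: float,
    fraction_loss: float,
    seed: int = 0,
    genome: Optional[dict[str, int]] = None,
) -> list[SegmentRecord]:
    """Tile a toy genome with non-overlapping gain/loss/neutral segments.

    The realized altered fraction matches the request to within one
    percentage point (exact up to 1-bp rounding). Segment placement is
    randomized by seed.
    """
    if fraction_gain < 0 or fraction_loss < 0:
        raise ValueError("fractions must be >= 0")
    if fraction_gain + fraction_loss > 1:
        raise ValueError("fraction_gain + fraction_loss must be <= 1")
    genome = dict(genome or DEFAULT_GENOME)
    rng = np.random.default_rng(seed)
    total = sum(genome.values())
    gain_bp = int(round(fraction_gain * total))
    loss_bp = int(round(fraction_loss * total))
    altered = gain_bp + loss_bp
    offset = int(rng.integers(0, total - altered + 1)) if altered < total else 0

    # altered block [offset, offset+gain_bp) gains, then losses, on the
    # concatenated genome; split back into per-chromosome segments.
    segments: list[SegmentRecord] = []
    cursor = 0
    for chrom, length in genome.items():
        lo, hi = cursor, cursor + length

        def clip(a: int, b: int) -> tuple[int, int]:
            return max(a, lo) - cursor, min(b, hi) - cursor

        boundaries = sorted(
            {0, length, *(x - cursor for x in (offset, offset + gain_bp, offset + gain_bp + loss_bp) if lo < x < hi)}
        )
        for a, b in zip(boundaries, boundaries[1:]):
            mid = cursor + (a + b) // 2
            if offset <= mid < offset + gain_bp:
                ratio = GAIN_LOG2
            elif offset + gain_bp <= mid < offset + altered:
                ratio = LOSS_LOG2
            else:
                ratio = 0.0
            segments.append(SegmentRecord(chrom=chrom, start=a, end=b, log2_ratio=ratio))
        cursor = hi
    return segments


def _load_hla_frequencies() -> dict[str, tuple[list[str], np.ndarray]]:
    table: dict[str, tuple[list[str], list[float]]] = {}
    with resources.files("germtrace.data").joinpath("hla_allele_freqs.tsv").open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            table.setdefault(row["gene"], ([], []))
            table[row["gene"]][0].append(row["allele"])
            table[row["gene"]][1].append(float(row["freq"]))
    out = {}
    for gene, (alleles, freqs) in table.items():
        p = np.asarray(freqs)
        out[gene] = (alleles, p / p.sum())
    return out


def simulate_hla_truth_and_calls(
    n_samples: int,
    class1_error: float = 0.05,
    class2_error: float = 0.15,
    seed: int = 0,
) -> tuple[list[HLARecord], list[HLARecord]]:
    """Draw gold HLA allele pairs and imputed calls with class-dependent error.

    Each imputed allele is independently replaced by a different allele of
    the same gene with its class error rate; corrupted calls receive lower
    posteriors on average than correct calls.
    """
    if not 0 <= class1_error <= 1 or not 0 <= class2_error <= 1:
        raise ValueError("error rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    freqs = _load_hla_frequencies()
    gold: list[HLARecord] = []
    called: list[HLARecord] = []
    for i in range(n_samples):
        sample_id = f"H{i:03d}"
        for gene, (alleles, p) in freqs.items():
            err = class1_error if gene in ("A", "B", "C") else class2_error
            pair = [alleles[k] for k in rng.choice(len(alleles), size=2, p=p)]
            gold.append(HLARecord(sample_id, gene, pair[0], pair[1]))
            imputed = []
            any_error = False
            for allele in pair:
                if rng.random() < err:
                    any_error = True
                    others = [a for a in alleles if a != allele]
                    imputed.append(others[int(rng.integers(len(others)))])
                else:
                    imputed.append(allele)
            mu = 0.60 if any_error else 0.93
            posterior = float(np.clip(rng.normal(mu, 0.08), 0.0, 1.0))
            called.append(HLARecord(sample_id, gene, imputed[0], imputed[1], posterior))
    return gold, called


@dataclass
class CohortSimConfig:
    """Knobs for the proportional-hazards cohort generator."""

    n_patients: int = 200
    true_log_hr_per_sd: float = 0.0
    baseline_rate: float = 0.03  # events per year at covariate reference
    covariate_effects: dict[str, float] = field(default_factory=dict)
    censor_time_years: float = 12.0
    control_fraction: Optional[float] = None  # case-control subsampling of non-events
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.n_patients < 10:
            raise ValueError("n_patients must be >= 10")
        if self.control_fraction is not None and not 0 < self.control_fraction <= 1:
            raise ValueError("control_fraction must be in (0, 1]")


def simulate_cohort(cfg: CohortSimConfig) -> list[CohortRecord]:
    """Simulate a survival cohort with a standard-normal PRS hazard effect.

    Event times are exponential with rate
    ``baseline_rate * exp(log_hr * PRS + covariate terms)``; administrative
    censoring at ``censor_time_years``. Optional case-control subsampling
    keeps every event and a stated fraction of non-events.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    prs = rng.standard_normal(n)
    grade = rng.choice([1, 2, 3], size=n, p=[0.35, 0.45, 0.20])
    size_cm = np.round(np.clip(rng.lognormal(np.log(0.9), 0.5, size=n), 0.1, 5.0), 1)
    age_band = rng.choice(len(AGE_BANDS), size=n, p=[0.05, 0.25, 0.30, 0.22, 0.13, 0.05])
    european = rng.random(n) < 0.88

    eff = cfg.covariate_effects
    lp = cfg.true_log_hr_per_sd * prs
    lp = lp + eff.get("grade", 0.0) * (grade - 2)
    lp = lp + eff.get("size_cm", 0.0) * (size_cm - 1.0)
    mids = np.array([age_band_midpoint(b) for b in AGE_BANDS])
    lp = lp + eff.get("age", 0.0) * (mids[age_band] - 55.0) / 10.0
    lp = lp + eff.get("european", 0.0) * european.astype(float)

    rate = cfg.baseline_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    event = t_event <= cfg.censor_time_years
    t_obs_years = np.minimum(t_event, cfg.censor_time_years)
    days = np.maximum(1.0, np.round(t_obs_years * 365.25))

    records = [
        CohortRecord(
            patient_id=f"P{i:04d}",
            event=bool(event[i]),
            time=float(days[i]),
            grade=int(grade[i]),
            size_cm=float(size_cm[i]),
            age_group=AGE_BANDS[age_band[i]],
            european_ancestry=bool(european[i]),
            prs_values={"PRS": float(prs[i])},
        )
        for i in range(n)
    ]

    if cfg.control_fraction is not None:
        controls = [r for r in records if not r.event]
        keep_n = int(round(cfg.control_fraction * len(controls)))
        keep_idx = set(rng.choice(len(controls), size=keep_n, replace=False))
        kept_controls = [r for k, r in enumerate(controls) if k in keep_idx]
        records = [r for r in records if r.event] + kept_controls
    return records
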