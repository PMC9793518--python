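"""Polygenic risk scores from dosage panels and effect-weight models.

The score for a sample is the sum over matched sites of the effect weight
times the effect-allele dosage; missing sites are skipped (no mean
imputation) and counted in the coverage report. Scores are normalized by
z-scoring within the analysis cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import DosagePanel, DosageRecord, PRSModel, PRSSite

logger = logging.getLogger("germtrace")

HIGH_QUALITY_THRESHOLD = 0.80

#: Strand-ambiguous allele pairs, excluded when only rsID matching is possible.
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class PRSResult:
    """Per-sample score for one model, with site-coverage counters."""

    sample_id: str
    model_id: str
    raw: float
    z: Optional[float]
    n_sites_total: int
    n_sites_used: int
    n_sites_high_quality: int


def match_effect_allele(record: DosageRecord, site: PRSSite) -> Optional[np.ndarray]:
    """Orient a dosage record so it counts the site's effect allele.

    Returns the per-sample effect-allele dosage, or None when the effect
    allele matches neither panel allele (the site is excluded, not an error).
    """
    if site.effect_allele == record.key.alt:
        return record.dosages
    if site.effect_allele == record.key.ref:
        return 2.0 - record.dosages
    return None


def _lookup(panel_index: dict, rsid_index: dict, site: PRSSite) -> Optional[DosageRecord]:
    if site.chrom is not None and site.pos is not None:
        rec = panel_index.get((site.chrom, site.pos))
        return rec
    if site.rsid is not None:
        rec = rsid_index.get(site.rsid)
        if rec is None:
            return None
        # without coordinates, strand-ambiguous sites cannot be oriented safely
        if (rec.key.ref, rec.key.alt) in _AMBIGUOUS_PAIRS:
            logger.info("excluding strand-ambiguous rsID-matched site %s", site.rsid)
            return None
        return rec
    return None


def compute_prs(panel: DosagePanel, model: PRSModel) -> list[PRSResult]:
    """Evaluate one model over every sample in the panel.

    Raises when zero sites match; z-scores are filled by :func:`zscore`
    (left None here).
    """
    panel_index = {(rec.key.chrom, rec.key.pos): rec for rec in panel.records}
    rsid_index = {rec.rsid: rec for rec in panel.records if rec.rsid is not None}
    raw = np.zeros(panel.n_samples)
    n_used = 0
    n_hq = 0
    for site in model.sites:
        rec = _lookup(panel_index, rsid_index, site)
        if rec is None:
            continue
        x = match_effect_allele(rec, site)
        if x is None:
            continue
        raw += site.beta * x
        n_used += 1
        if rec.quality > HIGH_QUALITY_THRESHOLD:
            n_hq += 1
    if n_used == 0:
        raise ValueError(f"model {model.model_id}: no sites matched the panel")
    return [
        PRSResult(
            sample_id=sample,
            model_id=model.model_id,
            raw=float(raw[j]),
            z=None,
            n_sites_total=model.n_sites,
            n_sites_used=n_used,
            n_sites_high_quality=n_hq,
        )
        for j, sample in enumerate(panel.samples)
    ]


def zscore(results: Sequence[PRSResult]) -> list[PRSResult]:
    """Normalize raw scores to cohort mean 0, sample SD 1 (ddof=1)."""
    raws = np.array([r.raw for r in results], dtype=float)
    if raws.size < 2:
        raise ValueError("need >= 2 samples to z-score")
    sd = raws.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in raw scores: cannot z-score")
    z = (raws - raws.mean()) / sd
    for r, zi in zip(results, z):
        r.z = float(zi)
    return list(results)


def format_percent(numerator: int, denominator: int) -> dict[str, float]:
    """One-decimal and integer roundings of a percentage, as reported."""
    pct = 100.0 * numerator / denominator if denominator else float("nan")
    return {"percent": round(pct, 1), "percent_int": int(round(pct))}


def prs_site_coverage(panel: DosagePanel, models: Sequence[PRSModel]) -> pd.DataFrame:
    """Per-model and pooled site-imputation coverage report.

    Counts, per model: total sites, sites present in the panel (matched by
    coordinates or rsID with an orientable allele), and the high-quality
    subset (quality > 0.80), with one-decimal and integer percentages.
    """
    panel_index = {(rec.key.chrom, rec.key.pos): rec for rec in panel.records}
    rsid_index = {rec.rsid: rec for rec in panel.records if rec.rsid is not None}
    rows = []
    pooled_total = pooled_used = pooled_hq = 0
    for model in models:
        n_used = n_hq = 0
        for site in model.sites:
            rec = _lookup(panel_index, rsid_index, site)
            if rec is None or match_effect_allele(rec, site) is None:
                continue
            n_used += 1
            if rec.quality > HIGH_QUALITY_THRESHOLD:
                n_hq += 1
        imputed = format_percent(n_used, model.n_sites)
        hq = format_percent(n_hq, n_used) if n_used else {"percent": float("nan"), "percent_int": 0}
        rows.append(
            {
                "model_id": model.model_id,
                "n_sites_total": model.n_sites,
                "n_sites_imputed": n_used,
                "n_sites_high_quality": n_hq,
                "imputed_percent": imputed["percent"],
                "imputed_percent_int": imputed["percent_int"],
                "high_quality_percent": hq["percent"],
                "high_quality_percent_int": hq["percent_int"],
            }
        )
        pooled_total += model.n_sites
        pooled_used += n_used
        pooled_hq += n_hq
    imputed = format_percent(pooled_used, pooled_total)
    hq = format_percent(pooled_hq, pooled_used) if pooled_used else {
        "percent": float("nan"),
        "percent_int": 0,
    }
    rows.append(
        {
            "model_id": "__pooled__",
            "n_sites_total": pooled_total,
            "n_sites_imputed": pooled_used,
            "n_sites_high_quality": pooled_hq,
            "imputed_percent": imputed["percent"],
            "imputed_percent_int": imputed["percent_int"],
            "high_quality_percent": hq["percent"],
            "high_quality_percent_int": hq["percent_int"],
        }
    )
    return pd.DataFrame(rows)


def results_to_frame(results: Sequence[PRSResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "model_id": r.model_id,
                "raw": r.raw,
                "z": r.z,
                "n_sites_total": r.n_sites_total,
                "n_sites_used": r.n_sites_used,
                "n_sites_high_quality": r.n_sites_high_quality,
            }
            for r in results
        ]
    )
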