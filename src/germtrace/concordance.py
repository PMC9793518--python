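"""Paired-panel dosage concordance: MAF-binned aggregate r² with bootstrap
confidence intervals, stratified by imputation quality and copy-number state,
plus Spearman comparison of paired per-sample scores."""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import DosagePanel, SegmentRecord

logger = logging.getLogger("germtrace")

#: Default MAF bin edges (log-spaced-ish; the axis convention, not a claim).
DEFAULT_MAF_BINS = (0.0005, 0.001, 0.005, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)

DEFAULT_QUALITY_THRESHOLD = 0.80
DEFAULT_MIN_SNPS = 1000
DEFAULT_N_BOOT = 1000

CN_STATES = ("neutral", "gain", "loss")


def aggregate_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of paired dosage vectors.

    Returns NaN (with a warning) when either vector is constant, where the
    correlation is undefined.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired dosage vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired dosages")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant dosage vector: r^2 undefined", stacklevel=2)
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _bootstrap_r2_ci(
    a: np.ndarray, b: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Percentile-bootstrap 95% CI for r², resampling variants."""
    n = a.size
    lo_q, hi_q = 2.5, 97.5
    r2s = np.empty(n_boot)
    chunk = max(1, min(n_boot, int(5e6 // max(n, 1)) or 1))
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(m, n))
        A = a[idx]
        B = b[idx]
        mA = A.mean(axis=1)
        mB = B.mean(axis=1)
        cov = (A * B).mean(axis=1) - mA * mB
        vA = (A * A).mean(axis=1) - mA * mA
        vB = (B * B).mean(axis=1) - mB * mB
        with np.errstate(divide="ignore", invalid="ignore"):
            r2s[done : done + m] = np.where(
                (vA > 0) & (vB > 0), (cov * cov) / (vA * vB), np.nan
            )
        done += m
    valid = r2s[np.isfinite(r2s)]
    if valid.size == 0:
        return float("nan"), float("nan")
    return (
        float(np.percentile(valid, lo_q)),
        float(np.percentile(valid, hi_q)),
    )


def annotate_cn_state(
    panel: DosagePanel, segments: Optional[Sequence[SegmentRecord]]
) -> np.ndarray:
    """Label each variant with the CN state of its containing segment.

    Uses the 1-based/0-based bridge (variant at p is in [start, end) iff
    start <= p-1 < end); variants outside any segment are neutral.
    """
    from .cnv import classify_segment

    labels = np.array(["neutral"] * panel.n_variants, dtype=object)
    if not segments:
        return labels
    by_chrom: dict[str, list[SegmentRecord]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for segs in by_chrom.values():
        segs.sort(key=lambda s: s.start)
    for i, key in enumerate(panel.keys()):
        for seg in by_chrom.get(key.chrom, ()):
            if seg.contains(key.pos):
                state = classify_segment(seg.log2_ratio)
                if state != "artifact":
                    labels[i] = state
                break
    return labels


def binned_concordance(
    panel_a: DosagePanel,
    panel_b: DosagePanel,
    bins: Sequence[float] = DEFAULT_MAF_BINS,
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
    cn_annotation: Optional[dict[str, np.ndarray]] = None,
    min_snps: int = DEFAULT_MIN_SNPS,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample, per-MAF-bin, per-stratum aggregate r² table.

    Strata: ``all`` (no filter), ``high_quality`` (quality > threshold), and
    — when ``cn_annotation`` maps sample ids to per-variant CN-state labels —
    ``neutral``/``gain``/``loss`` applied on top of the quality filter.
    Cells with fewer than ``min_snps`` variants report their count but a
    missing r². The 95% CI is a percentile bootstrap over variants.
    """
    if panel_a.samples != panel_b.samples:
        raise ValueError("panels must share the same sample list")
    keys_a, keys_b = panel_a.keys(), panel_b.keys()
    if keys_a != keys_b:
        offenders = [str(k) for k in (set(keys_a) ^ set(keys_b))][:5]
        raise ValueError(f"panels have mismatched variant sets; first offenders: {offenders}")

    edges = np.asarray(bins, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    maf = panel_a.maf()
    # quality from the tissue-like panel (panel_b) governs the filter;
    # bin membership: lo <= maf < hi (last bin inclusive of the upper edge)
    quality = panel_b.quality()
    bin_idx = np.digitize(maf, edges, right=False) - 1
    bin_idx[maf == edges[-1]] = len(edges) - 2

    A = panel_a.dosage_matrix()
    B = panel_b.dosage_matrix()
    rng = np.random.default_rng(seed)

    rows = []
    for s_i, sample in enumerate(panel_a.samples):
        strata: dict[str, np.ndarray] = {
            "all": np.ones(panel_a.n_variants, dtype=bool),
            "high_quality": quality > quality_threshold,
        }
        if cn_annotation is not None and sample in cn_annotation:
            labels = np.asarray(cn_annotation[sample])
            for state in CN_STATES:
                strata[state] = (labels == state) & (quality > quality_threshold)
        for b_i in range(len(edges) - 1):
            in_bin = bin_idx == b_i
            for stratum, mask in strata.items():
                sel = in_bin & mask
                n = int(sel.sum())
                row = {
                    "sample": sample,
                    "maf_lo": edges[b_i],
                    "maf_hi": edges[b_i + 1],
                    "stratum": stratum,
                    "n_snps": n,
                    "r2": np.nan,
                    "ci_lo": np.nan,
                    "ci_hi": np.nan,
                }
                if n >= min_snps:
                    a, b = A[sel, s_i], B[sel, s_i]
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        row["r2"] = aggregate_r2(a, b)
                    if np.isfinite(row["r2"]) and n_boot > 0:
                        row["ci_lo"], row["ci_hi"] = _bootstrap_r2_ci(a, b, n_boot, rng)
                rows.append(row)
    return pd.DataFrame(rows)


def summarize_binned(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate view: per bin x stratum, mean per-sample r² and totals."""
    grouped = (
        table.groupby(["maf_lo", "maf_hi", "stratum"], as_index=False)
        .agg(
            n_samples=("sample", "nunique"),
            n_snps_total=("n_snps", "sum"),
            mean_r2=("r2", "mean"),
            min_r2=("r2", "min"),
            max_r2=("r2", "max"),
        )
        .sort_values(["maf_lo", "stratum"])
    )
    return grouped.reset_index(drop=True)


def paired_score_correlation(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    n_tests_adjustment: float = 1.0,
) -> tuple[float, float, float]:
    """Spearman rank correlation of paired scores with Bonferroni q-value.

    Average ranks handle ties; ``q = min(1, p * n_tests_adjustment)``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size != b.size:
        raise ValueError("score vectors must be paired")
    if a.size < 3:
        raise ValueError("need at least 3 paired scores")
    res = stats.spearmanr(a, b)
    p = float(res.pvalue)
    return float(res.statistic), p, min(1.0, p * n_tests_adjustment)
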