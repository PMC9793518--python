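"""Readers and writers for the external formats the pipeline touches.

Formats: dosage VCF (per-genotype dosage + per-variant quality annotation),
PGS-Catalog-style scoring files, BED-like copy-number segment tables, HLA
typing TSVs and the cohort CSV. All writers emit plain text so that a write
then re-read round-trips values (floats to >= 6 decimals).
"""

from __future__ import annotations

import csv
import logging
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from cyvcf2 import VCF

from .types import (
    CohortRecord,
    DosagePanel,
    DosageRecord,
    HLARecord,
    PRSModel,
    PRSSite,
    SegmentRecord,
    VariantKey,
    normalize_chrom,
)

logger = logging.getLogger("germtrace")

#: Default VCF dialect: GLIMPSE-style dosage FORMAT tag and INFO quality tag.
DEFAULT_DOSAGE_FIELD = "DS"
DEFAULT_QUALITY_FIELD = "INFO_SCORE"
DEFAULT_MAF_FIELD = "MAF"

# QC thresholds: samples below this mean coverage or above this contamination
# estimate are excluded before any analysis.
QC_MIN_COVERAGE = 0.45
QC_MAX_CONTAMINATION = 0.05


# ---------------------------------------------------------------------------
# Dosage VCF
# ---------------------------------------------------------------------------

def read_dosage_vcf(
    path: str | Path,
    dosage_field: str = DEFAULT_DOSAGE_FIELD,
    quality_field: str = DEFAULT_QUALITY_FIELD,
    maf_field: str = DEFAULT_MAF_FIELD,
) -> DosagePanel:
    """Load a dosage VCF into a :class:`DosagePanel`.

    Only biallelic SNP records are retained; multi-allelic records and indels
    are dropped with a logged count. A record without the dosage FORMAT field
    is a hard error. When the MAF INFO tag is absent the MAF is derived from
    the mean dosage (folded to the minor allele).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[DosageRecord] = []
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        if v.REF not in "ACGT" or v.ALT[0] not in "ACGT":
            n_dropped += 1
            continue
        try:
            pos = int(v.POS)
        except (TypeError, ValueError) as exc:  # pragma: no cover - cyvcf2 guards
            raise ValueError(f"malformed position in record {v.CHROM}:{v.POS}") from exc
        try:
            ds = v.format(dosage_field)
        except KeyError:
            ds = None
        if ds is None:
            raise ValueError(
                f"record {v.CHROM}:{pos} {v.REF}>{v.ALT[0]} lacks dosage field "
                f"'{dosage_field}'"
            )
        dosages = np.asarray(ds, dtype=float).reshape(len(samples))
        quality = v.INFO.get(quality_field)
        if quality is None:
            quality = 1.0
        maf = v.INFO.get(maf_field)
        if maf is None:
            af = float(np.mean(dosages)) / 2.0
            maf = min(af, 1.0 - af)
        key = VariantKey(normalize_chrom(v.CHROM), pos, v.REF, v.ALT[0])
        rsid = v.ID if v.ID not in (None, ".") else None
        records.append(
            DosageRecord(
                key=key,
                maf=float(maf),
                quality=float(quality),
                dosages=np.clip(dosages, 0.0, 2.0),
                rsid=rsid,
            )
        )
    if n_dropped:
        logger.info("read_dosage_vcf: dropped %d non-SNP/multi-allelic records", n_dropped)
    return DosagePanel(samples, records)


def write_dosage_vcf(
    panel: DosagePanel,
    path: str | Path,
    dosage_field: str = DEFAULT_DOSAGE_FIELD,
    quality_field: str = DEFAULT_QUALITY_FIELD,
    maf_field: str = DEFAULT_MAF_FIELD,
) -> None:
    """Write a panel as an uncompressed VCF with dosage FORMAT records."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f'##INFO=<ID={maf_field},Number=1,Type=Float,'
            f'Description="Minor allele frequency">\n'
        )
        fh.write(
            f'##INFO=<ID={quality_field},Number=1,Type=Float,'
            f'Description="Imputation quality score">\n'
        )
        fh.write(
            f'##FORMAT=<ID={dosage_field},Number=1,Type=Float,'
            f'Description="Expected alternate allele dosage">\n'
        )
        for chrom in sorted({rec.key.chrom for rec in panel.records}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        for rec in sorted(panel.records, key=lambda r: (r.key.chrom, r.key.pos)):
            info = f"{maf_field}={rec.maf:.6g};{quality_field}={rec.quality:.6f}"
            cells = "\t".join(f"{d:.6f}" for d in rec.dosages)
            fh.write(
                f"{rec.key.chrom}\t{rec.key.pos}\t{rec.rsid or '.'}\t{rec.key.ref}\t"
                f"{rec.key.alt}\t.\tPASS\t{info}\t{dosage_field}\t{cells}\n"
            )


# ---------------------------------------------------------------------------
# PGS scoring files
# ---------------------------------------------------------------------------

_PGS_COLUMN_ALIASES = {
    "rsid": ("rsID", "rsid", "variant_id"),
    "chrom": ("chr_name", "chrom", "chromosome"),
    "pos": ("chr_position", "pos", "position"),
    "effect_allele": ("effect_allele",),
    "other_allele": ("other_allele", "reference_allele", "hm_inferOtherAllele"),
    "beta": ("effect_weight", "beta", "weight"),
}


def read_pgs_scoring_file(path: str | Path, model_id: Optional[str] = None) -> PRSModel:
    """Parse a tab-delimited PGS-Catalog-style scoring file.

    ``#`` comment lines are skipped. Duplicate variant rows keep the first
    occurrence with a logged warning; a non-numeric effect weight is a hard
    error naming the offending line.
    """
    path = Path(path)
    if model_id is None:
        model_id = path.stem
    header: Optional[list[str]] = None
    colmap: dict[str, int] = {}
    sites: list[PRSSite] = []
    seen: set[str] = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                for field_name, aliases in _PGS_COLUMN_ALIASES.items():
                    for alias in aliases:
                        if alias in header:
                            colmap[field_name] = header.index(alias)
                            break
                if "beta" not in colmap or "effect_allele" not in colmap:
                    raise ValueError(
                        f"{path}: header lacks effect_allele/effect_weight columns"
                    )
                continue

            def get(field_name: str) -> Optional[str]:
                idx = colmap.get(field_name)
                if idx is None or idx >= len(parts):
                    return None
                val = parts[idx].strip()
                return val or None

            raw_beta = get("beta")
            try:
                beta = float(raw_beta)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}:{lineno}: non-numeric effect weight {raw_beta!r}"
                ) from None
            chrom = get("chrom")
            pos = get("pos")
            site = PRSSite(
                effect_allele=get("effect_allele") or "",
                beta=beta,
                other_allele=get("other_allele"),
                chrom=normalize_chrom(chrom) if chrom else None,
                pos=int(pos) if pos else None,
                rsid=get("rsid"),
            )
            ident = site.identity()
            if ident in seen:
                n_dup += 1
                logger.warning("%s:%d: duplicate site %s, keeping first", path, lineno, ident)
                continue
            seen.add(ident)
            sites.append(site)
    if header is None:
        raise ValueError(f"{path}: no header found")
    if n_dup:
        logger.warning("%s: %d duplicate site rows dropped", path, n_dup)
    return PRSModel(model_id=model_id, sites=sites)


def write_pgs_scoring_file(model: PRSModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# model_id={model.model_id}\n")
        fh.write("rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight\n")
        for s in model.sites:
            fh.write(
                "\t".join(
                    [
                        s.rsid or "",
                        s.chrom or "",
                        str(s.pos) if s.pos is not None else "",
                        s.effect_allele,
                        s.other_allele or "",
                        f"{s.beta:.8g}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Segment tables (BED-like with a log2 ratio column)
# ---------------------------------------------------------------------------

def _validate_non_overlapping(segments: Sequence[SegmentRecord]) -> None:
    by_chrom: dict[str, list[SegmentRecord]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for prev, cur in zip(segs, segs[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"overlapping segments on chromosome {chrom}: "
                    f"[{prev.start},{prev.end}) and [{cur.start},{cur.end})"
                )


def read_segments(path: str | Path) -> dict[str, list[SegmentRecord]]:
    """Read a segment table keyed by sample.

    Columns (tab- or comma-delimited, with header): sample_id, chrom, start,
    end, log2_ratio. Overlapping segments on one chromosome are a hard error.
    """
    segments: dict[str, list[SegmentRecord]] = {}
    with open(path) as fh:
        delim = "\t" if "\t" in fh.readline() else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        for row in reader:
            seg = SegmentRecord(
                chrom=normalize_chrom(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                log2_ratio=float(row["log2_ratio"]),
            )
            segments.setdefault(row["sample_id"], []).append(seg)
    for sample_segs in segments.values():
        _validate_non_overlapping(sample_segs)
    return segments


def write_segments(segments: dict[str, list[SegmentRecord]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tchrom\tstart\tend\tlog2_ratio\n")
        for sample_id, segs in segments.items():
            for seg in sorted(segs, key=lambda s: (s.chrom, s.start)):
                fh.write(
                    f"{sample_id}\t{seg.chrom}\t{seg.start}\t{seg.end}\t"
                    f"{seg.log2_ratio:.6f}\n"
                )


# ---------------------------------------------------------------------------
# Cohort CSV
# ---------------------------------------------------------------------------

_COHORT_COLUMNS = [
    "patient_id",
    "bcse",
    "race",
    "ethnicity",
    "age_range",
    "surgery",
    "size_cm",
    "grade",
    "er_status",
    "days",
]


def _parse_optional_float(value: str) -> Optional[float]:
    value = value.strip()
    if value in ("", "NA", "nan", "None"):
        return None
    return float(value)


def read_cohort(path: str | Path) -> list[CohortRecord]:
    """Read the cohort CSV (columns mirroring the clinical table).

    Missing grade/size cells ("NA" or empty) are preserved as missing.
    European ancestry is derived from the race column when no explicit
    ``european_ancestry`` column is present.
    """
    records: list[CohortRecord] = []
    with open(path) as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            grade = _parse_optional_float(row.get("grade", ""))
            if "european_ancestry" in row and row["european_ancestry"].strip():
                european: Optional[bool] = row["european_ancestry"].strip().lower() in (
                    "1",
                    "true",
                    "yes",
                )
            elif row.get("race", "").strip():
                european = row["race"].strip().lower() == "white"
            else:
                european = None
            prs_values = {
                k[4:]: float(v)
                for k, v in row.items()
                if k.startswith("prs_") and v not in ("", "NA", None)
            }
            records.append(
                CohortRecord(
                    patient_id=row["patient_id"],
                    event=row["bcse"].strip().lower() in ("yes", "1", "true"),
                    time=float(row["days"]),
                    grade=int(grade) if grade is not None else None,
                    size_cm=_parse_optional_float(row.get("size_cm", "")),
                    age_group=row.get("age_range", "").replace("–", "-").strip() or None,
                    european_ancestry=european,
                    prs_values=prs_values,
                )
            )
    return records


def write_cohort(records: Iterable[CohortRecord], path: str | Path) -> None:
    records = list(records)
    prs_names = sorted({name for rec in records for name in rec.prs_values})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["patient_id", "bcse", "age_range", "size_cm", "grade", "days", "european_ancestry"]
            + [f"prs_{name}" for name in prs_names]
        )
        for rec in records:
            writer.writerow(
                [
                    rec.patient_id,
                    "Yes" if rec.event else "No",
                    rec.age_group or "",
                    "" if rec.size_cm is None else f"{rec.size_cm:.6g}",
                    "" if rec.grade is None else rec.grade,
                    f"{rec.time:.6g}",
                    "" if rec.european_ancestry is None else ("yes" if rec.european_ancestry else "no"),
                ]
                + [
                    "" if name not in rec.prs_values else f"{rec.prs_values[name]:.8g}"
                    for name in prs_names
                ]
            )


# ---------------------------------------------------------------------------
# HLA typing tables
# ---------------------------------------------------------------------------

def read_hla_table(path: str | Path) -> list[HLARecord]:
    """Read an HLA TSV: sample_id, gene, allele1, allele2, posterior (optional)."""
    records: list[HLARecord] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            posterior_raw = (row.get("posterior") or "").strip()
            posterior = float(posterior_raw) if posterior_raw not in ("", "NA") else None
            records.append(
                HLARecord(
                    sample_id=row["sample_id"],
                    gene=row["gene"].strip(),
                    allele1=row["allele1"].strip(),
                    allele2=row["allele2"].strip(),
                    posterior=posterior,
                )
            )
    return records


def write_hla_table(records: Iterable[HLARecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgene\tallele1\tallele2\tposterior\n")
        for rec in records:
            post = "" if rec.posterior is None else f"{rec.posterior:.6f}"
            fh.write(f"{rec.sample_id}\t{rec.gene}\t{rec.allele1}\t{rec.allele2}\t{post}\n")


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------

def apply_qc_filter(
    coverage: dict[str, float],
    contamination: dict[str, float],
    min_coverage: float = QC_MIN_COVERAGE,
    max_contamination: float = QC_MAX_CONTAMINATION,
) -> dict[str, object]:
    """Apply the sample-level exclusion rules and summarize the result.

    A sample is excluded if its mean coverage is below ``min_coverage`` or its
    contamination estimate exceeds ``max_contamination``. Returns retained and
    excluded sample lists plus the integer-rounded excluded percentage.
    """
    samples = sorted(set(coverage) | set(contamination))
    excluded: list[str] = []
    reasons: dict[str, str] = {}
    for s in samples:
        if coverage.get(s, math.inf) < min_coverage:
            excluded.append(s)
            reasons[s] = "low_coverage"
        elif contamination.get(s, 0.0) > max_contamination:
            excluded.append(s)
            reasons[s] = "contamination"
    retained = [s for s in samples if s not in reasons]
    pct = round(100.0 * len(excluded) / len(samples)) if samples else 0
    return {
        "n_total": len(samples),
        "retained": retained,
        "excluded": excluded,
        "reasons": reasons,
        "excluded_percent": pct,
    }
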