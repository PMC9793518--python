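"""HLA allele-string handling and typing concordance at 2/4-field resolution."""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import HLARecord, hla_gene_class

logger = logging.getLogger("germtrace")

_SUFFIX_RE = re.compile(r"[A-Z]+$")


@dataclass(frozen=True)
class AlleleString:
    """A parsed HLA allele: gene plus 1-4 colon-delimited field tokens."""

    gene: str
    fields: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.fields) <= 4:
            raise ValueError(f"allele must carry 1-4 fields: {self}")

    def __str__(self) -> str:
        return f"{self.gene}*{':'.join(self.fields)}"


def parse_allele(text: str) -> AlleleString:
    """Parse ``GENE*f1:f2[:f3[:f4]]``; expression-suffix letters are stripped."""
    if "*" not in text:
        raise ValueError(f"not an HLA allele string: {text!r}")
    gene, rest = text.split("*", 1)
    fields = rest.split(":")
    last = fields[-1]
    stripped = _SUFFIX_RE.sub("", last)
    if stripped != last:
        logger.info("stripped expression suffix from %s", text)
        fields[-1] = stripped
    return AlleleString(gene=gene, fields=tuple(fields))


def truncate_allele(allele: AlleleString, n_fields: int) -> tuple[AlleleString, bool]:
    """Drop trailing fields down to ``n_fields``.

    When the allele has fewer fields than requested it is returned unchanged
    with a flag, and comparisons fall back to the coarser resolution.
    """
    if n_fields not in (1, 2, 3, 4):
        raise ValueError("n_fields must be in 1..4")
    if len(allele.fields) < n_fields:
        return allele, True
    return AlleleString(allele.gene, allele.fields[:n_fields]), False


def _alleles_equal(a: AlleleString, b: AlleleString, n_fields: int) -> bool:
    k = min(n_fields, len(a.fields), len(b.fields))
    return a.gene == b.gene and a.fields[:k] == b.fields[:k]


@dataclass
class GeneConcordance:
    """Match count for one sample x gene comparison (0, 1 or 2 alleles)."""

    sample_id: str
    gene: str
    n_matched: int
    class_label: str

    def __post_init__(self) -> None:
        if self.n_matched not in (0, 1, 2):
            raise ValueError("n_matched must be 0, 1, or 2")


def gene_concordance(
    pred_pair: tuple[str, str],
    gold_pair: tuple[str, str],
    n_fields: int = 4,
    sample_id: str = "",
    gene: Optional[str] = None,
) -> GeneConcordance:
    """Maximum matching between two unordered allele pairs after truncation.

    Both pairings are evaluated and the better one kept, so a single
    predicted allele can never be counted against both gold alleles.
    """
    p1, p2 = (parse_allele(a) for a in pred_pair)
    g1, g2 = (parse_allele(a) for a in gold_pair)
    if gene is None:
        gene = g1.gene
    straight = int(_alleles_equal(p1, g1, n_fields)) + int(_alleles_equal(p2, g2, n_fields))
    crossed = int(_alleles_equal(p1, g2, n_fields)) + int(_alleles_equal(p2, g1, n_fields))
    return GeneConcordance(
        sample_id=sample_id,
        gene=gene,
        n_matched=max(straight, crossed),
        class_label=hla_gene_class(gene),
    )


def compare_typing_sets(
    pred: Sequence[HLARecord], gold: Sequence[HLARecord], n_fields: int = 4
) -> tuple[list[GeneConcordance], int]:
    """Score every (sample, gene) present in both sets.

    Returns the concordance records plus the count of (sample, gene) cells
    missing from one of the two sets (excluded from summaries).
    """
    pred_map = {(r.sample_id, r.gene): r for r in pred}
    gold_map = {(r.sample_id, r.gene): r for r in gold}
    shared = sorted(set(pred_map) & set(gold_map))
    n_missing = len(set(pred_map) ^ set(gold_map))
    out = []
    for sample_id, gene in shared:
        p = pred_map[(sample_id, gene)]
        g = gold_map[(sample_id, gene)]
        out.append(
            gene_concordance(
                (p.allele1, p.allele2),
                (g.allele1, g.allele2),
                n_fields=n_fields,
                sample_id=sample_id,
                gene=gene,
            )
        )
    return out, n_missing


def summarize_concordance(records: Sequence[GeneConcordance]) -> pd.DataFrame:
    """Per-class allele concordance: matched alleles over 2 x genes compared."""
    if not records:
        raise ValueError("no concordance records to summarize")
    rows = []
    for class_label in ("I", "II"):
        subset = [r for r in records if r.class_label == class_label]
        if not subset:
            continue
        concordant = sum(r.n_matched for r in subset)
        total = 2 * len(subset)
        rows.append(
            {
                "class_label": class_label,
                "n_genes_compared": len(subset),
                "concordant_alleles": concordant,
                "total_alleles": total,
                "percent": round(100.0 * concordant / total, 1),
            }
        )
    return pd.DataFrame(rows)


def posterior_by_concordance(
    concordances: Sequence[GeneConcordance],
    typings: Sequence[HLARecord],
) -> dict[str, object]:
    """Compare imputation posteriors between perfectly concordant genes and
    those with errors (rank-based two-sided Mann-Whitney U)."""
    post_map = {
        (r.sample_id, r.gene): r.posterior for r in typings if r.posterior is not None
    }
    perfect, with_errors = [], []
    for rec in concordances:
        post = post_map.get((rec.sample_id, rec.gene))
        if post is None:
            continue
        (perfect if rec.n_matched == 2 else with_errors).append(post)
    out: dict[str, object] = {
        "n_perfect": len(perfect),
        "n_with_errors": len(with_errors),
        "mean_perfect": float(np.mean(perfect)) if perfect else None,
        "mean_with_errors": float(np.mean(with_errors)) if with_errors else None,
        "p_value": None,
    }
    if perfect and with_errors:
        res = stats.mannwhitneyu(perfect, with_errors, alternative="two-sided")
        out["p_value"] = float(res.pvalue)
    return out


def concordance_grid(records: Sequence[GeneConcordance]) -> pd.DataFrame:
    """Genes x samples grid of match counts (figure-style layout)."""
    df = pd.DataFrame(
        [{"sample": r.sample_id, "gene": r.gene, "n_matched": r.n_matched} for r in records]
    )
    return df.pivot_table(index="gene", columns="sample", values="n_matched", aggfunc="first")
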