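"""Chromosomal-distribution randomness testing and genomic-context calls.

The expected number of integrations on a chromosome under uniform random
placement is e = Cl x n / Tl (Cl the ungapped chromosome length, n the
total locus count, Tl the summed ungapped length).  Departure from the
expectation is assessed two ways: an overall Pearson goodness-of-fit
chi-square across chromosomes, and per-chromosome two-sided exact binomial
tests with Benjamini-Hochberg adjustment, because a single overall
statistic cannot attribute an excess to one chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneModel

logger = logging.getLogger(__name__)

CONTEXT_INTERGENIC = "Intergenic"
CONTEXT_INTRON = "Intron"
CONTEXT_EXON_INTRON = "Exon_intron"
CONTEXT_EXONIC_INTERGENIC = "Exonic_intergenic"


def expected_counts(
    chrom_ungapped_lengths: Mapping[str, int], n: int
) -> dict[str, float]:
    """e = Cl x n / Tl per chromosome; the expectations sum to n exactly."""
    if n < 0:
        raise ValueError("n must be >= 0")
    tl = sum(chrom_ungapped_lengths.values())
    if tl <= 0:
        raise ValueError("total ungapped length must be > 0")
    return {c: cl * n / tl for c, cl in chrom_ungapped_lengths.items()}


@dataclass
class ChromDistribution:
    """Observed vs expected per-chromosome integration counts."""

    table: pd.DataFrame  # chrom, observed, expected, contribution, p_binomial, q_bh
    chi2: float
    df: int
    p_value: float


def distribution_test(
    observed: Mapping[str, int],
    chrom_ungapped_lengths: Mapping[str, int],
) -> ChromDistribution:
    """Goodness-of-fit chi-square plus per-chromosome exact binomial tests.

    Chromosomes with zero expectation and nonzero observation are excluded
    from the chi-square with a warning (they would be infinite
    contributions); the binomial test still covers them.
    """
    unknown = set(observed) - set(chrom_ungapped_lengths)
    if unknown:
        raise ValueError(f"observed counts on unknown chromosomes: {unknown}")
    n = sum(observed.values())
    expected = expected_counts(chrom_ungapped_lengths, n)
    tl = sum(chrom_ungapped_lengths.values())
    rows = []
    for chrom in chrom_ungapped_lengths:
        o = int(observed.get(chrom, 0))
        e = expected[chrom]
        if e == 0 and o > 0:
            logger.warning(
                "chromosome %s has zero expectation but %d observed; "
                "excluded from chi-square", chrom, o,
            )
            contribution = float("nan")
        else:
            contribution = (o - e) ** 2 / e if e > 0 else 0.0
        p_prop = chrom_ungapped_lengths[chrom] / tl
        p_binom = (
            stats.binomtest(o, n, p_prop, alternative="two-sided").pvalue
            if n > 0
            else 1.0
        )
        rows.append(
            {
                "chrom": chrom,
                "observed": o,
                "expected": e,
                "contribution": contribution,
                "p_binomial": p_binom,
            }
        )
    table = pd.DataFrame(rows)
    valid = table.contribution.notna()
    chi2 = float(table.loc[valid, "contribution"].sum())
    df = int(valid.sum()) - 1
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    if n == 0:
        chi2, p_value = 0.0, 1.0
    table["q_bh"] = multipletests(table.p_binomial, method="fdr_bh")[1]
    return ChromDistribution(table=table, chi2=chi2, df=df, p_value=p_value)


# ---------------------------------------------------------------------------
# Genomic context
# ---------------------------------------------------------------------------

@dataclass
class GenomicContext:
    """Context category and gene relation for one locus."""

    locus_id: str
    category: str
    gene_ids: tuple[str, ...]
    orientation_relation: str  # same | opposite | NA


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def classify_context(
    locus_id: str,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    genes: Sequence[GeneModel],
) -> GenomicContext:
    """Classify a locus against gene spans, exons and introns.

    Intergenic: no overlap with any gene span.  Intron: fully inside
    gene(s), touching no exon.  Exon_intron: inside gene(s), overlapping
    at least one exon and one intron.  Exonic_intergenic: overlapping a
    gene exon while extending beyond the gene span.  Orientation is taken
    from the overlapping gene with the largest overlap.
    """
    overlapping = [
        g
        for g in genes
        if g.chrom == chrom and _overlap(start, end, g.start, g.end) > 0
    ]
    if not overlapping:
        return GenomicContext(locus_id, CONTEXT_INTERGENIC, (), "NA")
    inside = any(g.start <= start and end <= g.end for g in overlapping)
    hits_exon = any(
        _overlap(start, end, s, e) > 0 for g in overlapping for s, e in g.exons
    )
    hits_intron = any(
        _overlap(start, end, s, e) > 0
        for g in overlapping
        for s, e in g.introns
    )
    if inside:
        if hits_exon and hits_intron:
            category = CONTEXT_EXON_INTRON
        elif hits_exon:
            category = CONTEXT_EXON_INTRON  # exon-contained: exonic overlap
        else:
            category = CONTEXT_INTRON
    else:
        # overlaps a gene but extends beyond its span
        category = CONTEXT_EXONIC_INTERGENIC
    best = max(overlapping, key=lambda g: _overlap(start, end, g.start, g.end))
    orientation = "same" if best.strand == strand else "opposite"
    return GenomicContext(
        locus_id,
        category,
        tuple(g.gene_id for g in overlapping),
        orientation,
    )


def summarize_context(
    categories: Sequence[str], merge_exonic: bool = True
) -> pd.DataFrame:
    """Category counts and percentages (2 decimals).

    With ``merge_exonic`` (default) the Exonic_intergenic category is
    grouped with Exon_intron, matching how exon-overlapping elements are
    summarized in catalog-level breakdowns.
    """
    if not categories:
        return pd.DataFrame(columns=["category", "count", "percent"])
    mapped = [
        CONTEXT_EXON_INTRON
        if merge_exonic and c == CONTEXT_EXONIC_INTERGENIC
        else c
        for c in categories
    ]
    total = len(mapped)
    order = [
        CONTEXT_INTERGENIC,
        CONTEXT_INTRON,
        CONTEXT_EXON_INTRON,
        CONTEXT_EXONIC_INTERGENIC,
    ]
    rows = []
    for cat in order:
        count = mapped.count(cat)
        if count:
            rows.append(
                {
                    "category": cat,
                    "count": count,
                    "percent": round(100.0 * count / total, 2),
                }
            )
    return pd.DataFrame(rows)
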