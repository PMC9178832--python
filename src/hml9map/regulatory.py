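"""Regulatory-domain construction, element-gene association, and ORA.

Each gene receives a basal regulatory domain around its TSS (5 kb
upstream, 1 kb downstream, strand-aware) which is then extended on each
side to the nearer of the closest neighboring basal domain boundary and
1 Mb, clipped to the chromosome.  Basal domains are inviolable: a
neighbor can stop another gene's extension but never truncate a basal
region.  Elements are associated with every gene whose extended domain
contains the element midpoint, and over-representation of gene
categories is tested with the hypergeometric upper tail under
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneModel

BASAL_UPSTREAM = 5000
BASAL_DOWNSTREAM = 1000
MAX_EXTENSION = 1_000_000

DISTANCE_BINS = ((0, 5_000), (5_000, 50_000), (50_000, 500_000))
BIN_LABELS = ("<5 kb", "5-50 kb", "50-500 kb", ">500 kb")


@dataclass
class RegulatoryDomain:
    """Strand-aware basal + extended regulatory domain of one gene."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    basal: tuple[int, int]
    extended: tuple[int, int]

    def contains(self, position: int) -> bool:
        return self.extended[0] <= position <= self.extended[1]


@dataclass
class Association:
    """An element-gene link with signed TSS distance."""

    element_id: str
    gene_id: str
    distance: int  # positive downstream of the TSS in reading direction
    bin: str


def basal_interval(
    gene: GeneModel,
    upstream: int = BASAL_UPSTREAM,
    downstream: int = BASAL_DOWNSTREAM,
) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.tss - upstream, gene.tss + downstream
    return gene.tss - downstream, gene.tss + upstream


def build_domains(
    genes: Sequence[GeneModel],
    chrom_lengths: Mapping[str, int],
    upstream: int = BASAL_UPSTREAM,
    downstream: int = BASAL_DOWNSTREAM,
    max_extension: int = MAX_EXTENSION,
) -> list[RegulatoryDomain]:
    """Basal + extension domains for all genes, grouped per chromosome."""
    domains: list[RegulatoryDomain] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        if not (1 <= g.tss <= chrom_lengths[g.chrom]):
            raise ValueError(
                f"gene {g.gene_id}: TSS {g.tss} outside chromosome"
            )
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, chrom_genes in by_chrom.items():
        clen = chrom_lengths[chrom]
        basals = {
            g.gene_id: (
                max(1, basal_interval(g, upstream, downstream)[0]),
                min(clen, basal_interval(g, upstream, downstream)[1]),
            )
            for g in chrom_genes
        }
        for g in chrom_genes:
            b_start, b_end = basals[g.gene_id]
            left_limits = [b_start - max_extension, 1]
            right_limits = [b_end + max_extension, clen]
            for gid, (bs, be) in basals.items():
                if gid == g.gene_id:
                    continue
                if be < b_start:
                    left_limits.append(be + 1)
                elif bs < b_start:  # neighbor basal overlaps ours from the left
                    left_limits.append(b_start)
                if bs > b_end:
                    right_limits.append(bs - 1)
                elif be > b_end:  # neighbor basal overlaps ours from the right
                    right_limits.append(b_end)
            ext_start = max(max(left_limits), 1)
            ext_end = min(min(right_limits), clen)
            domains.append(
                RegulatoryDomain(
                    gene_id=g.gene_id,
                    chrom=chrom,
                    strand=g.strand,
                    tss=g.tss,
                    basal=(b_start, b_end),
                    extended=(min(ext_start, b_start), max(ext_end, b_end)),
                )
            )
    return domains


def signed_tss_distance(midpoint: int, domain: RegulatoryDomain) -> int:
    """Signed distance in the gene's reading direction (downstream > 0)."""
    if domain.strand == "+":
        return midpoint - domain.tss
    return domain.tss - midpoint


def distance_bin(distance: int) -> str:
    """Bin by absolute distance; boundaries left-closed at 5/50/500 kb."""
    a = abs(distance)
    for (lo, hi), label in zip(DISTANCE_BINS, BIN_LABELS):
        if lo <= a < hi:
            return label
    return BIN_LABELS[-1]


def associate(
    elements: Mapping[str, tuple[str, int, int]],
    domains: Sequence[RegulatoryDomain],
) -> tuple[list[Association], dict[str, int]]:
    """Associate each element with the domains containing its midpoint.

    ``elements`` maps element id -> (chrom, start, end).  Returns the
    association list plus per-element gene counts (zero-gene elements
    included).
    """
    associations: list[Association] = []
    counts = {eid: 0 for eid in elements}
    for eid, (chrom, start, end) in elements.items():
        midpoint = (start + end) // 2
        for dom in domains:
            if dom.chrom == chrom and dom.contains(midpoint):
                dist = signed_tss_distance(midpoint, dom)
                associations.append(
                    Association(
                        element_id=eid,
                        gene_id=dom.gene_id,
                        distance=dist,
                        bin=distance_bin(dist),
                    )
                )
                counts[eid] += 1
    return associations, counts


def bin_distances(
    associations: Sequence[Association],
) -> dict[str, int]:
    out = {label: 0 for label in BIN_LABELS}
    for a in associations:
        out[a.bin] += 1
    return out


@dataclass
class EnrichmentResult:
    category_id: str
    K: int  # category size within the universe
    n: int  # gene-list size
    N: int  # universe size
    k: int  # overlap
    enrichment_ratio: float
    p_value: float
    fdr: float
    rank: int


def ora(
    gene_list: Sequence[str],
    categories: Mapping[str, set[str]],
    universe: Sequence[str],
    min_size: int = 5,
    max_size: int = 2000,
    top: int = 10,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation analysis with BH adjustment.

    Categories are intersected with the universe and those outside
    [min_size, max_size] are excluded; p = P(X >= k) for X hypergeometric
    (N, K, n).  Results are ranked by FDR (ties by p, then category id)
    and the top ``top`` returned.
    """
    uni = set(universe)
    genes = set(gene_list)
    if not genes:
        raise ValueError("empty gene list")
    if not uni:
        raise ValueError("empty universe")
    if not genes <= uni:
        raise ValueError("gene list must be a subset of the universe")
    N, n = len(uni), len(genes)
    tested = []
    for cid, members in categories.items():
        cat = members & uni
        K = len(cat)
        if not (min_size <= K <= max_size):
            continue
        k = len(cat & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        ratio = (k / n) / (K / N)
        tested.append((cid, K, k, p, ratio))
    if not tested:
        return []
    fdrs = multipletests([t[3] for t in tested], method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            category_id=cid,
            K=K,
            n=n,
            N=N,
            k=k,
            enrichment_ratio=ratio,
            p_value=p,
            fdr=float(f),
            rank=0,
        )
        for (cid, K, k, p, ratio), f in zip(tested, fdrs)
    ]
    results.sort(key=lambda r: (r.fdr, r.p_value, r.category_id))
    for i, r in enumerate(results, 1):
        r.rank = i
    return results[:top]
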