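"""Reference-homologous locus discovery by seeded local alignment.

The search follows the classic seed-and-extend design: the genome is
indexed with overlapping 11-mers stepped by 5, query k-mers (every offset)
are looked up on both strands, seed hits sharing a diagonal are extended
without gaps under an x-drop rule, and extended blocks are chained
colinearly.  Chains are merged into element loci, classified as provirus
vs solo LTR, named by cytoband, and screened for downstream analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .io_formats import GenomeAssembly, ProviralReference
from .synthetic import reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_K = 11
DEFAULT_STEP = 5


@dataclass
class SeedIndex:
    """Genome k-mer index: k-mers sampled at a fixed stride."""

    k: int
    step: int
    kmers: dict[str, list[tuple[str, int]]]  # kmer -> [(chrom, 1-based pos)]

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.kmers.get(kmer, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self.kmers.values())


@dataclass
class Block:
    """A gapless aligned segment on one diagonal."""

    q_start: int  # 1-based query (reference-orientation-specific) coords
    q_end: int
    g_start: int  # 1-based genome coords (plus strand)
    g_end: int
    matches: int
    mismatches: int


@dataclass
class AlignmentChain:
    """A maximal colinear set of gapless blocks on one strand."""

    chrom: str
    strand: str
    blocks: list[tuple[int, int, int, int]]  # (g_start, g_end, r_start, r_end)
    matches: int
    mismatches: int

    @property
    def score(self) -> int:
        return self.matches - self.mismatches

    @property
    def g_start(self) -> int:
        return min(b[0] for b in self.blocks)

    @property
    def g_end(self) -> int:
        return max(b[1] for b in self.blocks)

    @property
    def r_start(self) -> int:
        return min(b[2] for b in self.blocks)

    @property
    def r_end(self) -> int:
        return max(b[3] for b in self.blocks)

    @property
    def aligned_ref_positions(self) -> set[int]:
        out: set[int] = set()
        for _, _, rs, re in self.blocks:
            out.update(range(rs, re + 1))
        return out

    @property
    def qgap(self) -> int:
        """Reference bases spanned by the chain but unaligned inside it."""
        return (self.r_end - self.r_start + 1) - sum(
            re - rs + 1 for _, _, rs, re in self.blocks
        )


@dataclass
class ElementLocus:
    """One discovered genomic element."""

    locus_id: str
    chrom: str
    strand: str
    start: int
    end: int
    element_class: str  # provirus | solo_LTR
    coverage_pct: float
    qgap_pct: float
    name: str = ""
    chains: list[AlignmentChain] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


# ---------------------------------------------------------------------------
# Indexing and search
# ---------------------------------------------------------------------------

def build_index(
    genome: GenomeAssembly, k: int = DEFAULT_K, step: int = DEFAULT_STEP
) -> SeedIndex:
    """Index genome k-mers at positions 1, 1+step, 1+2*step, ...

    Words containing ambiguous bases are skipped; chromosomes shorter than
    k are skipped with a warning.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    if step < 1:
        raise ValueError("step must be >= 1")
    kmers: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in genome.chromosomes.items():
        if len(seq) < k:
            logger.warning("chromosome %s shorter than k=%d, skipped", chrom, k)
            continue
        for i in range(0, len(seq) - k + 1, step):
            word = seq[i : i + k]
            if "N" in word:
                continue
            kmers.setdefault(word, []).append((chrom, i + 1))
    return SeedIndex(k=k, step=step, kmers=kmers)


def _extend_ungapped(
    query: str,
    target: str,
    q_pos: int,
    g_pos: int,
    k: int,
    xdrop: int,
    match_score: int = 2,
    mismatch_score: int = -3,
) -> Block:
    """X-drop ungapped extension of a seed in both directions (0-based in)."""
    # right extension from the seed end
    score = best = 0
    qi, gi = q_pos + k, g_pos + k
    right_q = q_pos + k - 1
    while qi < len(query) and gi < len(target):
        score += match_score if query[qi] == target[gi] else mismatch_score
        if score > best:
            best = score
            right_q = qi
        if best - score > xdrop:
            break
        qi += 1
        gi += 1
    # left extension from the seed start
    score = best = 0
    qi, gi = q_pos - 1, g_pos - 1
    left_q = q_pos
    while qi >= 0 and gi >= 0:
        score += match_score if query[qi] == target[gi] else mismatch_score
        if score > best:
            best = score
            left_q = qi
        if best - score > xdrop:
            break
        qi -= 1
        gi -= 1
    diag = g_pos - q_pos
    qs, qe = left_q, right_q
    matches = mismatches = 0
    for q in range(qs, qe + 1):
        if query[q] == target[q + diag]:
            matches += 1
        else:
            mismatches += 1
    return Block(
        q_start=qs + 1,
        q_end=qe + 1,
        g_start=qs + diag + 1,
        g_end=qe + diag + 1,
        matches=matches,
        mismatches=mismatches,
    )


def _chain_blocks(
    blocks: list[Block],
    max_ref_gap: int,
    max_genome_gap: int,
) -> list[list[Block]]:
    """Greedy best-first colinear chaining (weighted by matches-mismatches)."""
    chains: list[list[Block]] = []
    remaining = sorted(blocks, key=lambda b: (b.q_start, b.g_start))
    while remaining:
        n = len(remaining)
        score = [b.matches - b.mismatches for b in remaining]
        back: list[int] = [-1] * n
        for j in range(n):
            bj = remaining[j]
            for i in range(j):
                bi = remaining[i]
                if (
                    bj.q_start > bi.q_end
                    and bj.g_start > bi.g_end
                    and bj.q_start - bi.q_end - 1 <= max_ref_gap
                    and bj.g_start - bi.g_end - 1 <= max_genome_gap
                ):
                    cand = score[i] + bj.matches - bj.mismatches
                    if cand > score[j]:
                        score[j] = cand
                        back[j] = i
        best_j = max(range(n), key=lambda j: score[j])
        chain_idx = []
        j = best_j
        while j != -1:
            chain_idx.append(j)
            j = back[j]
        chain_idx.reverse()
        chains.append([remaining[j] for j in chain_idx])
        used = set(chain_idx)
        remaining = [b for j, b in enumerate(remaining) if j not in used]
    return chains


def search(
    reference: ProviralReference,
    index: SeedIndex,
    genome: GenomeAssembly,
    min_seed_hits: int = 2,
    xdrop: int = 18,
    min_chain_matches: int = 50,
    min_block_matches: int = 25,
    max_ref_gap: int = 8000,
    max_genome_gap: int = 10000,
) -> list[AlignmentChain]:
    """Find reference-homologous chains on both strands of the genome.

    Seeds on the same (chromosome, diagonal) are required to occur at least
    ``min_seed_hits`` times before extension, which suppresses random k-mer
    matches in background sequence.  A chain must contain at least one
    block with ``min_block_matches`` matched bases: colinear chaining can
    otherwise accumulate scattered chance micro-matches into a spurious
    chain, while any genuine homologous segment extends into a long block.
    """
    k = index.k
    out: list[AlignmentChain] = []
    ref_len = len(reference)
    for strand in "+-":
        query = (
            reference.sequence
            if strand == "+"
            else reverse_complement(reference.sequence)
        )
        # 1. collect seed hits grouped by (chrom, diagonal)
        diagonals: dict[tuple[str, int], list[tuple[int, int]]] = {}
        for q0 in range(0, len(query) - k + 1):
            word = query[q0 : q0 + k]
            if "N" in word:
                continue
            for chrom, gpos1 in index.lookup(word):
                g0 = gpos1 - 1
                diagonals.setdefault((chrom, g0 - q0), []).append((q0, g0))
        # 2. ungapped extension per qualifying diagonal
        blocks_by_chrom: dict[str, list[Block]] = {}
        for (chrom, _diag), hits in diagonals.items():
            if len(hits) < min_seed_hits:
                continue
            target = genome.chromosomes[chrom]
            covered_to = -1
            for q0, g0 in sorted(hits):
                if q0 <= covered_to:
                    continue
                block = _extend_ungapped(query, target, q0, g0, k, xdrop)
                covered_to = block.q_end - 1
                blocks_by_chrom.setdefault(chrom, []).append(block)
        # 3. colinear chaining per chromosome
        for chrom, blocks in blocks_by_chrom.items():
            for chain_blocks in _chain_blocks(
                blocks, max_ref_gap, max_genome_gap
            ):
                matches = sum(b.matches for b in chain_blocks)
                mismatches = sum(b.mismatches for b in chain_blocks)
                if matches < min_chain_matches:
                    continue
                if max(b.matches for b in chain_blocks) < min_block_matches:
                    continue
                tuples = []
                for b in chain_blocks:
                    if strand == "+":
                        rs, re = b.q_start, b.q_end
                    else:
                        rs = ref_len - b.q_end + 1
                        re = ref_len - b.q_start + 1
                    tuples.append((b.g_start, b.g_end, rs, re))
                out.append(
                    AlignmentChain(
                        chrom=chrom,
                        strand=strand,
                        blocks=sorted(tuples),
                        matches=matches,
                        mismatches=mismatches,
                    )
                )
    out.sort(key=lambda c: (c.chrom, c.g_start, c.strand))
    return out


# ---------------------------------------------------------------------------
# Locus assembly, classification, naming
# ---------------------------------------------------------------------------

def classify_aligned_positions(
    aligned_ref_positions: Iterable[int],
    reference: ProviralReference,
    min_internal_bp: int = 20,
) -> str:
    """provirus iff at least ``min_internal_bp`` aligned bases fall in an
    internal region (gag..env); otherwise solo_LTR.

    Restricting the provirus criterion to the coding regions, with a small
    minimum, makes the call robust to a few bases of ungapped-extension
    overhang past an LTR boundary (env ends 2 bp before the 3'LTR starts
    in the canonical region map).
    """
    internal = [
        reference.regions[r]
        for r in ("gag", "pro", "pol", "env")
        if r in reference.regions
    ]
    internal_bp = 0
    for pos in aligned_ref_positions:
        for s, e in internal:
            if s <= pos <= e:
                internal_bp += 1
                break
        if internal_bp >= min_internal_bp:
            return "provirus"
    return "solo_LTR"


def _canonical_ltr_positions(
    positions: Iterable[int], reference: ProviralReference
) -> set[int]:
    """Aligned LTR positions folded onto 5'LTR coordinates.

    A solo LTR matches both reference LTRs when they are near-identical;
    folding 3'LTR coordinates onto the 5'LTR deduplicates that double
    alignment so solo coverage stays within [0, 100]%.
    """
    l5s, l5e = reference.regions["LTR5"]
    l3s, l3e = reference.regions["LTR3"]
    offset = l3s - l5s
    out: set[int] = set()
    for pos in positions:
        if l5s <= pos <= l5e:
            out.add(pos)
        elif l3s <= pos <= l3e:
            out.add(pos - offset)
    return out


def classify_locus(
    locus_chains: Sequence[AlignmentChain],
    reference: ProviralReference,
    min_internal_bp: int = 20,
) -> str:
    positions: set[int] = set()
    for c in locus_chains:
        positions.update(c.aligned_ref_positions)
    return classify_aligned_positions(positions, reference, min_internal_bp)


def merge_chains_to_loci(
    chains: Sequence[AlignmentChain],
    reference: ProviralReference,
    max_locus_gap: int = 10000,
) -> list[ElementLocus]:
    """Merge nearby chains into element loci and compute catalog metrics.

    Chains on one chromosome+strand merge when their genomic gap is at
    most ``max_locus_gap`` (an element fragmented by internal deletions or
    by the twin-LTR cross matches of a single integration is one locus).
    Opposite strands never merge.  Coverage is computed against the full
    reference for proviruses and against the 5'LTR (with 3'LTR positions
    folded onto it) for solo LTRs; Qgap is the unaligned reference span
    inside the locus, relative to aligned + gap bases, so terminal
    truncations do not count.
    """
    groups: dict[tuple[str, str], list[AlignmentChain]] = {}
    for c in chains:
        groups.setdefault((c.chrom, c.strand), []).append(c)
    loci: list[ElementLocus] = []
    for (chrom, strand), group in sorted(groups.items()):
        group = sorted(group, key=lambda c: c.g_start)
        merged: list[list[AlignmentChain]] = []
        for c in group:
            if merged:
                last = merged[-1]
                gap = c.g_start - max(x.g_end for x in last) - 1
                if gap <= max_locus_gap:
                    last.append(c)
                    continue
            merged.append([c])
        for group_chains in merged:
            positions: set[int] = set()
            matches = mismatches = 0
            for c in group_chains:
                positions.update(c.aligned_ref_positions)
                matches += c.matches
                mismatches += c.mismatches
            element_class = classify_aligned_positions(positions, reference)
            if element_class == "solo_LTR":
                folded = _canonical_ltr_positions(positions, reference)
                aligned = len(folded)
                basis = reference.region_length("LTR5")
                if folded:
                    r_lo, r_hi = min(folded), max(folded)
                    qgap = (r_hi - r_lo + 1) - aligned
                else:
                    qgap = 0
            else:
                aligned = len(positions)
                basis = len(reference)
                r_lo, r_hi = min(positions), max(positions)
                qgap = (r_hi - r_lo + 1) - aligned
            start = min(c.g_start for c in group_chains)
            end = max(c.g_end for c in group_chains)
            loci.append(
                ElementLocus(
                    locus_id=f"{chrom}:{start}-{end}({strand})",
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    element_class=element_class,
                    coverage_pct=100.0 * aligned / basis,
                    qgap_pct=100.0 * qgap / (aligned + qgap),
                    chains=list(group_chains),
                )
            )
    loci.sort(key=lambda l: (l.chrom, l.start, l.strand))
    return loci


def name_locus(
    locus: ElementLocus,
    cytobands: Optional[Mapping[str, IntervalTree]] = None,
) -> str:
    """Name by the cytoband containing the locus midpoint; coordinate fallback."""
    fallback = f"{locus.chrom}:{locus.start}-{locus.end}"
    if not cytobands or locus.chrom not in cytobands:
        return fallback
    hits = cytobands[locus.chrom][locus.midpoint]
    if not hits:
        logger.warning("midpoint of %s in no cytoband", fallback)
        return fallback
    return sorted(iv.data for iv in hits)[0]


def name_loci(
    loci: Sequence[ElementLocus],
    cytobands: Optional[Mapping[str, IntervalTree]] = None,
) -> None:
    for locus in loci:
        locus.name = name_locus(locus, cytobands)


def stratify_lengths(
    coverage_pcts: Iterable[float],
) -> tuple[int, int, int]:
    """Counts of elements with coverage >70%, 40-70%, and <40%."""
    gt70 = mid = lt40 = 0
    for c in coverage_pcts:
        if c > 70:
            gt70 += 1
        elif c >= 40:
            mid += 1
        else:
            lt40 += 1
    return gt70, mid, lt40


@dataclass
class ScreenResult:
    """Subsets passing the length screens used for downstream analyses."""

    solo_ltrs: list  # solo LTRs longer than the LTR threshold
    proviruses: list  # proviruses longer than the full-length threshold
    regions: dict[str, list]  # per-region sets above the region threshold


def screen_for_analysis(
    solo_pcts: Mapping[str, float],
    provirus_pcts: Mapping[str, float],
    region_integrity: Mapping[str, Mapping[str, float]],
    solo_threshold: float = 90.0,
    provirus_threshold: float = 80.0,
    region_threshold: float = 90.0,
) -> ScreenResult:
    """Apply the solo-LTR (>90% of LTR), provirus (>80% of reference) and
    per-region (>90% of the corresponding section) length screens.

    ``region_integrity`` maps element id -> region -> integrity percent.
    """
    solos = [k for k, v in solo_pcts.items() if v > solo_threshold]
    provs = [k for k, v in provirus_pcts.items() if v > provirus_threshold]
    regions: dict[str, list] = {}
    for eid, per_region in region_integrity.items():
        for region, pct in per_region.items():
            if pct > region_threshold:
                regions.setdefault(region, []).append(eid)
    return ScreenResult(solo_ltrs=solos, proviruses=provs, regions=regions)
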