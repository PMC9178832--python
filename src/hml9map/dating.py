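"""Divergence computation, consensus building, and molecular-clock dating.

Integration ages follow the neutral-clock relations used for LTR
retroelements: internal regions are dated against a group consensus with
T = D / 0.2 (D in percent per the 0.2%/nt/my rate), while LTR pairs are
dated with T = D / 0.2 / 2 because the two LTRs are identical at
integration and diverge independently afterwards.

The default divergence measure is the p-distance with pairwise deletion
of gapped/ambiguous columns; the Kimura two-parameter correction is
available as an option.  A deterministic neighbor-joining clusterer is
provided as a lightweight phylogenetic grouping tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

#: Neutral substitution rate, percent/nucleotide/million years.
CLOCK_RATE_PCT_PER_MY = 0.2

_VALID = set("ACGT")
_PURINES = set("AG")


class UndefinedDistanceError(ValueError):
    """No comparable sites between two sequences."""


class SaturationError(ValueError):
    """Distance correction undefined (log argument non-positive)."""


@dataclass
class DistanceResult:
    D: float
    sites_compared: int
    model: str  # p_distance | K2P
    P: Optional[float] = None  # transition fraction (K2P)
    Q: Optional[float] = None  # transversion fraction (K2P)


def _comparable_columns(a: str, b: str):
    if len(a) != len(b):
        raise ValueError("sequences must be pre-aligned to equal length")
    for x, y in zip(a.upper(), b.upper()):
        if x in _VALID and y in _VALID:
            yield x, y


def p_distance(seq_a: str, seq_b: str) -> DistanceResult:
    """Fraction of differing sites over columns where both bases are ACGT."""
    sites = diffs = 0
    for x, y in _comparable_columns(seq_a, seq_b):
        sites += 1
        if x != y:
            diffs += 1
    if sites == 0:
        raise UndefinedDistanceError("no comparable sites")
    return DistanceResult(D=diffs / sites, sites_compared=sites, model="p_distance")


def k2p_distance(seq_a: str, seq_b: str) -> DistanceResult:
    """Kimura two-parameter distance: D = -1/2 ln((1-2P-Q) sqrt(1-2Q))."""
    sites = ts = tv = 0
    for x, y in _comparable_columns(seq_a, seq_b):
        sites += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if sites == 0:
        raise UndefinedDistanceError("no comparable sites")
    P, Q = ts / sites, tv / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P undefined for P={P:.4f}, Q={Q:.4f}")
    D = -0.5 * math.log(w1 * math.sqrt(w2))
    return DistanceResult(D=D, sites_compared=sites, model="K2P", P=P, Q=Q)


def build_consensus(
    aligned_set: Sequence[str],
    reference: Optional[str] = None,
) -> str:
    """Majority-rule consensus of pre-aligned sequences.

    Per column the most frequent base wins; a gap wins only when gaps
    exceed half the sequences.  Base ties are broken by the reference base
    at that column when provided (and tied), else alphabetically.
    """
    if len(aligned_set) < 2:
        raise ValueError("consensus requires >= 2 sequences")
    length = len(aligned_set[0])
    if any(len(s) != length for s in aligned_set):
        raise ValueError("aligned sequences must have equal length")
    if length == 0:
        raise ValueError("empty columns")
    if reference is not None and len(reference) != length:
        raise ValueError("reference must match alignment length")
    out = []
    for i in range(length):
        column = [s[i].upper() for s in aligned_set]
        n = len(column)
        gaps = column.count("-")
        if gaps > n / 2:
            out.append("-")
            continue
        counts: dict[str, int] = {}
        for c in column:
            if c in _VALID:
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append("-")
            continue
        best = max(counts.values())
        tied = sorted(c for c, k in counts.items() if k == best)
        if len(tied) > 1 and reference is not None:
            ref_base = reference[i].upper()
            if ref_base in tied:
                out.append(ref_base)
                continue
        out.append(tied[0])
    return "".join(out)


# ---------------------------------------------------------------------------
# Clock dating
# ---------------------------------------------------------------------------

def age_from_divergence(
    D: float, rate_pct: float = CLOCK_RATE_PCT_PER_MY, paired_ltr: bool = False
) -> float:
    """T = D / rate (internal regions) or T = D / rate / 2 (LTR pairs).

    ``D`` is a fraction of divergent nucleotides; the returned age is in
    million years (D is converted to percent before dividing by the
    percent-scale rate).
    """
    t = (D * 100.0) / rate_pct
    return t / 2.0 if paired_ltr else t


def date_internal(
    region_Ds: Mapping[str, Optional[float]],
    rate_pct: float = CLOCK_RATE_PCT_PER_MY,
) -> tuple[Optional[float], Optional[float]]:
    """Mean of available per-region divergences and the implied age.

    NA regions are skipped; all-NA input yields (None, None).  The mean is
    taken over unrounded per-region values.
    """
    values = [d for d in region_Ds.values() if d is not None and not (
        isinstance(d, float) and math.isnan(d)
    )]
    if not values:
        return None, None
    mean_d = sum(values) / len(values)
    return mean_d, age_from_divergence(mean_d, rate_pct)


def date_ltr_pair(
    ltr5_seq: str,
    ltr3_seq: str,
    rate_pct: float = CLOCK_RATE_PCT_PER_MY,
    model: str = "p_distance",
) -> tuple[Optional[float], Optional[float]]:
    """Divergence between the two LTRs of a provirus and the implied age.

    The inputs are expected gapped onto a shared LTR coordinate system
    (equal lengths).  Returns (None, None) when there is nothing to
    compare, mirroring NA propagation in report tables.
    """
    if not ltr5_seq or not ltr3_seq:
        return None, None
    dist = p_distance if model == "p_distance" else k2p_distance
    try:
        res = dist(ltr5_seq, ltr3_seq)
    except UndefinedDistanceError:
        return None, None
    return res.D, age_from_divergence(res.D, rate_pct, paired_ltr=True)


@dataclass
class DivergenceRecord:
    """Dated element: per-region divergences plus LTR-pair dating."""

    locus_id: str
    region_D: dict[str, Optional[float]]
    mean_region_D: Optional[float]
    age_internal_my: Optional[float]
    ltr_pair_D: Optional[float]
    age_ltr_my: Optional[float]
    rate_pct: float = CLOCK_RATE_PCT_PER_MY


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_cluster(
    distance_matrix: np.ndarray, labels: Optional[Sequence[str]] = None
) -> str:
    """Neighbor-joining agglomeration; returns an unrooted tree in newick.

    Ties in the Q criterion are broken by the lowest (i, j) index pair, so
    the output is deterministic.  The input must be symmetric with a zero
    diagonal.
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have zero diagonal")
    if labels is None:
        labels = [f"t{i}" for i in range(n)]
    labels = list(labels)
    if n == 1:
        return labels[0] + ";"
    if n == 2:
        return f"({labels[0]}:{d[0, 1] / 2:.6f},{labels[1]}:{d[0, 1] / 2:.6f});"
    nodes = labels[:]
    dm = d.copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = dm[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = sub[a, b]
        li = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_label = f"({nodes[i]}:{li:.6f},{nodes[j]}:{lj:.6f})"
        # distances from the new node to the remaining ones
        new_row = np.zeros(dm.shape[0] + 1)
        for c in range(m):
            kk = active[c]
            if kk in (i, j):
                continue
            new_row[kk] = 0.5 * (dm[i, kk] + dm[j, kk] - dij)
        dm = np.pad(dm, ((0, 1), (0, 1)))
        dm[-1, :-1] = new_row[:-1]
        dm[:-1, -1] = new_row[:-1]
        nodes.append(new_label)
        active = [x for x in active if x not in (i, j)] + [dm.shape[0] - 1]
    i, j = active
    dij = dm[i, j]
    return f"({nodes[i]}:{dij / 2:.6f},{nodes[j]}:{dij / 2:.6f});"


def newick_bipartitions(newick: str) -> list[frozenset[str]]:
    """Leaf-set bipartitions (one side each) of a newick tree; for tests."""
    import re

    stripped = re.sub(r":[0-9.eE+-]+", "", newick)
    tokens = re.findall(r"\(|\)|,|[^(),;]+", stripped)
    stack: list[list[set[str]]] = []
    clades: list[set[str]] = []
    current: list[set[str]] = []
    for tok in tokens:
        if tok == "(":
            stack.append(current)
            current = []
        elif tok == ")":
            merged = set().union(*current) if current else set()
            clades.append(merged)
            current = stack.pop()
            current.append(merged)
        elif tok == ",":
            continue
        else:
            name = tok.split(":")[0]
            if name:
                current.append({name})
    return [frozenset(c) for c in clades]
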