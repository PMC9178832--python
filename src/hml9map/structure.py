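"""Element-to-reference alignment and per-region integrity annotation.

An element is aligned to the proviral reference with an affine-gap
semi-global alignment (free end gaps, so terminal truncations are not
penalized and are excluded from Qgap).  Integrity of a region is the
percentage of its reference positions aligned to an element base - a
presence measure, deliberately independent of sequence identity, so that
an old but complete region still scores near 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from Bio import Align

from .io_formats import ProviralReference, REGION_NAMES

MATCH = 0
MISMATCH = 1
ELEMENT_GAP = 2  # deletion relative to the reference
REFERENCE_GAP = 3  # insertion relative to the reference

AMBIGUOUS = set("NRYSWKMBDHV")


@dataclass
class PairwiseAlignment:
    """A column-classified global alignment of an element to the reference."""

    aligned_element: str
    aligned_reference: str
    columns: np.ndarray  # per-column class codes
    ref_positions: np.ndarray  # 1-based ref position per column (0 in ref gaps)

    def __post_init__(self) -> None:
        if len(self.aligned_element) != len(self.aligned_reference):
            raise ValueError("aligned strings must have equal length")

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def element_sequence(self) -> str:
        return self.aligned_element.replace("-", "")

    @property
    def reference_sequence(self) -> str:
        return self.aligned_reference.replace("-", "")

    def counts(self) -> dict[int, int]:
        vals, cnts = np.unique(self.columns, return_counts=True)
        out = {MATCH: 0, MISMATCH: 0, ELEMENT_GAP: 0, REFERENCE_GAP: 0}
        out.update(dict(zip(vals.tolist(), cnts.tolist())))
        return out

    @property
    def internal_span(self) -> tuple[int, int]:
        """Column range [lo, hi] between the first and last aligned base."""
        aligned = np.nonzero(
            (self.columns == MATCH) | (self.columns == MISMATCH)
        )[0]
        if len(aligned) == 0:
            raise ValueError("alignment has no aligned columns")
        return int(aligned[0]), int(aligned[-1])


@dataclass
class RegionIntegrity:
    """Per-region integrity percentages for one element."""

    locus_id: str
    integrity: dict[str, float]  # region -> percent [0, 100]


@dataclass
class Indel:
    """An insertion or deletion in reference coordinates."""

    kind: str  # deletion | insertion | truncation
    ref_start: int
    ref_end: int  # for insertions, the flanking ref position on both fields
    length: int
    regions: tuple[str, ...]


def _make_aligner(
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -12.0,
    gap_extend: float = -1.0,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps on both sides: fragments and flank-carrying elements
    aligner.end_gap_score = 0.0
    return aligner


def align_to_reference(
    element_seq: str,
    reference: ProviralReference,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> PairwiseAlignment:
    """Affine-gap semi-global alignment of an element to the reference.

    Ambiguous bases are scored as mismatches.  The first optimal alignment
    reported by the dynamic program is used, which is deterministic.
    """
    element_seq = element_seq.upper()
    if len(element_seq) < 50:
        raise ValueError("element must be >= 50 bp")
    if aligner is None:
        aligner = _make_aligner()
    # aligner works on plain ACGT; map ambiguity codes to N (mismatch to all)
    clean = "".join("N" if c in AMBIGUOUS else c for c in element_seq)
    alignment = aligner.align(reference.sequence, clean)[0]
    ref_aln, elem_aln = str(alignment[0]), str(alignment[1])
    n = len(ref_aln)
    columns = np.empty(n, dtype=np.int8)
    ref_positions = np.zeros(n, dtype=np.int64)
    rpos = 0
    for i, (r, e) in enumerate(zip(ref_aln, elem_aln)):
        if r != "-":
            rpos += 1
            ref_positions[i] = rpos
        if r == "-":
            columns[i] = REFERENCE_GAP
        elif e == "-":
            columns[i] = ELEMENT_GAP
        elif r == e and e != "N":
            columns[i] = MATCH
        else:
            columns[i] = MISMATCH
    return PairwiseAlignment(
        aligned_element=elem_aln,
        aligned_reference=ref_aln,
        columns=columns,
        ref_positions=ref_positions,
    )


def annotate_regions(
    alignment: PairwiseAlignment,
    regions: Mapping[str, tuple[int, int]],
    locus_id: str = "",
) -> tuple[RegionIntegrity, list[Indel]]:
    """Per-region integrity plus a region-tagged indel list.

    Integrity of a region is 100 x (aligned reference positions in the
    region) / (region length).  Terminal element-gap runs are reported as
    truncations, internal runs as deletions; reference-gap runs are
    insertions located at the reference position preceding them.
    """
    cols = alignment.columns
    refpos = alignment.ref_positions
    aligned_mask = (cols == MATCH) | (cols == MISMATCH)
    aligned_positions = set(refpos[aligned_mask].tolist())
    integrity = {}
    for rname in REGION_NAMES:
        if rname not in regions:
            continue
        s, e = regions[rname]
        length = e - s + 1
        count = sum(1 for p in range(s, e + 1) if p in aligned_positions)
        integrity[rname] = 100.0 * count / length
    # indel runs
    indels: list[Indel] = []
    lo, hi = alignment.internal_span

    def regions_of_interval(rs: int, re_: int) -> tuple[str, ...]:
        out = []
        for rname in REGION_NAMES:
            if rname not in regions:
                continue
            s, e = regions[rname]
            if not (re_ < s or rs > e):
                out.append(rname)
        return tuple(out)

    i = 0
    n = len(cols)
    while i < n:
        c = cols[i]
        if c in (ELEMENT_GAP, REFERENCE_GAP):
            j = i
            while j + 1 < n and cols[j + 1] == c:
                j += 1
            if c == ELEMENT_GAP:
                rs, re_ = int(refpos[i]), int(refpos[j])
                kind = "deletion" if (i > lo and j < hi) else "truncation"
                indels.append(
                    Indel(
                        kind=kind,
                        ref_start=rs,
                        ref_end=re_,
                        length=j - i + 1,
                        regions=regions_of_interval(rs, re_),
                    )
                )
            else:
                prev_ref = int(refpos[:i].max()) if i > 0 else 0
                indels.append(
                    Indel(
                        kind="insertion",
                        ref_start=prev_ref,
                        ref_end=prev_ref,
                        length=j - i + 1,
                        regions=regions_of_interval(prev_ref, prev_ref),
                    )
                )
            i = j + 1
        else:
            i += 1
    return RegionIntegrity(locus_id=locus_id, integrity=integrity), indels


def coverage_metrics(
    alignment: PairwiseAlignment, reference_length: Optional[int] = None
) -> tuple[float, float]:
    """Catalog coverage metrics from one alignment.

    coverage_pct = 100 x (match + mismatch columns) / reference length;
    qgap_pct counts only element-gap columns strictly inside the aligned
    span (terminal truncations are free).
    """
    counts = alignment.counts()
    aligned = counts[MATCH] + counts[MISMATCH]
    if reference_length is None:
        reference_length = len(alignment.reference_sequence)
    lo, hi = alignment.internal_span
    inner = alignment.columns[lo : hi + 1]
    qgap = int(np.count_nonzero(inner == ELEMENT_GAP))
    coverage_pct = 100.0 * aligned / reference_length
    qgap_pct = 100.0 * qgap / (aligned + qgap) if aligned + qgap else 0.0
    return coverage_pct, qgap_pct


def extract_region_sequences(
    alignment: PairwiseAlignment,
    regions: Mapping[str, tuple[int, int]],
) -> dict[str, str]:
    """Element sequence per region, gapped onto reference coordinates.

    For each region the returned string has exactly one character per
    reference position (element base, or ``-`` where the element has no
    aligned base); insertions relative to the reference are dropped.  All
    elements extracted this way share the reference coordinate system, so
    they are directly comparable column-by-column.
    """
    cols = alignment.columns
    refpos = alignment.ref_positions
    by_pos: dict[int, str] = {}
    for i in range(len(cols)):
        if cols[i] == MATCH or cols[i] == MISMATCH:
            by_pos[int(refpos[i])] = alignment.aligned_element[i]
    out = {}
    for rname, (s, e) in regions.items():
        out[rname] = "".join(by_pos.get(p, "-") for p in range(s, e + 1))
    return out
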