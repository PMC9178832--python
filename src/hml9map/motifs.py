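"""PWM scanning at a relative-score threshold, and PBS typing.

Motif hits are reported when the log-odds score of a window, rescaled
between the minimum and maximum attainable matrix scores, reaches the
relative profile score threshold (default 95%); both strands are scanned
and antisense hits are reported in plus-strand coordinates.

The primer binding site (PBS) of a provirus is the ~18 nt stretch a few
nucleotides downstream of the 5'LTR that is complementary to the 3' end
of a host tRNA; the best-matching tRNA names the element's PBS type.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .synthetic import reverse_complement

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

DEFAULT_PSEUDOCOUNT_TOTAL = 0.8
DEFAULT_THRESHOLD = 0.95
PBS_LENGTH = 18
PBS_WINDOW = (1, 30)


@dataclass
class PWM:
    """A position weight matrix with background and pseudocount handling."""

    matrix_id: str
    counts: np.ndarray  # 4 x L (A, C, G, T)
    background: np.ndarray = None
    pseudocount_total: float = DEFAULT_PSEUDOCOUNT_TOTAL

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def probabilities(self) -> np.ndarray:
        """Column-normalized probabilities with background-proportional
        pseudocounts (``pseudocount_total`` distributed per column)."""
        pseudo = self.background[:, None] * self.pseudocount_total
        padded = self.counts + pseudo
        return padded / padded.sum(axis=0, keepdims=True)

    def log_odds(self) -> np.ndarray:
        """4 x L log2(p / background) scoring matrix."""
        return np.log2(self.probabilities() / self.background[:, None])

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probabilities().argmax(axis=0))

    @classmethod
    def from_jaspar(cls, path: str | Path) -> list["PWM"]:
        """Read matrices from JASPAR-format text (pfm/jaspar layout)."""
        from Bio import motifs

        with open(path) as fh:
            parsed = motifs.parse(fh, "jaspar")
        out = []
        for m in parsed:
            counts = np.array([m.counts[b] for b in _BASES], dtype=float)
            name = m.matrix_id or m.name
            out.append(cls(matrix_id=name, counts=counts))
        return out


@dataclass
class MotifHit:
    matrix_id: str
    position: int  # 1-based start on plus-strand coordinates
    strand: str
    score: float
    relative_score: float


def _encode(sequence: str) -> np.ndarray:
    """Map bases to 0..3, ambiguous characters to 4."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    out = np.full(len(sequence), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def scan(
    pwm: PWM,
    sequence: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[MotifHit]:
    """Scan both strands; report hits with relative score >= threshold.

    The relative score of a window is (S - S_min) / (S_max - S_min) with
    S_min/S_max the minimum/maximum attainable matrix scores.  Ambiguous
    bases contribute a log-odds of 0 (scored at background probability).
    A matrix with S_max == S_min is degenerate: every window scores
    relative 1.0 and a warning is emitted.
    """
    L = pwm.length
    if len(sequence) < L:
        raise ValueError("sequence shorter than the matrix")
    lods = pwm.log_odds()
    smin = float(lods.min(axis=0).sum())
    smax = float(lods.max(axis=0).sum())
    degenerate = math.isclose(smin, smax)
    if degenerate:
        logger.warning("PWM %s is degenerate (flat score range)", pwm.matrix_id)
    # row 4 = ambiguous base, log-odds 0
    lods5 = np.vstack([lods, np.zeros((1, L))])
    seq = sequence.upper()
    n = len(seq)
    hits: list[MotifHit] = []
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        enc = _encode(s)
        n_windows = n - L + 1
        scores = np.zeros(n_windows)
        for j in range(L):
            scores += lods5[enc[j : j + n_windows], j]
        for i, sc in enumerate(scores):
            rel = 1.0 if degenerate else (sc - smin) / (smax - smin)
            if rel >= threshold:
                if strand == "+":
                    pos = i + 1
                else:
                    pos = n - (i + L) + 1
                hits.append(
                    MotifHit(
                        matrix_id=pwm.matrix_id,
                        position=pos,
                        strand=strand,
                        score=float(sc),
                        relative_score=float(rel),
                    )
                )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


# ---------------------------------------------------------------------------
# PBS extraction and typing
# ---------------------------------------------------------------------------

@dataclass
class PBSCall:
    locus_id: str
    found: bool
    pbs_seq: str = ""
    offset: int = 0  # nt downstream of the 5'LTR end to the PBS start
    trna_id: str = ""
    trna_type: str = ""
    identity: float = 0.0


def trna_type_from_id(trna_id: str) -> str:
    """Extract the amino-acid type from a tRNA identifier.

    Accepts common id shapes such as ``tRNA-Lys-TTT-1-1`` or
    ``Lys-tRNA-...``; falls back to the whole id.
    """
    parts = trna_id.replace("_", "-").split("-")
    for i, p in enumerate(parts):
        if p.lower() == "trna":
            if i + 1 < len(parts) and parts[i + 1].isalpha():
                return parts[i + 1]
            if i > 0 and parts[i - 1].isalpha():
                return parts[i - 1]
    return trna_id


def _identity(a: str, b: str) -> float:
    return sum(1 for x, y in zip(a, b) if x == y) / len(a)


def extract_pbs(
    provirus_seq: str,
    ltr5_end: int,
    trna_lib: Sequence[tuple[str, str]],
    window: tuple[int, int] = PBS_WINDOW,
    pbs_len: int = PBS_LENGTH,
    min_identity: float = 12 / 18,
    locus_id: str = "",
) -> PBSCall:
    """Locate the PBS downstream of the 5'LTR and type it by tRNA.

    Every window start offset in ``window`` (nt downstream of the LTR end)
    is compared against the reverse complement of each tRNA's 3'-terminal
    ``pbs_len``-mer; the best identity wins, ties broken by smaller
    offset then library order.  Best identity below ``min_identity``
    reports the PBS as not found; the default floor of 12/18 keeps the
    false-discovery rate of random sequence low (a 9/18 match arises by
    chance in almost every 30-offset window against a small library).
    """
    if not trna_lib:
        raise ValueError("tRNA library is empty")
    seq = provirus_seq.upper()
    lo, hi = window
    if len(seq) < ltr5_end + hi + pbs_len:
        hi = len(seq) - ltr5_end - pbs_len
        if hi < lo:
            return PBSCall(locus_id=locus_id, found=False)
    targets = [
        (name, reverse_complement(s.upper()[-pbs_len:])) for name, s in trna_lib
    ]
    best: Optional[tuple[float, int, int]] = None  # (identity, offset, lib idx)
    for offset in range(lo, hi + 1):
        start0 = ltr5_end + offset - 1  # 0-based start of candidate
        candidate = seq[start0 : start0 + pbs_len]
        if len(candidate) < pbs_len:
            break
        for idx, (_, target) in enumerate(targets):
            ident = _identity(candidate, target)
            key = (-ident, offset, idx)
            if best is None or key < best[0]:
                best = (key, candidate)
    (neg_ident, offset, idx), candidate = best
    identity = -neg_ident
    if identity < min_identity:
        return PBSCall(locus_id=locus_id, found=False)
    trna_id = trna_lib[idx][0]
    return PBSCall(
        locus_id=locus_id,
        found=True,
        pbs_seq=candidate,
        offset=offset,
        trna_id=trna_id,
        trna_type=trna_type_from_id(trna_id),
        identity=identity,
    )


@dataclass
class PBSProfile:
    """Conservation profile of an aligned PBS set."""

    counts: np.ndarray  # 4 x L base counts
    frequencies: np.ndarray  # 4 x L
    information_content: np.ndarray  # bits per position, IC = 2 - H
    consensus: str
    n_sequences: int


def pbs_logo(pbs_seqs: Sequence[str], length: int = PBS_LENGTH) -> PBSProfile:
    """Per-position conservation of a PBS set (logo matrix).

    IC_i = 2 - H_i with H the Shannon entropy (log2) of the base
    frequencies at position i; consensus is the modal base, ties broken
    alphabetically.
    """
    if not pbs_seqs:
        raise ValueError("no PBS sequences")
    if any(len(s) != length for s in pbs_seqs):
        raise ValueError(f"all PBS sequences must be {length} nt")
    counts = np.zeros((4, length))
    for s in pbs_seqs:
        for i, c in enumerate(s.upper()):
            if c in _BASE_INDEX:
                counts[_BASE_INDEX[c], i] += 1
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("column with no unambiguous bases")
    freqs = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(freqs > 0, np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    entropy = -(freqs * logs).sum(axis=0)
    ic = 2.0 - entropy
    consensus = "".join(_BASES[int(freqs[:, i].argmax())] for i in range(length))
    return PBSProfile(
        counts=counts,
        frequencies=freqs,
        information_content=ic,
        consensus=consensus,
        n_sequences=len(pbs_seqs),
    )


def write_logo_matrix(profile: PBSProfile, path: str | Path) -> None:
    """Export the logo matrix as TSV (position x A, C, G, T, IC)."""
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\tIC\n")
        for i in range(profile.frequencies.shape[1]):
            freqs = "\t".join(
                f"{profile.frequencies[j, i]:.4f}" for j in range(4)
            )
            fh.write(f"{i + 1}\t{freqs}\t{profile.information_content[i]:.4f}\n")
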