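"""E-box and position-weight-matrix motif scanning of candidate enhancers.

Myogenic regulatory factors (MYOD, MYOG and relatives) bind the degenerate
E-box element CANNTG; `ebox_scan` enumerates its occurrences.  `pwm_score`
scores a JASPAR-style position probability matrix against a sequence with a
fully specified log-odds scheme:

    score(bits) = sum_j log2( (p_bj + c * bg_b) / ((1 + c) * bg_b) )

with pseudocount c (default 0.01) and uniform background; an N in the
sequence contributes 0 at its position.  Hits above 80% of the maximum
attainable score are reported, and `rank_motifs` ranks a PWM collection by
best score across a set of candidate sequences.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
THRESHOLD_FRACTION = 0.8


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int
    strand: str
    score: float


@dataclass
class PWM:
    """A position probability matrix (rows A, C, G, T)."""

    name: str
    matrix: np.ndarray  # shape (4, L)
    pseudocount: float = 0.01
    background: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError("PWM matrix must be 4 x L with L >= 1")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-3):
            raise ValueError("PWM columns must each sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        """4 x L log-odds matrix in bits (pseudocount-smoothed)."""
        bg = np.asarray(self.background, dtype=float)[:, None]
        c = self.pseudocount
        with np.errstate(divide="ignore"):  # -inf is correct at p=0, c=0
            return np.log2((self.matrix + c * bg) / ((1 + c) * bg))

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray, **kwargs) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(name, counts / counts.sum(axis=0, keepdims=True), **kwargs)


def parse_jaspar(path) -> List[PWM]:
    """Read JASPAR-style plain-text matrices (count or probability)."""
    from Bio import motifs as bio_motifs

    out: List[PWM] = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            out.append(PWM.from_counts(m.name or m.matrix_id or "motif", counts))
    return out


_EBOX_FWD = re.compile(r"(?=(CA[ACGTN]{2}TG))")


def ebox_scan(sequence: str, sequence_id: str = "seq") -> List[MotifHit]:
    """All occurrences of the E-box CANNTG (both strands).

    The pattern class CANNTG is its own reverse complement, so forward and
    reverse occurrences coincide; each position is reported once, strand "+".
    """
    seq = sequence.upper()
    return [
        MotifHit(sequence_id, m.start(), "+", 0.0)
        for m in _EBOX_FWD.finditer(seq)
    ]


def _scores_one_strand(seq: str, lo: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset of `seq` (N contributes 0)."""
    L = lo.shape[1]
    idx = np.fromiter((_BASE_INDEX.get(c, 4) for c in seq), dtype=np.int64, count=len(seq))
    lo5 = np.vstack([lo, np.zeros(L)])  # row 4 = N
    n_off = len(seq) - L + 1
    scores = np.zeros(n_off)
    for j in range(L):
        scores += lo5[idx[j : j + n_off], j]
    return scores


def pwm_score(
    sequence: str,
    pwm: PWM,
    sequence_id: str = "seq",
    threshold_fraction: float = THRESHOLD_FRACTION,
) -> Tuple[MotifHit, List[MotifHit]]:
    """Best hit and all above-threshold hits of a PWM on both strands.

    The threshold is `threshold_fraction` of the maximum attainable score.
    Ties for best hit are broken by strand (+ first) then smaller offset.
    """
    seq = sequence.upper()
    L = pwm.length
    if len(seq) < L:
        raise ValueError(f"sequence shorter than motif ({len(seq)} < {L})")
    lo = pwm.log_odds()
    fwd = _scores_one_strand(seq, lo)
    rc = reverse_complement(seq)
    rev = _scores_one_strand(rc, lo)
    n_off = len(seq) - L + 1
    threshold = threshold_fraction * pwm.max_score()

    hits: List[MotifHit] = []
    for strand, scores in (("+", fwd), ("-", rev)):
        for o in np.nonzero(scores >= threshold)[0]:
            offset = int(o) if strand == "+" else n_off - 1 - int(o)
            hits.append(MotifHit(sequence_id, offset, strand, float(scores[o])))
    hits.sort(key=lambda h: (-h.score, h.strand, h.offset))

    best_f = int(np.argmax(fwd))
    best_r = int(np.argmax(rev))
    if fwd[best_f] >= rev[best_r]:
        best = MotifHit(sequence_id, best_f, "+", float(fwd[best_f]))
    else:
        best = MotifHit(sequence_id, n_off - 1 - best_r, "-", float(rev[best_r]))
    return best, hits


def rank_motifs(
    candidates: Mapping[str, str],
    pwms: Sequence[PWM],
    threshold_fraction: float = THRESHOLD_FRACTION,
) -> pd.DataFrame:
    """Per-PWM best score and above-threshold hit count across candidates.

    Sorted by best score descending, ties by PWM name.
    """
    if not candidates or not pwms:
        raise ValueError("need at least one candidate sequence and one PWM")
    rows = []
    for pwm in pwms:
        best_score = -math.inf
        best_candidate = ""
        n_hits = 0
        for cid in sorted(candidates):
            seq = candidates[cid]
            if len(seq) < pwm.length:
                continue
            best, hits = pwm_score(seq, pwm, cid, threshold_fraction)
            n_hits += len(hits)
            if best.score > best_score:
                best_score, best_candidate = best.score, cid
        rows.append(
            {
                "pwm": pwm.name,
                "max_score": best_score if best_score > -math.inf else float("nan"),
                "n_hits": n_hits,
                "best_candidate": best_candidate,
                "max_attainable": pwm.max_score(),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["max_score", "pwm"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
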