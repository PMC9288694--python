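"""Candidate active-enhancer screening.

An interaction site becomes a candidate enhancer when it is (1) on the
viewpoint chromosome, (2) simultaneously covered (>= 1 bp, half-open) by an
H3K27ac peak and an ATAC peak, and (3) not overlapping any annotated
promoter.  Surviving adjacent windows are merged into regions, and each
region is reduced to the window of at most 1000 bp with the maximum
integrated ATAC signal — the candidate active enhancer.  Candidates are then
annotated for overlap with conserved elements.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

WIDTH_CAP = 1_000


@dataclass
class CandidateEnhancer:
    chrom: str
    start: int
    end: int
    source_region: Tuple[int, int]  # merged interaction region (start, end)
    summit_signal: float  # integrated ATAC signal inside the candidate window
    h3k27ac_ids: List[str] = field(default_factory=list)
    atac_ids: List[str] = field(default_factory=list)
    conserved: Optional[bool] = None
    zero_summit: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _trees(peaks: pd.DataFrame) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for chrom, sub in peaks.groupby("chrom"):
        t = IntervalTree()
        for i, row in enumerate(sub.itertuples(index=False)):
            name = getattr(row, "name", None)
            t[int(row.start) : int(row.end)] = name if name is not None else f"{chrom}:{row.start}"
        trees[chrom] = t
    return trees


def _overlapping(trees: Dict[str, IntervalTree], chrom: str, start: int, end: int) -> List[str]:
    if chrom not in trees or start >= end:
        return []
    return sorted(str(iv.data) for iv in trees[chrom][start:end])


class SignalTrack:
    """A step function over a genome, built from bedGraph-style runs."""

    def __init__(self, runs: pd.DataFrame):
        self._by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in runs.groupby("chrom"):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping signal runs on {chrom}")
            vals = sub["value"].to_numpy(dtype=float)
            if not np.isfinite(vals).all() or (vals < 0).any():
                raise ValueError("signal values must be finite and >= 0")
            self._by_chrom[chrom] = (starts, ends, vals)

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Integrated signal (value x covered bp) over [start, end)."""
        if chrom not in self._by_chrom or start >= end:
            return 0.0
        starts, ends, vals = self._by_chrom[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum(vals[lo:hi] * np.maximum(e - s, 0)))

    def breakpoints(self, chrom: str, start: int, end: int) -> np.ndarray:
        if chrom not in self._by_chrom:
            return np.array([], dtype=np.int64)
        starts, ends, _ = self._by_chrom[chrom]
        pts = np.concatenate([starts, ends])
        return pts[(pts > start) & (pts < end)]


def max_signal_window(
    signal: SignalTrack,
    chrom: str,
    start: int,
    end: int,
    width_cap: int = WIDTH_CAP,
) -> Tuple[int, int, float, bool]:
    """The window of length <= `width_cap` inside [start, end) maximising
    integrated signal; ties broken by the leftmost start.

    Returns (window start, window end, integrated signal, zero_summit flag);
    a region with no signal yields the leftmost window, flagged.
    """
    if start >= end:
        raise ValueError("empty region")
    if width_cap <= 0:
        raise ValueError("width_cap must be positive")
    width = min(width_cap, end - start)
    last = end - width
    # the integrated-signal objective is piecewise linear in the window start,
    # with kinks only where a window edge crosses a run boundary
    bp = signal.breakpoints(chrom, start, end)
    cand = np.unique(np.clip(np.concatenate([[start, last], bp, bp - width]), start, last))
    best_s, best_v = int(start), -1.0
    for s in cand:
        v = signal.integral(chrom, int(s), int(s) + width)
        if v > best_v + 1e-12:
            best_s, best_v = int(s), v
    zero = best_v <= 0.0
    if zero:
        best_s = int(start)
        best_v = 0.0
    return best_s, best_s + width, best_v, zero


def merge_windows(windows: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge abutting or overlapping (start, end) intervals."""
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(windows):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def screen(
    interactions: pd.DataFrame,
    h3k27ac: pd.DataFrame,
    atac: pd.DataFrame,
    promoters: pd.DataFrame,
    atac_signal: "SignalTrack | pd.DataFrame",
    viewpoint_chrom: str,
    width_cap: int = WIDTH_CAP,
) -> List[CandidateEnhancer]:
    """Run the enhancer screen on a set of (high-fidelity) interaction windows.

    Pipeline order: drop interchromosomal sites; keep sites overlapping
    >= 1 bp of both an H3K27ac and an ATAC peak; drop sites overlapping any
    promoter; merge adjacent survivors into regions; emit the maximum-ATAC-
    signal window (<= `width_cap` bp) of each region as one candidate.
    """
    for name, obj in [("interactions", interactions), ("h3k27ac", h3k27ac),
                      ("atac", atac), ("promoters", promoters), ("atac_signal", atac_signal)]:
        if obj is None:
            raise ValueError(f"missing required input: {name}")
    if isinstance(atac_signal, pd.DataFrame):
        atac_signal = SignalTrack(atac_signal)
    if interactions.empty:
        return []
    k27_t, atac_t, prom_t = _trees(h3k27ac), _trees(atac), _trees(promoters)

    surviving: List[Tuple[int, int]] = []
    for row in interactions.itertuples(index=False):
        if row.chrom != viewpoint_chrom:
            continue
        s, e = int(row.start), int(row.end)
        if not _overlapping(k27_t, row.chrom, s, e):
            continue
        if not _overlapping(atac_t, row.chrom, s, e):
            continue
        if _overlapping(prom_t, row.chrom, s, e):
            continue
        surviving.append((s, e))

    candidates: List[CandidateEnhancer] = []
    for rs, re_ in merge_windows(surviving):
        ws, we, val, zero = max_signal_window(atac_signal, viewpoint_chrom, rs, re_, width_cap)
        candidates.append(
            CandidateEnhancer(
                chrom=viewpoint_chrom,
                start=ws,
                end=we,
                source_region=(rs, re_),
                summit_signal=val,
                h3k27ac_ids=_overlapping(k27_t, viewpoint_chrom, ws, we),
                atac_ids=_overlapping(atac_t, viewpoint_chrom, ws, we),
                zero_summit=zero,
            )
        )
    return candidates


def annotate_conservation(
    candidates: List[CandidateEnhancer], conserved: pd.DataFrame
) -> Tuple[List[CandidateEnhancer], float]:
    """Flag candidates overlapping (>= 1 bp) a conserved element; return fraction."""
    trees = _trees(conserved) if len(conserved) else {}
    n_cons = 0
    for c in candidates:
        c.conserved = bool(_overlapping(trees, c.chrom, c.start, c.end))
        n_cons += int(c.conserved)
    frac = n_cons / len(candidates) if candidates else 0.0
    return candidates, frac


_SPAN_RE = re.compile(
    r"^\s*(?P<chrom>[\w.]+)\s*:\s*(?P<start>[\d,]+)\s*[–—-]\s*(?P<end>[\d,]+)\s*$"
)


def region_width(span: str) -> Tuple[int, int]:
    """Width of a printed genomic span like "chr11:67,104,519-67,142,456".

    Accepts comma thousands separators and hyphen/en-dash/em-dash range
    separators.  Returns (width in bp, width rounded to the nearest kb).
    """
    m = _SPAN_RE.match(span)
    if not m:
        raise ValueError(f"unparseable genomic span: {span!r}")
    start = int(m["start"].replace(",", ""))
    end = int(m["end"].replace(",", ""))
    if end <= start:
        raise ValueError(f"degenerate span (end <= start): {span!r}")
    width = end - start
    return width, round(width / 1000)


def candidates_to_frame(candidates: List[CandidateEnhancer]) -> pd.DataFrame:
    rows = [
        {
            "chrom": c.chrom,
            "start": c.start,
            "end": c.end,
            "name": f"candidate_{i}",
            "summit_signal": c.summit_signal,
            "region_start": c.source_region[0],
            "region_end": c.source_region[1],
            "h3k27ac": ",".join(c.h3k27ac_ids) or ".",
            "atac": ",".join(c.atac_ids) or ".",
            "conserved": {True: 1, False: 0, None: -1}[c.conserved],
        }
        for i, c in enumerate(candidates)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "summit_signal",
            "region_start", "region_end", "h3k27ac", "atac", "conserved",
        ],
    )
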