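"""From fragment-level reads to significant interaction calls.

Stages, in the order a sample moves through them:

1. `filter_invalid` — drop reads on the viewpoint fragment (undigested
   template) and its two flanking fragments (self-ligation products).
2. `compute_qc` — cis/overall read ratio with the > 40% quality gate.
3. `window_rpm` — count retained reads into non-overlapping 2 kb windows and
   normalise to RPM (reads per million per window).
4. `call_interactions` — per-window significance against a distance-decay
   background: the background mean is a running median of counts over 101
   distance-ordered cis windows (floored at 0.5), each window gets a
   one-sided upper-tail Poisson p-value, and Benjamini-Hochberg adjustment
   across tested windows flags windows with padj < 0.05.
5. `high_fidelity` — intersect the significant windows of two biological
   replicates; only replicate-shared ("high-fidelity") sites move forward.

Windows within 10 kb of the viewpoint are excluded from both background
fitting and calling: the over-represented near-cis zone would otherwise
dominate the background estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .digest import FragmentMap, Viewpoint

CIS_GATE = 0.40
CORR_GATE = 0.40
DEFAULT_WINDOW = 2_000
EXCLUSION_RADIUS = 10_000
BACKGROUND_SPAN = 101
BACKGROUND_FLOOR = 0.5


@dataclass
class QCReport:
    """Per-sample quality metrics with the standard 4C acceptance gates."""

    sample: str
    total_reads: int
    cis_reads: int
    cis_ratio: float
    passes_cis_gate: bool
    replicate_pearson: Optional[float] = None
    passes_corr_gate: Optional[bool] = None

    def as_dict(self) -> Dict:
        return dict(self.__dict__)


@dataclass
class WindowTrack:
    """Fixed-grid window counts and RPM for one sample."""

    sample: str
    window_size: int
    chrom_sizes: Dict[str, int]
    df: pd.DataFrame  # chrom, start, end, count, rpm
    total_reads: int

    def cis(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom].reset_index(drop=True)


@dataclass
class InteractionCallSet:
    """Per-window background, p-values and significance flags for one sample."""

    sample: str
    viewpoint: Viewpoint
    window_size: int
    chrom_sizes: Dict[str, int]
    df: pd.DataFrame  # chrom, start, end, count, distance, background, pvalue, padj, significant

    @property
    def significant(self) -> pd.DataFrame:
        return self.df[self.df["significant"]].reset_index(drop=True)

    def significant_ids(self) -> Set[Tuple[str, int]]:
        sig = self.significant
        return set(zip(sig["chrom"], sig["start"].astype(int)))


@dataclass
class HighFidelitySites:
    """Windows significant in both biological replicates of a sample group."""

    window_size: int
    ids: Set[Tuple[str, int]] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.ids)
        return pd.DataFrame(
            {
                "chrom": [c for c, _ in rows],
                "start": [s for _, s in rows],
                "end": [s + self.window_size for _, s in rows],
            }
        )


def filter_invalid(
    reads: pd.DataFrame, fmap: FragmentMap, viewpoint: Viewpoint
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Remove undigested / self-ligated reads.

    Reads on the viewpoint fragment itself (non-digested template) and on its
    two flanking fragments (self-ligation circles) are artifacts of the 4C
    protocol and are removed before windowing.  Returns the retained reads
    and a removal report.
    """
    if viewpoint.chrom not in fmap.chrom_sizes:
        raise KeyError(f"viewpoint chromosome {viewpoint.chrom!r} absent from fragment map")
    if not 0 <= viewpoint.fragment_index < fmap.n_fragments(viewpoint.chrom):
        raise ValueError("viewpoint fragment absent from fragment map")
    bad = {viewpoint.fragment_index - 1, viewpoint.fragment_index, viewpoint.fragment_index + 1}
    mask = (reads["chrom"] == viewpoint.chrom) & reads["fragment_index"].isin(bad)
    removed = int(reads.loc[mask, "count"].sum())
    kept = reads[~mask].reset_index(drop=True)
    report = {
        "removed_reads": removed,
        "retained_reads": int(kept["count"].sum()),
        "removed_fraction": removed / max(int(reads["count"].sum()), 1),
    }
    return kept, report


def compute_qc(
    reads: pd.DataFrame, viewpoint: Viewpoint, cis_gate: float = CIS_GATE
) -> QCReport:
    """Cis/overall read ratio on the unfiltered reads, with the strict > gate."""
    total = int(reads["count"].sum())
    if total == 0:
        raise ValueError("cannot compute QC on zero reads")
    cis = int(reads.loc[reads["chrom"] == viewpoint.chrom, "count"].sum())
    ratio = cis / total
    sample = str(reads["sample"].iloc[0]) if "sample" in reads and len(reads) else ""
    return QCReport(
        sample=sample,
        total_reads=total,
        cis_reads=cis,
        cis_ratio=ratio,
        passes_cis_gate=ratio > cis_gate,
    )


def window_rpm(
    reads: pd.DataFrame,
    fmap: FragmentMap,
    window_size: int = DEFAULT_WINDOW,
    sample: Optional[str] = None,
) -> WindowTrack:
    """Count reads into non-overlapping windows and normalise to RPM.

    Each read is credited to the window containing its fragment's midpoint;
    RPM = count / total retained reads x 10^6, so RPM sums to 10^6 whenever
    all retained reads fall in windows.
    """
    if window_size <= 0:
        raise ValueError("window size must be positive")
    total = int(reads["count"].sum())
    frames = []
    for chrom, size in fmap.chrom_sizes.items():
        n_win = -(-size // window_size)
        starts = np.arange(n_win, dtype=np.int64) * window_size
        counts = np.zeros(n_win, dtype=np.int64)
        sub = reads[reads["chrom"] == chrom]
        if len(sub):
            mids = fmap.midpoints(chrom)[sub["fragment_index"].to_numpy()]
            win = np.minimum(mids // window_size, n_win - 1)
            np.add.at(counts, win, sub["count"].to_numpy())
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + window_size, size),
                    "count": counts,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["rpm"] = df["count"] / max(total, 1) * 1e6
    if sample is None:
        sample = str(reads["sample"].iloc[0]) if "sample" in reads and len(reads) else ""
    return WindowTrack(
        sample=sample,
        window_size=window_size,
        chrom_sizes=dict(fmap.chrom_sizes),
        df=df,
        total_reads=total,
    )


def call_interactions(
    track: WindowTrack,
    viewpoint: Viewpoint,
    alpha: float = 0.05,
    exclusion_radius: int = EXCLUSION_RADIUS,
    background_span: int = BACKGROUND_SPAN,
    background_floor: float = BACKGROUND_FLOOR,
) -> InteractionCallSet:
    """Call significantly interacting cis windows against a local background.

    Only windows on the viewpoint chromosome are tested (trans windows are
    never called significant).  The background for each window is the running
    median of counts over `background_span` distance-ordered cis windows,
    floored at `background_floor`; significance is a one-sided upper-tail
    Poisson test, BH-adjusted across all tested windows.
    """
    cis = track.cis(viewpoint.chrom).copy()
    if cis.empty:
        raise ValueError("no cis windows present")
    near = (cis["end"] > viewpoint.position - exclusion_radius) & (
        cis["start"] < viewpoint.position + exclusion_radius
    )
    tested = cis[~near].copy()
    if len(tested) < background_span:
        raise ValueError(
            f"only {len(tested)} cis windows available after viewpoint exclusion; "
            f"need >= {background_span} (use a larger genome or smaller windows)"
        )
    mid = (tested["start"] + tested["end"]) // 2
    tested["distance"] = (mid - viewpoint.position).abs()
    tested = tested.sort_values("distance", kind="mergesort").reset_index(drop=True)
    bg = (
        tested["count"]
        .rolling(background_span, center=True, min_periods=1)
        .median()
        .clip(lower=background_floor)
    )
    tested["background"] = bg
    tested["pvalue"] = stats.poisson.sf(tested["count"] - 1, tested["background"])
    reject, padj, _, _ = multipletests(tested["pvalue"], alpha=alpha, method="fdr_bh")
    tested["padj"] = padj
    tested["significant"] = tested["padj"] < alpha
    tested = tested.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return InteractionCallSet(
        sample=track.sample,
        viewpoint=viewpoint,
        window_size=track.window_size,
        chrom_sizes=dict(track.chrom_sizes),
        df=tested[
            ["chrom", "start", "end", "count", "distance", "background", "pvalue", "padj", "significant"]
        ],
    )


def high_fidelity(rep_a: InteractionCallSet, rep_b: InteractionCallSet) -> HighFidelitySites:
    """Replicate-shared significant windows (the high-fidelity interaction set)."""
    if rep_a.window_size != rep_b.window_size or rep_a.chrom_sizes != rep_b.chrom_sizes:
        raise ValueError("replicate call sets are on different window grids")
    return HighFidelitySites(
        window_size=rep_a.window_size,
        ids=rep_a.significant_ids() & rep_b.significant_ids(),
    )
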