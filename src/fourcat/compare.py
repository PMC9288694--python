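"""Cross-sample comparison of interaction profiles.

Covers the comparative analyses of the study design: per-sample
intrachromosomal interaction-site counts in 1 Mb bins (the unit of replicate
QC and clustering), Pearson-correlation hierarchical clustering, PCA, Venn
overlaps of interaction-site sets, and differential interaction-site
analysis between two conditions.

The differential test is a negative-binomial Wald analogue of the standard
RNA-seq style count test: median-of-ratios size factors, per-window
log2 fold change of normalised means with pseudocount 1, a method-of-moments
dispersion floored at 0.01, and BH adjustment.  A window is a significantly
differential interaction site (SDIS) when |log2FC| > 1 and padj < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

BIN_SIZE = 1_000_000
LFC_MIN = 1.0
ALPHA = 0.05
DISPERSION_FLOOR = 0.01


def bin_profile(
    sites: pd.DataFrame,
    chrom: str,
    chrom_sizes: Mapping[str, int],
    bin_size: int = BIN_SIZE,
) -> np.ndarray:
    """Count intrachromosomal interaction sites per fixed-size bin.

    Only sites on `chrom` (the viewpoint chromosome) are counted; a site is
    assigned to the bin containing its start coordinate.
    """
    size = chrom_sizes[chrom]
    n_bins = -(-size // bin_size)
    out = np.zeros(n_bins, dtype=np.int64)
    sub = sites[sites["chrom"] == chrom]
    if len(sub) == 0:
        return out
    if (sub["start"] < 0).any() or (sub["end"] > size).any():
        raise ValueError(f"site outside the bounds of {chrom} (length {size})")
    np.add.at(out, (sub["start"] // bin_size).to_numpy(), 1)
    return out


def replicate_pearson(profile_a: np.ndarray, profile_b: np.ndarray) -> float:
    """Pearson correlation of two binned profiles (nan if either is constant)."""
    if np.std(profile_a) == 0 or np.std(profile_b) == 0:
        return float("nan")
    return float(np.corrcoef(profile_a, profile_b)[0, 1])


@dataclass
class ClusterResult:
    correlation: pd.DataFrame
    linkage: Optional[np.ndarray]
    leaf_order: List[str]
    excluded: List[str]  # zero-variance profiles (correlation undefined)


def correlation_cluster(profiles: Mapping[str, np.ndarray]) -> ClusterResult:
    """Pairwise Pearson correlation + average-linkage clustering on 1 - r.

    Zero-variance profiles get NaN correlations and are excluded from the
    clustering.  Sample order (and linkage tie-breaking) is by sample id.
    """
    names = sorted(profiles)
    if len(names) < 2:
        raise ValueError("need at least two profiles")
    lengths = {len(profiles[n]) for n in names}
    if len(lengths) != 1:
        raise ValueError("profiles have unequal lengths")
    mat = np.array([np.asarray(profiles[n], dtype=float) for n in names])
    sd = mat.std(axis=1)
    excluded = [n for n, s in zip(names, sd) if s == 0]
    corr = pd.DataFrame(np.nan, index=names, columns=names)
    ok = [i for i, s in enumerate(sd) if s > 0]
    if ok:
        sub = np.corrcoef(mat[ok])
        sub = np.atleast_2d(sub)
        for a, i in enumerate(ok):
            for b, j in enumerate(ok):
                corr.iloc[i, j] = sub[a, b]
    kept = [names[i] for i in ok]
    if len(kept) < 2:
        return ClusterResult(corr, None, kept, excluded)
    dist = 1.0 - corr.loc[kept, kept].to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(link)
    return ClusterResult(corr, link, [kept[i] for i in order], excluded)


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # components x bins


def pca(profiles: Mapping[str, np.ndarray]) -> PCAResult:
    """Centred PCA of binned profiles via SVD.

    Sign convention: within each component, the loading of largest magnitude
    is made positive, so coordinates are reproducible across runs.
    """
    names = sorted(profiles)
    if len(names) < 2:
        raise ValueError("need at least two profiles")
    mat = np.array([np.asarray(profiles[n], dtype=float) for n in names])
    centred = mat - mat.mean(axis=0, keepdims=True)
    if np.allclose(centred, 0):
        raise ValueError("constant profile matrix: PCA undefined")
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    var = s**2
    evr = var / var.sum()
    coords = u * s
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=names, columns=cols),
        explained_variance_ratio=evr,
        loadings=vt,
    )


@dataclass
class OverlapSummary:
    set_sizes: Dict[str, int]
    partition_counts: Dict[Tuple[str, ...], int]  # exact Venn regions
    pairwise_shared: Dict[Tuple[str, str], int]
    shared_all: int
    union: int
    shared_fraction: float


def overlap_sets(site_sets: Mapping[str, Set]) -> OverlapSummary:
    """Exact Venn partition of 2 or 3 named window-id sets.

    `shared_fraction` is |intersection of all| / |union of all| — the
    "shared among genes/conditions" statistic.
    """
    names = list(site_sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("overlap_sets supports exactly 2 or 3 sets")
    sets = {n: set(site_sets[n]) for n in names}
    union = set().union(*sets.values())
    inter = set.intersection(*sets.values())
    partition: Dict[Tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) if r < len(names) else set()
            partition[combo] = len(inside - outside)
    pairwise = {
        (a, b): len(sets[a] & sets[b]) for a, b in combinations(names, 2)
    }
    return OverlapSummary(
        set_sizes={n: len(sets[n]) for n in names},
        partition_counts=partition,
        pairwise_shared=pairwise,
        shared_all=len(inter),
        union=len(union),
        shared_fraction=(len(inter) / len(union)) if union else 0.0,
    )


@dataclass
class DifferentialResult:
    """Per-window differential statistics (condition B vs condition A)."""

    df: pd.DataFrame  # index = window id; base_mean, log2fc, pvalue, padj, sdis
    size_factors: pd.Series
    lfc_min: float
    alpha: float

    @property
    def sdis(self) -> pd.DataFrame:
        return self.df[self.df["sdis"]]


def _size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (falls back to totals if no all-positive row)."""
    log = np.log(counts.where(counts > 0))
    log_geo = log.mean(axis=1)
    usable = np.isfinite(log_geo)
    if usable.sum() == 0:
        totals = counts.sum(axis=0).astype(float)
        sf = totals / np.exp(np.log(totals.where(totals > 0)).mean())
        return sf.fillna(1.0)
    ratios = log.loc[usable].sub(log_geo[usable], axis=0)
    sf = np.exp(ratios.median(axis=0))
    return sf.fillna(1.0)


def differential(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    lfc_min: float = LFC_MIN,
    alpha: float = ALPHA,
    dispersion_floor: float = DISPERSION_FLOOR,
) -> DifferentialResult:
    """Negative-binomial Wald test for differential interaction sites.

    `counts_a` / `counts_b` are raw window counts (windows x replicates),
    aligned on the same window index (normally the replicate-shared
    high-fidelity site set).  Requires >= 2 replicates per condition.

    The per-window dispersion is a method-of-moments estimate pooled over
    the two conditions and floored at `dispersion_floor`; the Wald standard
    error of the log2 fold change follows by the delta method.
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need at least two replicates per condition")
    if not counts_a.index.equals(counts_b.index):
        raise ValueError("count matrices are not aligned on the same windows")
    all_counts = pd.concat([counts_a, counts_b], axis=1)
    sf = _size_factors(all_counts)
    norm = all_counts / sf
    na, nb = counts_a.shape[1], counts_b.shape[1]
    norm_a, norm_b = norm.iloc[:, :na], norm.iloc[:, na:]

    mean_a = norm_a.mean(axis=1).to_numpy()
    mean_b = norm_b.mean(axis=1).to_numpy()
    var_a = norm_a.var(axis=1, ddof=1).to_numpy()
    var_b = norm_b.var(axis=1, ddof=1).to_numpy()

    log2fc = np.log2(mean_b + 1.0) - np.log2(mean_a + 1.0)

    # method-of-moments NB dispersion, pooled over conditions where defined
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_a = (var_a - mean_a) / np.square(mean_a)
        disp_b = (var_b - mean_b) / np.square(mean_b)
    disp = np.nanmean(np.vstack([disp_a, disp_b]), axis=0)
    disp = np.where(np.isfinite(disp), disp, 0.0)
    disp = np.maximum(disp, dispersion_floor)

    ln2sq = math.log(2) ** 2
    var_mean_a = (mean_a + disp * mean_a**2) / na
    var_mean_b = (mean_b + disp * mean_b**2) / nb
    se2 = var_mean_a / (np.square(mean_a + 1.0) * ln2sq) + var_mean_b / (
        np.square(mean_b + 1.0) * ln2sq
    )
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    pvalue = np.where((se == 0) & (log2fc == 0), 1.0, 2.0 * stats.norm.sf(np.abs(z)))
    if len(pvalue):
        _, padj, _, _ = multipletests(pvalue, alpha=alpha, method="fdr_bh")
    else:
        padj = pvalue
    df = pd.DataFrame(
        {
            "base_mean": (mean_a + mean_b) / 2,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "se": se,
            "pvalue": pvalue,
            "padj": padj,
        },
        index=counts_a.index,
    )
    df["sdis"] = (df["log2fc"].abs() > lfc_min) & (df["padj"] < alpha)
    return DifferentialResult(df=df, size_factors=sf, lfc_min=lfc_min, alpha=alpha)


def mean_abs_lfc(result: DifferentialResult, sdis_only: bool = True) -> float:
    """Arithmetic mean of |log2FC| over SDIS (or all tested) windows."""
    sel = result.sdis if sdis_only else result.df
    if len(sel) == 0:
        raise ValueError("empty selection: no windows to average")
    return float(sel["log2fc"].abs().mean())
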