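"""Synthetic 4C-seq data with planted enhancer contacts.

The generator emulates the study design the pipeline is built for: a
viewpoint (a gene promoter) assayed in two muscle conditions with two
biological replicates each.  It emits everything downstream stages consume —
a small multi-chromosome genome with restriction sites, fragment-level read
tables, H3K27ac/ATAC peak files, an ATAC signal track and a promoter
annotation — plus a truth record of where enhancer contacts were planted and
at what strength, so recovery can be measured exactly.

Model
-----
* Cis (viewpoint-chromosome) reads land on restriction fragments with
  probability proportional to a power-law distance decay
  ``(1 + d/d0)**(-alpha)`` (d = fragment midpoint to viewpoint), multiplied
  by the contact effect of any planted enhancer covering the fragment.
* Trans reads are uniform over the fragments of the other chromosomes.
* A fixed fraction of reads is "invalid": undigested (on the viewpoint
  fragment) or self-ligated (on its two neighbours), split 50/50 between the
  two classes.
* Biological noise enters as per-fragment Gamma multipliers at two levels:
  a condition-level multiplier shared by the replicates of one condition
  (tissues differ in their contact landscape) and a replicate-level
  multiplier independent per sample.  Each dispersion is the variance of
  its multiplier.

Everything is deterministic given (seed, condition, replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .digest import FragmentMap, RestrictionEnzyme, build_fragment_map

FORCED_SITE_SPACING = 5_000  # bp; guarantees no fragment exceeds this


@dataclass(frozen=True)
class PlantedEnhancer:
    """A planted enhancer contact: a summit with per-condition effect sizes.

    `effect_by_condition` multiplies the contact probability of every
    fragment overlapping the enhancer footprint (summit ± width/2); an effect
    of 1 means no contact above background in that condition.
    """

    chrom: str
    summit: int
    effect_by_condition: Mapping[str, float]
    width: int = 1_000

    def __post_init__(self) -> None:
        if any(e < 1 for e in self.effect_by_condition.values()):
            raise ValueError("enhancer effects must be >= 1")
        if self.width <= 0:
            raise ValueError("enhancer width must be positive")

    @property
    def start(self) -> int:
        return self.summit - self.width // 2

    @property
    def end(self) -> int:
        return self.summit + self.width // 2

    def effect(self, condition: str) -> float:
        return float(self.effect_by_condition.get(condition, 1.0))


@dataclass
class SimConfig:
    seed: int = 0
    chrom_sizes: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 2_000_000, "chr3": 2_000_000}
    )
    enzyme_name: str = "DpnII"
    viewpoint: Tuple[str, int] = ("chr1", 2_500_000)
    n_reads: int = 500_000
    decay_alpha: float = 1.0
    decay_d0: float = 10_000.0
    cis_fraction: float = 0.45
    invalid_fraction: float = 0.10
    planted: List[PlantedEnhancer] = field(default_factory=list)
    conditions: Tuple[str, ...] = ("quad", "sol")
    replicates: int = 2
    noise_dispersion: float = 0.025
    condition_dispersion: float = 0.025

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0 <= self.invalid_fraction <= 1 or not 0 <= self.cis_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.cis_fraction < self.invalid_fraction:
            raise ValueError(
                "cis_fraction must be >= invalid_fraction (invalid reads are cis)"
            )
        if self.noise_dispersion < 0 or self.condition_dispersion < 0:
            raise ValueError("dispersions must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        vp_chrom, vp_pos = self.viewpoint
        if vp_chrom not in self.chrom_sizes:
            raise ValueError(f"viewpoint chromosome {vp_chrom!r} not in genome")
        if not 0 <= vp_pos < self.chrom_sizes[vp_chrom]:
            raise ValueError("viewpoint position out of bounds")
        for enh in self.planted:
            if enh.chrom not in self.chrom_sizes:
                raise ValueError(f"planted enhancer on unknown chromosome {enh.chrom!r}")
            if not 0 <= enh.summit < self.chrom_sizes[enh.chrom]:
                raise ValueError("planted summit out of chromosome bounds")

    @property
    def enzyme(self) -> RestrictionEnzyme:
        return RestrictionEnzyme.from_name(self.enzyme_name)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def default_planted() -> List[PlantedEnhancer]:
    """Five enhancers at effect 8: three shared, one specific per condition."""
    return [
        PlantedEnhancer("chr1", 600_000, {"quad": 8.0, "sol": 8.0}),
        PlantedEnhancer("chr1", 1_400_000, {"quad": 8.0, "sol": 1.0}),
        PlantedEnhancer("chr1", 1_900_000, {"quad": 8.0, "sol": 8.0}),
        PlantedEnhancer("chr1", 3_300_000, {"quad": 1.0, "sol": 8.0}),
        PlantedEnhancer("chr1", 4_100_000, {"quad": 8.0, "sol": 8.0}),
    ]


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The study-design defaults: two conditions x two replicates, 5 enhancers."""
    kwargs = dict(seed=seed, planted=default_planted())
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def contrast_config(seed: int = 0, **overrides) -> SimConfig:
    """Two strongly divergent conditions on a larger viewpoint chromosome.

    Emulates tissues whose contact landscapes differ across many loci: eight
    enhancer domains with 8 kb contact footprints, three specific to each
    condition and two shared, spread over distinct 1 Mb bins of a 12 Mb
    viewpoint chromosome.  Used to demonstrate condition separation in
    clustering/PCA of binned interaction-site profiles.
    """

    def _e(pos: int, quad: float, sol: float) -> PlantedEnhancer:
        return PlantedEnhancer("chr1", pos, {"quad": quad, "sol": sol}, width=8_000)

    kwargs = dict(
        seed=seed,
        chrom_sizes={"chr1": 12_000_000, "chr2": 2_000_000, "chr3": 2_000_000},
        viewpoint=("chr1", 6_000_000),
        planted=[
            _e(3_500_000, 8.0, 8.0), _e(8_500_000, 8.0, 8.0),
            _e(2_500_000, 8.0, 1.0), _e(5_500_000, 8.0, 1.0), _e(9_500_000, 8.0, 1.0),
            _e(1_500_000, 1.0, 8.0), _e(7_500_000, 1.0, 8.0), _e(10_500_000, 1.0, 8.0),
        ],
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@dataclass
class SimTruth:
    """What was planted, and the expected window contact intensity it implies."""

    planted: List[PlantedEnhancer]
    #: condition -> DataFrame (chrom, start, end, expected_count) on 2 kb windows
    expected: Dict[str, pd.DataFrame]

    def enhancer_windows(self, window_size: int = 2_000) -> List[Tuple[str, int]]:
        """(chrom, window start) of the window containing each planted summit."""
        return [
            (e.chrom, (e.summit // window_size) * window_size) for e in self.planted
        ]


def make_genome(config: SimConfig) -> Tuple[Dict[str, str], FragmentMap]:
    """Generate a random genome with restriction sites, plus its fragment map.

    Recognition sites occur at their natural random density (~1/4^k for a
    k-mer site) and are additionally forced every 5 kb so that no fragment
    exceeds 5 kb.  Deterministic given the config seed.
    """
    rng = np.random.default_rng([int(config.seed), 101])
    from .digest import IUPAC_DNA

    site = config.enzyme.recognition_site
    # concrete realisation of a possibly degenerate site (first base of each class)
    concrete = "".join(c if c in "ACGT" else IUPAC_DNA[c][0] for c in site)
    genome: Dict[str, str] = {}
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for chrom, size in config.chrom_sizes.items():
        if size < 2 * FORCED_SITE_SPACING:
            raise ValueError(
                f"chromosome {chrom!r} too short ({size} bp) for forced-site "
                f"construction; need >= {2 * FORCED_SITE_SPACING} bp"
            )
        arr = bases[rng.integers(0, 4, size=size)]
        for pos in range(FORCED_SITE_SPACING, size - len(concrete) + 1, FORCED_SITE_SPACING):
            arr[pos : pos + len(concrete)] = np.frombuffer(concrete.encode(), dtype="S1")
        genome[chrom] = arr.tobytes().decode("ascii")
    fmap = build_fragment_map(genome, config.enzyme)
    return genome, fmap


def _cis_weights(
    config: SimConfig, fmap: FragmentMap, condition: str
) -> Tuple[np.ndarray, int]:
    """Unnormalised valid-cis fragment weights and the viewpoint fragment index."""
    vp_chrom, vp_pos = config.viewpoint
    vp_idx = fmap.fragment_index_at(vp_chrom, vp_pos)
    mids = fmap.midpoints(vp_chrom).astype(float)
    d = np.abs(mids - vp_pos)
    bounds = fmap.boundaries(vp_chrom)
    # decay evaluated at the fragment midpoint, scaled by fragment length:
    # capture is per ligation junction, so longer fragments draw
    # proportionally more reads, and windowed intensity varies smoothly
    # with distance rather than with the local fragment density
    lengths = (bounds[1:] - bounds[:-1]).astype(float)
    w = lengths * (1.0 + d / config.decay_d0) ** (-config.decay_alpha)
    for enh in config.planted:
        if enh.chrom != vp_chrom:
            continue  # trans reads are uniform; effects only shape cis contacts
        eff = enh.effect(condition)
        if eff != 1.0:
            overlap = (bounds[1:] > enh.start) & (bounds[:-1] < enh.end)
            w[overlap] *= eff
    lo = max(vp_idx - 1, 0)
    w[lo : vp_idx + 2] = 0.0  # viewpoint fragment + neighbours carry only invalid reads
    return w, vp_idx


def simulate_sample(
    config: SimConfig,
    condition: str,
    replicate: int,
    fmap: Optional[FragmentMap] = None,
    truth: Optional[SimTruth] = None,
) -> pd.DataFrame:
    """Draw one sample's fragment-level read table.

    Returns a DataFrame (sample, chrom, fragment_index, count) whose counts
    sum exactly to ``config.n_reads``.
    """
    if condition not in config.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    if fmap is None:
        _, fmap = make_genome(config)
    cond_idx = config.conditions.index(condition)
    rng = np.random.default_rng([int(config.seed), 211, cond_idx, int(replicate)])

    vp_chrom, _ = config.viewpoint
    w_cis, vp_idx = _cis_weights(config, fmap, condition)

    trans_chroms = [c for c in fmap.chrom_sizes if c != vp_chrom]
    n_trans = sum(fmap.n_fragments(c) for c in trans_chroms)
    w_trans = np.ones(n_trans, dtype=float)

    # condition-level biological variability: replicates of one condition share
    # that condition's contact landscape, so this multiplier is drawn per
    # (seed, condition) and reused across its replicates
    if config.condition_dispersion > 0:
        rng_cond = np.random.default_rng([int(config.seed), 223, cond_idx])
        shape_c = 1.0 / config.condition_dispersion
        w_cis = w_cis * rng_cond.gamma(shape_c, config.condition_dispersion, size=w_cis.size)
    # replicate-level technical/biological noise, independent per sample
    if config.noise_dispersion > 0:
        shape = 1.0 / config.noise_dispersion
        w_cis = w_cis * rng.gamma(shape, config.noise_dispersion, size=w_cis.size)
        w_trans = w_trans * rng.gamma(shape, config.noise_dispersion, size=n_trans)

    p_invalid = config.invalid_fraction
    p_cis_valid = config.cis_fraction - p_invalid
    p_trans = 1.0 - config.cis_fraction

    # one global label array: (chrom code, fragment index, probability)
    chroms: List[str] = []
    frag_idx: List[np.ndarray] = []
    chrom_of: List[np.ndarray] = []
    probs: List[np.ndarray] = []

    def _add(chrom: str, idxs: np.ndarray, p: np.ndarray) -> None:
        frag_idx.append(idxs.astype(np.int64))
        chrom_of.append(np.full(len(idxs), len(chroms), dtype=np.int64))
        chroms.append(chrom)
        probs.append(p)

    if p_cis_valid > 0 and w_cis.sum() > 0:
        _add(vp_chrom, np.arange(w_cis.size), w_cis / w_cis.sum() * p_cis_valid)
    if p_trans > 0 and n_trans:
        off = 0
        for c in trans_chroms:
            n = fmap.n_fragments(c)
            _add(c, np.arange(n), w_trans[off : off + n] / w_trans.sum() * p_trans)
            off += n
    if p_invalid > 0:
        # 50% undigested (viewpoint fragment), 50% self-ligated (neighbours)
        n_vp = fmap.n_fragments(vp_chrom)
        neighbours = [i for i in (vp_idx - 1, vp_idx + 1) if 0 <= i < n_vp]
        inv_idx = np.array([vp_idx] + neighbours)
        inv_p = np.array(
            [p_invalid * 0.5] + [p_invalid * 0.5 / len(neighbours)] * len(neighbours)
        )
        _add(vp_chrom, inv_idx, inv_p)

    p = np.concatenate(probs)
    p = p / p.sum()
    counts = rng.multinomial(config.n_reads, p)

    all_idx = np.concatenate(frag_idx)
    all_chrom_code = np.concatenate(chrom_of)
    nz = np.nonzero(counts)[0]
    sample_id = f"{condition}_rep{replicate}"
    df = pd.DataFrame(
        {
            "sample": sample_id,
            "chrom": [chroms[c] for c in all_chrom_code[nz]],
            "fragment_index": all_idx[nz],
            "count": counts[nz],
        }
    )
    # merge duplicate (chrom, fragment) rows (invalid block overlaps cis indexing)
    df = (
        df.groupby(["sample", "chrom", "fragment_index"], as_index=False)["count"]
        .sum()
        .sort_values(["chrom", "fragment_index"], kind="mergesort")
        .reset_index(drop=True)
    )
    return df


def build_truth(
    config: SimConfig, fmap: Optional[FragmentMap] = None, window_size: int = 2_000
) -> SimTruth:
    """Expected valid-cis window counts per condition (noise-free)."""
    if fmap is None:
        _, fmap = make_genome(config)
    vp_chrom, _ = config.viewpoint
    mids = fmap.midpoints(vp_chrom)
    expected: Dict[str, pd.DataFrame] = {}
    p_cis_valid = config.cis_fraction - config.invalid_fraction
    size = fmap.chrom_sizes[vp_chrom]
    n_win = -(-size // window_size)
    starts = np.arange(n_win, dtype=np.int64) * window_size
    for cond in config.conditions:
        w, _ = _cis_weights(config, fmap, cond)
        if w.sum() > 0:
            frag_exp = w / w.sum() * p_cis_valid * config.n_reads
        else:
            frag_exp = w
        win = np.minimum(mids // window_size, n_win - 1)
        agg = np.bincount(win, weights=frag_exp, minlength=n_win)
        expected[cond] = pd.DataFrame(
            {
                "chrom": vp_chrom,
                "start": starts,
                "end": np.minimum(starts + window_size, size),
                "expected_count": agg,
            }
        )
    return SimTruth(planted=list(config.planted), expected=expected)


def simulate_tracks(
    config: SimConfig,
    truth: Optional[SimTruth] = None,
    signal_bin: int = 100,
) -> Dict[str, pd.DataFrame]:
    """Emit peak/signal/promoter tracks co-located with the planted enhancers.

    Returns BED-style DataFrames: "h3k27ac" and "atac" peak sets (each planted
    summit covered, with seeded jitter <= 200 bp, plus single-mark decoys),
    "atac_signal" (a bedGraph-style step track on the viewpoint chromosome:
    Gaussian bumps of sd 150 bp at each summit over uniform noise), and
    "promoters" (viewpoint ± 1 kb, plus a decoy promoter flanked by both marks).
    """
    planted = truth.planted if truth is not None else config.planted
    rng = np.random.default_rng([int(config.seed), 307])
    vp_chrom, vp_pos = config.viewpoint
    size = config.chrom_sizes[vp_chrom]

    half = 400  # peak half-width; > max jitter, so summits stay covered
    k27_rows, atac_rows = [], []
    for i, enh in enumerate(planted):
        j1, j2 = rng.integers(-200, 201, size=2)
        k27_rows.append((enh.chrom, enh.summit - half + int(j1), enh.summit + half + int(j1), f"k27_enh{i}"))
        atac_rows.append((enh.chrom, enh.summit - half + int(j2), enh.summit + half + int(j2), f"atac_enh{i}"))

    # decoy peaks: single-mark only, kept away from planted summits and viewpoint
    keep_away = [e.summit for e in planted if e.chrom == vp_chrom] + [vp_pos]

    def _decoy_positions(n: int) -> List[int]:
        # small chromosomes may not fit every decoy; give up after a bounded
        # number of draws rather than demanding full decoy placement
        out: List[int] = []
        lo, hi = min(10_000, size // 4), size - min(10_000, size // 4)
        for _ in range(200 * n):
            if len(out) == n:
                break
            pos = int(rng.integers(lo, hi))
            if all(abs(pos - q) > 20_000 for q in keep_away + out):
                out.append(pos)
        return out

    for i, pos in enumerate(_decoy_positions(3)):
        atac_rows.append((vp_chrom, pos - half, pos + half, f"atac_decoy{i}"))
    for i, pos in enumerate(_decoy_positions(3)):
        k27_rows.append((vp_chrom, pos - half, pos + half, f"k27_decoy{i}"))

    promoters = [(vp_chrom, max(vp_pos - 1_000, 0), vp_pos + 1_000, "viewpoint_promoter")]
    for decoy_prom in _decoy_positions(1):
        promoters.append((vp_chrom, decoy_prom - 1_000, decoy_prom + 1_000, "decoy_promoter"))
        # the decoy promoter carries both marks: exclusion is rule-based,
        # not an absence of signal
        k27_rows.append((vp_chrom, decoy_prom - half, decoy_prom + half, "k27_decoy_prom"))
        atac_rows.append((vp_chrom, decoy_prom - half, decoy_prom + half, "atac_decoy_prom"))

    n_bins = -(-size // signal_bin)
    starts = np.arange(n_bins, dtype=np.int64) * signal_bin
    centres = starts + signal_bin // 2
    values = rng.uniform(0.5, 1.5, size=n_bins)
    for enh in planted:
        if enh.chrom != vp_chrom:
            continue
        values = values + 20.0 * np.exp(-((centres - enh.summit) ** 2) / (2 * 150.0**2))
    signal = pd.DataFrame(
        {
            "chrom": vp_chrom,
            "start": starts,
            "end": np.minimum(starts + signal_bin, size),
            "value": values,
        }
    )
    bed_cols = ["chrom", "start", "end", "name"]
    return {
        "h3k27ac": pd.DataFrame(k27_rows, columns=bed_cols).sort_values(["chrom", "start"]).reset_index(drop=True),
        "atac": pd.DataFrame(atac_rows, columns=bed_cols).sort_values(["chrom", "start"]).reset_index(drop=True),
        "promoters": pd.DataFrame(promoters, columns=bed_cols),
        "atac_signal": signal,
    }
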