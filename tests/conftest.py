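import numpy as np
import pandas as pd
import pytest

import fourcat as fc
from fourcat.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on the default simulated experiment."""
    return run_pipeline(fc.PipelineConfig(seed=3))


@pytest.fixture(scope="session")
def contrast_runs():
    """Binned significant-site profiles from divergent-condition simulations."""
    out = []
    for seed in range(10):
        res = run_pipeline(fc.PipelineConfig(seed=950 + seed), fc.contrast_config(seed=950 + seed))
        out.append(
            {
                s: fc.bin_profile(c.significant, "chr1", res.fmap.chrom_sizes)
                for s, c in res.calls.items()
            }
        )
    return out


@pytest.fixture(scope="session")
def toy_genome():
    """Two-chromosome toy genome with known GATC positions."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    return {
        "chrA": "".join(rng.choice(bases, size=3_000)),
        "chrB": "".join(rng.choice(bases, size=1_500)),
    }


@pytest.fixture(scope="session")
def dpnii():
    return fc.RestrictionEnzyme.from_name("DpnII")


def make_track(counts, chrom="chr1", window_size=2_000, sample="test", extra_chrom=None):
    """WindowTrack with prescribed cis window counts (viewpoint at position 0)."""
    counts = np.asarray(counts, dtype=np.int64)
    n = len(counts)
    starts = np.arange(n, dtype=np.int64) * window_size
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + window_size,
            "count": counts,
        }
    )
    chrom_sizes = {chrom: int(n * window_size)}
    if extra_chrom:
        chrom_sizes.update(extra_chrom)
    total = int(counts.sum())
    df["rpm"] = df["count"] / max(total, 1) * 1e6
    return fc.WindowTrack(
        sample=sample,
        window_size=window_size,
        chrom_sizes=chrom_sizes,
        df=df,
        total_reads=total,
    )


@pytest.fixture
def flat_track():
    return make_track(np.full(5_000, 7))
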