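import numpy as np
import pandas as pd
import pytest

from gsvdcna import core_gsvd, genome_io, synthetic_cohort


def make_bins(n_bins, chrom="1", bin_size=1000, gc=None, start_offset=0):
    """Contiguous equal-width bins on one chromosome."""
    starts = start_offset + np.arange(n_bins) * bin_size
    df = pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + bin_size})
    if gc is not None:
        df["gc"] = gc
    return genome_io.BinTable(df)


def make_multi_bins(chrom_sizes, bin_size=1000, gc=None):
    """Bins over several chromosomes: {chrom: n_bins}."""
    frames = []
    for chrom, n in chrom_sizes.items():
        starts = np.arange(n) * bin_size
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + bin_size}))
    df = pd.concat(frames, ignore_index=True)
    if gc is not None:
        df["gc"] = gc
    return genome_io.BinTable(df)


def random_pair(rng, m1, m2, n):
    ids = [f"P{i}" for i in range(n)]
    return core_gsvd.ProfilePair(
        rng.normal(size=(m1, n)), rng.normal(size=(m2, n)), ids
    )


def tiny_sim_config(**overrides):
    """Fast desk-scale simulation: 20 patients, 4 small chromosomes."""
    chroms = overrides.pop("chromosomes", ("1", "2", "3", "X"))
    defaults = dict(
        n_patients=20,
        chromosomes=chroms,
        bins_per_chromosome=120,
        cna_segments=(
            synthetic_cohort.CnaSegment("1", 0.0, 0.5, +1.0),
            synthetic_cohort.CnaSegment("2", 0.25, 1.0, -1.0),
        ),
        extra_normal_bins=5,
        seed=0,
    )
    defaults.update(overrides)
    return synthetic_cohort.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def default_cohort():
    """The full-scale synthetic cohort (85 patients x ~20K bins) plus its GSVD.

    Session-scoped: shared by the recovery and classification tests.
    """
    config = synthetic_cohort.SimulationConfig(seed=7)
    tumor, normal, cohort, truth = synthetic_cohort.generate(config)
    pair = genome_io.match_pair(tumor, normal)
    result = core_gsvd.gsvd(pair)
    return {
        "config": config,
        "tumor": tumor,
        "normal": normal,
        "cohort": cohort,
        "truth": truth,
        "pair": pair,
        "result": result,
    }
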