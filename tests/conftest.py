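import numpy as np
import pytest

from diffmark.simulate import SimConfig, build_toy_genome, simulate_coverage


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    """Default synthetic study conditions (2x300 kb, 100 genes, 10-kb ITR)."""
    return SimConfig(seed=5)


@pytest.fixture(scope="session")
def toy(sim_config):
    return build_toy_genome(sim_config)


@pytest.fixture(scope="session")
def coverage(sim_config, toy):
    tracks, manifest = simulate_coverage(sim_config, toy.truth)
    return tracks, manifest


@pytest.fixture(scope="session")
def demo_scorecard(tmp_path_factory):
    """One shared full-pipeline demo run on synthetic data."""
    from diffmark.pipeline import run_demo

    outdir = tmp_path_factory.mktemp("demo")
    return run_demo(seed=11, outdir=str(outdir))


def random_track_arrays(rng: np.random.Generator, length: int, max_records: int = 40):
    """Random sorted non-overlapping (starts, ends, values) within [0, length)."""
    n_edges = rng.integers(2, max_records * 2)
    edges = np.sort(rng.choice(length + 1, size=n_edges, replace=False))
    starts, ends, values = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi > lo and rng.random() < 0.6:
            starts.append(lo)
            ends.append(hi)
            values.append(round(float(rng.uniform(0, 5)), 3))
    return (np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64),
            np.array(values, dtype=np.float64))
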