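import numpy as np
import pytest

from mreseq import simulate as sim
from mreseq import sites as st
from mreseq.nn import DNNConfig
from mreseq.preprocess import DepthMatrix


@pytest.fixture(scope="session")
def fast_dnn() -> DNNConfig:
    """Small training budget for unit tests where convergence is not the point."""
    return DNNConfig(epochs=30, batch_size=8, seed=0)


@pytest.fixture(scope="session")
def toy_genome() -> sim.GenomeSequence:
    return sim.planted_sites_genome(30, seed=3)


@pytest.fixture(scope="session")
def toy_sites(toy_genome) -> st.SacIISiteTable:
    return st.enumerate_sacii_sites(toy_genome)


def separable_cohort(
    n_sites: int = 60,
    n_control: int = 20,
    n_cancer: int = 20,
    delta: float = 0.3,
    tf_range=(0.2, 0.5),
    seed: int = 5,
    cancer: str = "crc",
):
    """Depth matrix + labels for a well-separated two-class cohort."""
    atlas = sim.build_methylation_atlas(
        n_sites, {"crc": sim.CancerClassConfig(delta=delta),
                  "lung": sim.CancerClassConfig(delta=delta)}, seed=seed
    )
    plan = sim.CohortPlan(
        counts={"control": n_control, cancer: n_cancer},
        tf_ranges={k: tf_range for k in ["I", "II", "III", "IV"]},
    )
    depth, meta = sim.simulate_cohort(atlas, plan, sim.LibraryConfig(), seed=seed)
    dm = DepthMatrix.from_raw(depth)
    y = (meta["truth_class"] == cancer).astype(int).to_numpy()
    return dm, meta, y


@pytest.fixture(scope="session")
def small_cohort():
    return separable_cohort()


def naive_motif_count(seq: str, motif: str = "CCGCGG") -> int:
    """Independent O(n*m) sliding-window oracle for motif occurrences."""
    return sum(seq[i : i + len(motif)] == motif for i in range(len(seq) - len(motif) + 1))


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
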