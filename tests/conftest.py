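import numpy as np
import pytest

from microsatpop import (
    GenotypeDataset,
    OutlierLocusSpec,
    StudyEmulationParams,
    generate_two_cluster_dataset,
    inject_outlier_locus,
)


@pytest.fixture(scope="session")
def study_fixture() -> GenotypeDataset:
    """Study-emulating dataset: 14 populations in two groups, 11 loci,
    between-group F'_ST calibrated to 0.27, plus the injected
    selection-signature locus (0.87-dominant allele in the epicormic group)."""
    ds = generate_two_cluster_dataset(StudyEmulationParams(seed=7))
    return inject_outlier_locus(ds, OutlierLocusSpec(), seed=8)


@pytest.fixture(scope="session")
def plain_study_fixture() -> GenotypeDataset:
    """Study-emulating dataset without the injected outlier locus."""
    return generate_two_cluster_dataset(StudyEmulationParams(seed=7))


@pytest.fixture
def small_two_pop() -> GenotypeDataset:
    """Two populations with disjoint allele sets at every locus.

    80 loci: with the fixed admixture hyperparameter alpha = 1 the
    posterior-mean membership is bounded by (2L + 1)/(2L + 2), so saturated
    memberships > 0.99 need L >= 80."""
    rng = np.random.default_rng(5)
    n, L = 20, 80
    calls = np.zeros((2 * n, L, 2), dtype=np.int32)
    calls[:n] = rng.choice([101, 103, 105], size=(n, L, 2))
    calls[n:] = rng.choice([201, 203, 205], size=(n, L, 2))
    return GenotypeDataset(
        individuals=[f"i{j}" for j in range(2 * n)],
        populations=["A"] * n + ["B"] * n,
        loci=[f"loc{l}" for l in range(L)],
        calls=calls,
        groups={"A": "g1", "B": "g2"},
    )


def make_dataset(pop_sizes: dict[str, int], n_loci: int, seed: int,
                 states=(101, 103, 105, 107)) -> GenotypeDataset:
    """Random panmictic dataset helper shared across test modules."""
    rng = np.random.default_rng(seed)
    individuals, populations, blocks = [], [], []
    for pop, n in pop_sizes.items():
        blocks.append(rng.choice(states, size=(n, n_loci, 2)).astype(np.int32))
        individuals += [f"{pop}_{i}" for i in range(n)]
        populations += [pop] * n
    return GenotypeDataset(
        individuals=individuals,
        populations=populations,
        loci=[f"loc{l}" for l in range(n_loci)],
        calls=np.concatenate(blocks),
    )
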