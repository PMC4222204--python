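import itertools

import numpy as np
import pandas as pd
import pytest

from microsatpop import (
    GenotypeDataset,
    allele_frequencies,
    block_summary,
    bonferroni,
    bootstrap_ci,
    gst,
    hedrick_fst_prime,
    jost_d,
    locus_group_differentiation,
    pairwise_matrix,
    permutation_test,
)
from microsatpop.differentiation import hs_ht, multilocus_statistic

from _oracles import oracle_fst_prime, oracle_gst, oracle_gst_max, oracle_jost_d
from conftest import make_dataset


def dataset_from_allele_counts(counts_by_pop: dict[str, list[int]], states=(101, 103)):
    """Build a dataset whose per-population allele-copy counts are exact."""
    individuals, populations, rows = [], [], []
    for pop, counts in counts_by_pop.items():
        copies = []
        for state, c in zip(states, counts):
            copies += [state] * c
        copies = np.array(copies, dtype=np.int32).reshape(-1, 2)
        for i, pair in enumerate(copies):
            individuals.append(f"{pop}_{i}")
            populations.append(pop)
            rows.append([pair])
    return GenotypeDataset(individuals, populations, ["l1"], np.array(rows))


class TestEstimatorLimits:
    def test_identical_populations_near_zero(self):
        ds = dataset_from_allele_counts({"A": [30, 10], "B": [30, 10]})
        freqs = allele_frequencies(ds)
        assert abs(gst(freqs)) < 0.05  # slightly negative allowed by the correction
        assert abs(jost_d(freqs)) < 0.05

    def test_fixed_difference_is_complete_differentiation(self):
        ds = dataset_from_allele_counts({"A": [40, 0], "B": [0, 40]})
        freqs = allele_frequencies(ds)
        assert gst(freqs) == pytest.approx(1.0)
        assert hedrick_fst_prime(freqs) == pytest.approx(1.0)
        assert jost_d(freqs) == pytest.approx(1.0)

    def test_standardization_is_identity_when_hs_zero(self):
        ds = dataset_from_allele_counts({"A": [20, 0], "B": [0, 20]})
        freqs = allele_frequencies(ds)
        assert hedrick_fst_prime(freqs) == pytest.approx(gst(freqs))

    def test_standardization_inflates_when_diverse(self):
        ds = dataset_from_allele_counts({"A": [35, 5], "B": [10, 30]})
        freqs = allele_frequencies(ds)
        g = gst(freqs)
        fp = hedrick_fst_prime(freqs)
        assert g > 0
        assert fp > g
        assert fp <= 1 + 1e-9


def test_estimators_match_bruteforce_oracle_grid():
    """Exhaustive 2-population 2-allele grid vs the independent formulas."""
    max_diff = 0.0
    for n1, n2 in itertools.product([4, 8], repeat=2):
        for c1, c2 in itertools.product(range(2 * n1 + 1), range(2 * n2 + 1)):
            if (c1 == 0 and c2 == 0) or (c1 == 2 * n1 and c2 == 2 * n2):
                continue  # globally monomorphic: undefined
            ds = dataset_from_allele_counts(
                {"A": [c1, 2 * n1 - c1], "B": [c2, 2 * n2 - c2]})
            freqs = allele_frequencies(ds)
            rows = [[c1 / (2 * n1), 1 - c1 / (2 * n1)],
                    [c2 / (2 * n2), 1 - c2 / (2 * n2)]]
            sizes = [n1, n2]
            max_diff = max(
                max_diff,
                abs(gst(freqs) - oracle_gst(rows, sizes)),
                abs(hedrick_fst_prime(freqs) - oracle_fst_prime(rows, sizes)),
                abs(jost_d(freqs) - oracle_jost_d(rows, sizes)),
            )
    assert max_diff < 1e-12


def test_fst_prime_equals_gst_over_gst_max():
    ds = dataset_from_allele_counts({"A": [25, 15], "B": [5, 35]})
    freqs = allele_frequencies(ds)
    P, n, _ = freqs.frequency_matrix("l1", ["A", "B"])
    rows = [list(P[0]), list(P[1])]
    expected = oracle_gst(rows, list(n)) / oracle_gst_max(rows, list(n))
    assert hedrick_fst_prime(freqs) == pytest.approx(expected, abs=1e-12)


def test_invariance_under_relabeling_and_reordering():
    ds = make_dataset({"A": 15, "B": 12, "C": 18}, n_loci=4, seed=8)
    freqs = allele_frequencies(ds)
    shifted = GenotypeDataset(ds.individuals, ds.populations, ds.loci, ds.calls + 50)
    assert gst(allele_frequencies(shifted)) == pytest.approx(gst(freqs), abs=1e-12)
    reordered = allele_frequencies(ds, ["C", "A", "B"])
    assert jost_d(reordered, ["C", "A", "B"]) == pytest.approx(
        jost_d(freqs, ["A", "B", "C"]), abs=1e-12)


def test_pairwise_matrix_structure():
    rng_states = (101, 103, 105)
    ds = make_dataset({"A": 20, "B": 20}, 3, seed=2, states=rng_states)
    fixed = np.full((20, 3, 2), 301, dtype=np.int32)
    ds_c = GenotypeDataset(
        ds.individuals + [f"C_{i}" for i in range(20)],
        ds.populations + ["C"] * 20,
        ds.loci,
        np.concatenate([ds.calls, fixed]),
    )
    mat = pairwise_matrix(ds_c, "fst_prime")
    assert mat.matrix.loc["A", "C"] == pytest.approx(1.0)
    assert mat.matrix.loc["B", "C"] == pytest.approx(1.0)
    assert abs(mat.matrix.loc["A", "B"]) < 0.1
    assert mat.matrix.equals(mat.matrix.T)


class TestPermutation:
    def test_fully_differentiated_pair_minimal_p(self):
        ds = dataset_from_allele_counts({"A": [40, 0], "B": [0, 40]})
        p = permutation_test(ds, ("A", "B"), "gst", n_perm=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_monomorphic_data_p_one(self):
        ds = dataset_from_allele_counts({"A": [40, 0], "B": [40, 0]},
                                        states=(101, 103))
        # single shared allele: statistic undefined -> use two alleles, equal
        ds = dataset_from_allele_counts({"A": [20, 20], "B": [20, 20]})
        calls = ds.calls.copy()
        p = permutation_test(ds, ("A", "B"), "gst", n_perm=99, seed=1)
        assert p > 0.5  # permutation cannot beat an undifferentiated observed value

    def test_panmictic_pair_not_significant(self):
        ds = make_dataset({"A": 25, "B": 25}, 5, seed=21)
        p = permutation_test(ds, ("A", "B"), "fst_prime", n_perm=199, seed=3)
        assert p > 0.05

    def test_too_few_permutations_rejected(self):
        ds = make_dataset({"A": 5, "B": 5}, 2, seed=0)
        with pytest.raises(ValueError):
            permutation_test(ds, ("A", "B"), "gst", n_perm=50, seed=0)


def test_bonferroni_flags():
    assert bonferroni([], 0.05).size == 0
    flags = bonferroni([1.0] * 28, 0.05)
    assert not flags.any()
    pvals = [0.001, 0.002, 0.04, 0.5]
    expected = [p <= 0.05 / 4 for p in pvals]
    assert bonferroni(pvals, 0.05).tolist() == expected


class TestBootstrap:
    def test_single_replicate_bounds_collapse(self):
        ds = make_dataset({"A": 10, "B": 10}, 3, seed=5)
        ci = bootstrap_ci(ds, ["A", "B"], "jost_d", n_boot=1, seed=7)
        assert np.allclose(ci["lower"], ci["upper"], equal_nan=True)

    def test_monomorphic_locus_is_undefined(self):
        ds = make_dataset({"A": 10, "B": 10}, 2, seed=5)
        calls = ds.calls.copy()
        calls[:, 0, :] = 101  # locus 0 globally monomorphic
        ds = GenotypeDataset(ds.individuals, ds.populations, ds.loci, calls)
        ci = bootstrap_ci(ds, ["A", "B"], "gst", n_boot=50, seed=1)
        assert np.isnan(ci.loc["loc0", "point"])  # undefined, not zero
        assert ci.loc["loc1", "lower"] <= ci.loc["loc1", "upper"]

    def test_interval_width_shrinks_with_sample_size(self):
        widths = {}
        for n in (10, 100):
            ds = make_dataset({"A": n, "B": n}, 4, seed=13)
            ci = bootstrap_ci(ds, ["A", "B"], "jost_d", n_boot=200, seed=2)
            widths[n] = float((ci["upper"] - ci["lower"]).mean())
        assert widths[100] < widths[10]

    def test_size_one_population_rejected(self):
        ds = make_dataset({"A": 1, "B": 10}, 2, seed=0)
        with pytest.raises(ValueError):
            bootstrap_ci(ds, ["A", "B"], n_boot=10, seed=0)


def test_block_summary_constant_matrix():
    pops = ["L1", "L2", "E1", "E2"]
    M = pd.DataFrame(0.42, index=pops, columns=pops)
    groups = {"L1": "g1", "L2": "g1", "E1": "g2", "E2": "g2"}
    out = block_summary(M, groups)
    assert np.allclose(out["mean"], 0.42)
    assert np.allclose(out["min"], 0.42)
    assert out.loc["between", "n_pairs"] == 4


def test_block_summary_requires_full_mapping():
    pops = ["A", "B", "C"]
    M = pd.DataFrame(0.1, index=pops, columns=pops)
    with pytest.raises(ValueError, match="not in group mapping"):
        block_summary(M, {"A": "g1", "B": "g2"})


def test_locus_group_differentiation_layout(small_two_pop):
    out = locus_group_differentiation(small_two_pop, small_two_pop.groups)
    assert list(out.index) == small_two_pop.loci
    assert {"within_g1", "within_g2", "between"} <= set(out.columns)
    # disjoint allele sets between groups: between-group D = 1 everywhere
    assert np.allclose(out["between"], 1.0)
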