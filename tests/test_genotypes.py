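import numpy as np
import pytest

from microsatpop import (
    GenotypeDataset,
    allele_frequencies,
    read_genepop,
    read_group_map,
    read_table,
    standardize_sample,
    write_genepop,
    write_group_map,
    write_table,
)
from microsatpop.genotypes import GenepopEncodeError, GenepopParseError

from conftest import make_dataset

MINIMAL_GENEPOP = """two populations, one locus
locA
POP
a1 ,  001002
a2 ,  001001
POP
b1 ,  002002
b2 ,  000000
"""


def test_read_minimal_genepop(tmp_path):
    path = tmp_path / "toy.gen"
    path.write_text(MINIMAL_GENEPOP)
    ds = read_genepop(path)
    assert ds.population_ids == ["pop1", "pop2"]
    assert ds.loci == ["locA"]
    assert ds.n_individuals == 4
    assert ds.calls[0].tolist() == [[1, 2]]


def test_missing_code_excluded_from_n(tmp_path):
    path = tmp_path / "toy.gen"
    path.write_text(MINIMAL_GENEPOP)
    freqs = allele_frequencies(read_genepop(path))
    assert freqs.n("pop2", "locA") == 1  # the 000000 record is excluded
    assert freqs.freq("pop2", "locA") == {2: 1.0}


@pytest.mark.parametrize(
    "content, message",
    [
        ("t\nlocA\nPOP\na1  001002\n", "separator"),
        ("t\nlocA\nPOP\na1 ,  001002 003004\n", "expected 1 genotypes"),
        ("t\nlocA\nPOP\na1 ,  0012\n", "mixed"),  # 4- and 6-wide in one file
        ("t\nlocA\na1 ,  001002\n", "no POP"),
    ],
)
def test_malformed_genepop_rejected(tmp_path, content, message):
    if "mixed" in message:
        content += "POP\nb1 ,  001002\n"
    path = tmp_path / "bad.gen"
    path.write_text(content)
    with pytest.raises(GenepopParseError, match=message):
        read_genepop(path)


def test_two_digit_coding(tmp_path):
    path = tmp_path / "two.gen"
    path.write_text("t\nlocA\nPOP\na1 ,  0102\na2 ,  0000\n")
    ds = read_genepop(path)
    assert ds.calls[0].tolist() == [[1, 2]]
    assert ds.calls[1].tolist() == [[0, 0]]


def test_genepop_roundtrip_random_datasets(tmp_path):
    for seed in range(3):
        ds = make_dataset({"p1": 8, "p2": 5, "p3": 11}, n_loci=4, seed=seed)
        ds.calls[0, 0] = 0  # force a missing call through the roundtrip
        path = tmp_path / f"rt{seed}.gen"
        write_genepop(ds, path)
        back = read_genepop(path)
        assert back.loci == ds.loci
        assert np.array_equal(back.calls, ds.calls)
        # second roundtrip is byte-identical (canonical form)
        path2 = tmp_path / f"rt{seed}b.gen"
        write_genepop(back, path2, title=path.read_text().splitlines()[0])
        assert path.read_text() == path2.read_text()


def test_write_rejects_wide_alleles(tmp_path):
    ds = make_dataset({"p": 2}, 1, 0, states=(1000, 1002))
    with pytest.raises(GenepopEncodeError):
        write_genepop(ds, tmp_path / "x.gen")


def test_empty_locus_list_rejected():
    with pytest.raises(ValueError):
        GenotypeDataset(["a"], ["p"], [], np.zeros((1, 0, 2)))


def test_half_missing_rejected():
    calls = np.array([[[1, 0]]])
    with pytest.raises(ValueError, match="half-missing"):
        GenotypeDataset(["a"], ["p"], ["l"], calls)


def test_tsv_roundtrip(tmp_path):
    ds = make_dataset({"p1": 6, "p2": 4}, n_loci=3, seed=2)
    ds.calls[1, 2] = 0
    path = tmp_path / "geno.tsv"
    write_table(ds, path)
    back = read_table(path)
    assert back.equals(ds)


def test_group_map_roundtrip(tmp_path):
    groups = {"L1": "lignotuberous", "E1": "epicormic"}
    path = tmp_path / "groups.tsv"
    write_group_map(groups, path)
    assert read_group_map(path) == groups


def test_allele_frequencies_direct_count():
    calls = np.array([[[1, 1]], [[1, 2]]])
    ds = GenotypeDataset(["a", "b"], ["p", "p"], ["l"], calls)
    freqs = allele_frequencies(ds)
    assert freqs.freq("p", "l") == {1: 0.75, 2: 0.25}
    assert freqs.n("p", "l") == 2


def test_all_missing_locus_has_n_zero():
    calls = np.zeros((3, 1, 2), dtype=np.int32)
    ds = GenotypeDataset(["a", "b", "c"], ["p"] * 3, ["l"], calls)
    freqs = allele_frequencies(ds)
    assert freqs.n("p", "l") == 0
    assert freqs.freq("p", "l") == {}


def test_frequencies_sum_to_one_and_reorder_invariant():
    ds = make_dataset({"p1": 10, "p2": 7}, n_loci=5, seed=3)
    freqs = allele_frequencies(ds)
    for pop in ds.population_ids:
        for locus in ds.loci:
            assert abs(sum(freqs.freq(pop, locus).values()) - 1.0) < 1e-9
    # shuffle individuals within populations: identical table
    rng = np.random.default_rng(0)
    order = np.concatenate([
        rng.permutation(ds.population_indices("p1")),
        rng.permutation(ds.population_indices("p2")),
    ])
    shuffled = ds.subset_individuals(order)
    freqs2 = allele_frequencies(shuffled)
    assert freqs2.freqs == freqs.freqs and freqs2.counts == freqs.counts


class TestStandardizeSample:
    def test_identity_when_n_matches(self):
        ds = make_dataset({"p1": 6, "p2": 6}, 2, seed=1)
        out = standardize_sample(ds, 6, seed=0)
        assert out.individuals == ds.individuals

    def test_deterministic_and_exact_size(self):
        ds = make_dataset({"p1": 35, "p2": 28}, 3, seed=4)
        a = standardize_sample(ds, 25, seed=11)
        b = standardize_sample(ds, 25, seed=11)
        assert a.individuals == b.individuals
        assert all(v == 25 for v in a.population_sizes().values())

    def test_seeds_differ_but_sizes_match(self):
        ds = make_dataset({"p1": 35, "p2": 28}, 3, seed=4)
        a = standardize_sample(ds, 25, seed=1)
        b = standardize_sample(ds, 25, seed=2)
        assert a.individuals != b.individuals
        assert a.population_sizes() == b.population_sizes()

    def test_error_names_small_population(self):
        ds = make_dataset({"p1": 10, "tiny": 3}, 2, seed=0)
        with pytest.raises(ValueError, match="tiny"):
            standardize_sample(ds, 5, seed=0)


try:
    from hypothesis import given, settings, strategies as st

    @st.composite
    def _datasets(draw):
        n_loci = draw(st.integers(1, 4))
        n_pops = draw(st.integers(1, 3))
        individuals, populations, rows = [], [], []
        for p in range(n_pops):
            for i in range(draw(st.integers(1, 4))):
                individuals.append(f"p{p}_i{i}")
                populations.append(f"p{p}")
                row = []
                for _ in range(n_loci):
                    if draw(st.booleans()):
                        row.append([0, 0])
                    else:
                        row.append([draw(st.integers(1, 999)),
                                    draw(st.integers(1, 999))])
                rows.append(row)
        return GenotypeDataset(individuals, populations,
                               [f"l{j}" for j in range(n_loci)],
                               np.array(rows, dtype=np.int32))

    @given(_datasets())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_genepop_roundtrip_property(tmp_path_factory, ds):
        """write -> read preserves loci, population structure and calls for
        any dataset expressible in 3-digit coding."""
        path = tmp_path_factory.mktemp("hyp") / "ds.gen"
        write_genepop(ds, path)
        back = read_genepop(path)
        assert back.loci == ds.loci
        assert np.array_equal(back.calls, ds.calls)
        assert [len(back.population_indices(p)) for p in back.population_ids] == [
            len(ds.population_indices(p)) for p in ds.population_ids]
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass
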