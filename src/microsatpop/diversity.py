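"""Per-population genetic-diversity statistics.

For each population the module reports, averaged over loci with data:

* ``A`` -- mean number of alleles per locus;
* ``Ae`` -- mean effective number of alleles, ``1 / sum(p_i^2)``;
* ``Ho`` -- observed heterozygosity (fraction of heterozygous genotypes);
* ``He`` -- unbiased expected heterozygosity with Nei's small-sample
  correction, ``(2n / (2n - 1)) * (1 - sum(p_i^2))``.

Loci with no data in a population (``n = 0``) are treated as undefined and
excluded from the average rather than counted as zeros; ``He`` additionally
requires ``n >= 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, AlleleFrequencyTable, GenotypeDataset, allele_frequencies

__all__ = [
    "num_alleles",
    "effective_alleles",
    "observed_heterozygosity",
    "unbiased_expected_heterozygosity",
    "diversity_table",
]


def _defined_loci(freqs: AlleleFrequencyTable, population: str, min_n: int = 1) -> list[str]:
    loci = [l for l in freqs.loci if freqs.n(population, l) >= min_n]
    if not loci:
        raise ValueError(f"population {population!r} has no locus with n >= {min_n}")
    return loci


def num_alleles(freqs: AlleleFrequencyTable, population: str) -> float:
    """Mean number of alleles per locus (alleles with frequency > 0)."""
    loci = _defined_loci(freqs, population)
    return float(np.mean([len(freqs.freq(population, l)) for l in loci]))


def effective_alleles(freqs: AlleleFrequencyTable, population: str) -> float:
    """Mean effective number of alleles per locus, ``1 / sum(p^2)``."""
    loci = _defined_loci(freqs, population)
    vals = []
    for l in loci:
        p = np.array(list(freqs.freq(population, l).values()))
        vals.append(1.0 / np.sum(p * p))
    return float(np.mean(vals))


def observed_heterozygosity(ds: GenotypeDataset, population: str) -> float:
    """Fraction of non-missing genotypes with two distinct alleles, mean over loci."""
    idx = ds.population_indices(population)
    sub = ds.calls[idx]
    vals = []
    for l in range(ds.n_loci):
        col = sub[:, l, :]
        defined = col[:, 0] != MISSING
        if not defined.any():
            continue
        het = col[defined, 0] != col[defined, 1]
        vals.append(het.mean())
    if not vals:
        raise ValueError(f"population {population!r} has no genotyped locus")
    return float(np.mean(vals))


def unbiased_expected_heterozygosity(freqs: AlleleFrequencyTable, population: str) -> float:
    """Nei's unbiased gene diversity, mean over loci with ``n >= 2``."""
    loci = _defined_loci(freqs, population, min_n=2)
    vals = []
    for l in loci:
        n = freqs.n(population, l)
        p = np.array(list(freqs.freq(population, l).values()))
        vals.append((2 * n / (2 * n - 1)) * (1.0 - np.sum(p * p)))
    return float(np.mean(vals))


@dataclass
class DiversityTable:
    """Per-population A, Ae, Ho, He plus group mean +/- sd rows."""

    per_population: pd.DataFrame  # index: population; columns A, Ae, Ho, He, group
    group_summary: pd.DataFrame | None  # index: group; columns <stat>_mean, <stat>_sd

    def to_tsv(self, path) -> None:
        frames = [self.per_population]
        if self.group_summary is not None:
            frames.append(self.group_summary)
        with open(path, "w") as fh:
            self.per_population.to_csv(fh, sep="\t", float_format="%.4f")
            if self.group_summary is not None:
                fh.write("\n")
                self.group_summary.to_csv(fh, sep="\t", float_format="%.4f")


def diversity_table(
    ds: GenotypeDataset,
    standardize_n: int | None = None,
    seed: int = 0,
) -> DiversityTable:
    """Compute the per-population diversity report.

    If ``standardize_n`` is given, every population is first subsampled to
    that many individuals (seeded, without replacement) so that allele counts
    are comparable across unequal sample sizes.
    """
    from .genotypes import standardize_sample

    if standardize_n is not None:
        ds = standardize_sample(ds, standardize_n, seed)
    freqs = allele_frequencies(ds)
    rows = {}
    for pop in ds.population_ids:
        rows[pop] = {
            "A": num_alleles(freqs, pop),
            "Ae": effective_alleles(freqs, pop),
            "Ho": observed_heterozygosity(ds, pop),
            "He": unbiased_expected_heterozygosity(freqs, pop),
        }
    per_pop = pd.DataFrame.from_dict(rows, orient="index")
    per_pop.index.name = "population"
    group_summary = None
    if ds.groups is not None:
        per_pop["group"] = [ds.groups[p] for p in per_pop.index]
        agg = per_pop.groupby("group", sort=False)[["A", "Ae", "Ho", "He"]]
        mean, sd = agg.mean(), agg.std(ddof=1)
        group_summary = pd.concat(
            {f"{c}_mean": mean[c] for c in mean} | {f"{c}_sd": sd[c] for c in sd}, axis=1
        )
    return DiversityTable(per_pop, group_summary)
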