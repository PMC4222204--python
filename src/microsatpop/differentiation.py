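"""Population differentiation statistics for multi-allelic markers.

Implements the heterozygosity-based family of estimators on allele-frequency
tables with Nei & Chesser small-sample bias corrections:

* ``gst`` -- multi-locus bias-corrected G_ST (the classical F_ST analogue for
  multi-allelic loci), aggregated over loci by summing numerators and
  denominators;
* ``hedrick_fst_prime`` -- Hedrick's standardized G'_ST = G_ST / G_ST(max),
  computed through the closed form
  ``G'_ST = G_ST * (k - 1 + HS) / ((k - 1) * (1 - HS))``;
* ``jost_d`` -- Jost's D, ``(k / (k - 1)) * (HT - HS) / (1 - HS)`` per locus.

Per locus, with ``k`` populations, unweighted mean allele frequencies and the
harmonic mean sample size ``n_h``:

    hs = 1 - mean_i sum_a p_ia^2          (uncorrected within)
    ht = 1 - sum_a pbar_a^2               (uncorrected total)
    HS = 2 n_h / (2 n_h - 1) * hs         (bias-corrected within)
    HT = ht + HS / (2 n_h k)              (bias-corrected total)

Negative estimates are legitimate sampling outcomes for undifferentiated
populations and are reported as computed, never clamped.

Resampling utilities (permutation tests between population pairs, bootstrap
intervals over individuals) and block summaries over phenotype groups round
out the pairwise analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import (
    AlleleFrequencyTable,
    GenotypeDataset,
    allele_frequencies,
)

__all__ = [
    "hs_ht",
    "corrected_heterozygosities",
    "gst",
    "hedrick_fst_prime",
    "jost_d",
    "multilocus_statistic",
    "pairwise_matrix",
    "PairwiseDifferentiation",
    "permutation_test",
    "bonferroni",
    "bootstrap_ci",
    "locus_group_differentiation",
    "block_summary",
    "pooled_group_frequencies",
]

STATISTICS = ("gst", "fst_prime", "jost_d")


def hs_ht(P: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    """Bias-corrected (HS, HT) from a dense frequency matrix.

    ``P`` is ``(k, n_alleles)`` with rows summing to 1; ``n`` holds diploid
    sample sizes.  Uses unweighted mean frequencies and the harmonic mean
    sample size, per the Nei-Chesser corrections in the module docstring.
    """
    P = np.asarray(P, dtype=float)
    n = np.asarray(n, dtype=float)
    k = P.shape[0]
    n_h = k / np.sum(1.0 / n)
    hs = 1.0 - np.mean(np.sum(P * P, axis=1))
    pbar = P.mean(axis=0)
    ht = 1.0 - np.sum(pbar * pbar)
    HS = (2.0 * n_h / (2.0 * n_h - 1.0)) * hs
    HT = ht + HS / (2.0 * n_h * k)
    return float(HS), float(HT)


def corrected_heterozygosities(
    freqs: AlleleFrequencyTable, populations: Sequence[str], locus: str
) -> tuple[float, float] | None:
    """Bias-corrected (HS, HT) at one locus, or None if undefined.

    A locus is undefined for a population set when any member population has
    no data there (missingness propagates as undefined, not as zero).
    """
    P, n, _ = freqs.frequency_matrix(locus, populations)
    if (n == 0).any() or P.shape[1] == 0:
        return None
    return hs_ht(P, n)


def _per_locus_components(
    freqs: AlleleFrequencyTable, populations: Sequence[str]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    loci, HS, HT = [], [], []
    for locus in freqs.loci:
        h = corrected_heterozygosities(freqs, populations, locus)
        if h is None:
            continue
        loci.append(locus)
        HS.append(h[0])
        HT.append(h[1])
    if not loci:
        raise ValueError("no locus is defined for all requested populations")
    return loci, np.asarray(HS), np.asarray(HT)


def gst(
    freqs: AlleleFrequencyTable,
    populations: Sequence[str] | None = None,
    per_locus: bool = False,
):
    """Multi-locus Nei-Chesser bias-corrected G_ST.

    Aggregation sums (HT - HS) and HT over loci.  Raises if every locus is
    globally monomorphic (HT = 0 everywhere).
    """
    pops = list(populations) if populations is not None else freqs.populations
    if len(pops) < 2:
        raise ValueError("G_ST needs at least two populations")
    loci, HS, HT = _per_locus_components(freqs, pops)
    if np.all(HT == 0):
        raise ValueError("all loci monomorphic across populations; G_ST undefined")
    value = float(np.sum(HT - HS) / np.sum(HT))
    if not per_locus:
        return value
    with np.errstate(divide="ignore", invalid="ignore"):
        per = np.where(HT > 0, (HT - HS) / np.where(HT > 0, HT, 1.0), np.nan)
    return value, pd.Series(per, index=loci, name="gst")


def _fst_prime_from(gst_value: float, hs_mean: float, k: int) -> float:
    if hs_mean >= 1.0:
        raise ValueError("HS = 1; standardized differentiation undefined")
    return gst_value * (k - 1 + hs_mean) / ((k - 1) * (1.0 - hs_mean))


def hedrick_fst_prime(
    freqs: AlleleFrequencyTable,
    populations: Sequence[str] | None = None,
    per_locus: bool = False,
):
    """Hedrick's standardized G'_ST (F'_ST) via the closed form.

    Equals G_ST / G_ST(max) with ``G_ST(max) = (k - 1)(1 - HS) / (k - 1 + HS)``.
    The multi-locus value uses the multi-locus G_ST and the mean corrected HS.
    """
    pops = list(populations) if populations is not None else freqs.populations
    if len(pops) < 2:
        raise ValueError("F'_ST needs at least two populations")
    loci, HS, HT = _per_locus_components(freqs, pops)
    if np.all(HT == 0):
        raise ValueError("all loci monomorphic; F'_ST undefined")
    k = len(pops)
    g_multi = float(np.sum(HT - HS) / np.sum(HT))
    value = _fst_prime_from(g_multi, float(np.mean(HS)), k)
    if not per_locus:
        return value
    per = []
    for hs_l, ht_l in zip(HS, HT):
        if ht_l <= 0 or hs_l >= 1.0:
            per.append(np.nan)
        else:
            per.append(_fst_prime_from((ht_l - hs_l) / ht_l, hs_l, k))
    return value, pd.Series(per, index=loci, name="fst_prime")


def jost_d(
    freqs: AlleleFrequencyTable,
    populations: Sequence[str] | None = None,
    per_locus: bool = False,
    aggregate: str = "arithmetic",
):
    """Jost's D per locus; multi-locus summary by arithmetic (default) or
    harmonic mean over defined loci."""
    pops = list(populations) if populations is not None else freqs.populations
    if len(pops) < 2:
        raise ValueError("Jost's D needs at least two populations")
    if aggregate not in ("arithmetic", "harmonic"):
        raise ValueError("aggregate must be 'arithmetic' or 'harmonic'")
    loci, HS, HT = _per_locus_components(freqs, pops)
    k = len(pops)
    per = np.full(len(loci), np.nan)
    ok = HS < 1.0
    per[ok] = (k / (k - 1.0)) * (HT[ok] - HS[ok]) / (1.0 - HS[ok])
    defined = per[~np.isnan(per)]
    if defined.size == 0:
        raise ValueError("Jost's D undefined at every locus (HS = 1)")
    if aggregate == "arithmetic":
        value = float(np.mean(defined))
    else:
        # Harmonic mean of 1/(1/D) following the additive-partition variant;
        # only defined when all per-locus values are positive.
        if np.any(defined <= 0):
            raise ValueError("harmonic aggregation requires positive per-locus D")
        value = float(defined.size / np.sum(1.0 / defined))
    if not per_locus:
        return value
    return value, pd.Series(per, index=loci, name="jost_d")


_STAT_FUNCS: dict[str, Callable] = {
    "gst": gst,
    "fst_prime": hedrick_fst_prime,
    "jost_d": jost_d,
}


def multilocus_statistic(
    ds: GenotypeDataset, populations: Sequence[str], statistic: str
) -> float:
    """Evaluate a named differentiation statistic on a dataset subset."""
    if statistic not in _STAT_FUNCS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    freqs = allele_frequencies(ds, populations)
    return _STAT_FUNCS[statistic](freqs, list(populations))


@dataclass
class PairwiseDifferentiation:
    """Symmetric matrix of a differentiation statistic over populations."""

    statistic: str
    matrix: pd.DataFrame          # symmetric, NaN diagonal
    pvalues: pd.DataFrame | None = None

    def pairs(self):
        """Iterate unordered pairs (p, q, value)."""
        pops = list(self.matrix.index)
        for i, p in enumerate(pops):
            for q in pops[:i]:
                yield p, q, float(self.matrix.loc[p, q])

    def to_tsv(self, path) -> None:
        """Lower-triangular layout matching the conventional printed table."""
        pops = list(self.matrix.index)
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(pops[:-1]) + "\n")
            for i in range(1, len(pops)):
                vals = [f"{self.matrix.iloc[i, j]:.4f}" for j in range(i)]
                fh.write(pops[i] + "\t" + "\t".join(vals) + "\n")


def pairwise_matrix(
    ds: GenotypeDataset,
    statistic: str = "fst_prime",
    n_perm: int | None = None,
    seed: int = 0,
) -> PairwiseDifferentiation:
    """Evaluate a statistic on every unordered population pair (k = 2).

    With ``n_perm`` set, a per-pair permutation p-value is attached.
    """
    pops = ds.population_ids
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    freqs = allele_frequencies(ds)
    M = pd.DataFrame(np.nan, index=pops, columns=pops)
    P = pd.DataFrame(np.nan, index=pops, columns=pops) if n_perm else None
    rng = np.random.default_rng(seed)
    for i, p in enumerate(pops):
        for q in pops[:i]:
            try:
                v = _STAT_FUNCS[statistic](freqs, [p, q])
            except ValueError:
                v = np.nan
            M.loc[p, q] = M.loc[q, p] = v
            if n_perm:
                pv = permutation_test(
                    ds, (p, q), statistic, n_perm, int(rng.integers(2**31 - 1))
                )
                P.loc[p, q] = P.loc[q, p] = pv
    return PairwiseDifferentiation(statistic, M, P)


def permutation_test(
    ds: GenotypeDataset,
    pair: tuple[str, str],
    statistic: str,
    n_perm: int,
    seed: int,
) -> float:
    """One-sided permutation p-value for differentiation > 0 between a pair.

    Individuals are shuffled between the two populations; the p-value uses the
    add-one rule ``(1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 for usable resolution")
    p, q = pair
    idx = np.concatenate([ds.population_indices(p), ds.population_indices(q)])
    n_p = len(ds.population_indices(p))
    sub = ds.subset_individuals(idx)
    labels = np.array([p] * n_p + [q] * (len(idx) - n_p), dtype=object)
    observed = _pair_stat(sub, labels, p, q, statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _pair_stat(sub, perm, p, q, statistic) >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def _pair_stat(ds: GenotypeDataset, labels: np.ndarray, p: str, q: str, statistic: str) -> float:
    relabeled = GenotypeDataset(
        individuals=list(ds.individuals),
        populations=list(labels),
        loci=list(ds.loci),
        calls=ds.calls,
    )
    return multilocus_statistic(relabeled, [p, q], statistic)


def bonferroni(pvals: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Boolean significance flags at the Bonferroni-corrected threshold."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    return p <= alpha / p.size


def bootstrap_ci(
    ds: GenotypeDataset,
    populations: Sequence[str],
    statistic: str = "jost_d",
    n_boot: int = 1000,
    seed: int = 0,
    bounds: str = "percentile",
) -> pd.DataFrame:
    """Per-locus bootstrap bounds for a differentiation statistic.

    Individuals are resampled with replacement within each population.
    ``bounds`` is ``"percentile"`` (2.5/97.5) or ``"minmax"``.
    Returns a DataFrame indexed by locus with columns ``point``, ``lower``,
    ``upper``.  Populations of size 1 are excluded (logged via ValueError if
    fewer than two usable populations remain).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if bounds not in ("percentile", "minmax"):
        raise ValueError("bounds must be 'percentile' or 'minmax'")
    usable = [p for p in populations if len(ds.population_indices(p)) > 1]
    if len(usable) < 2:
        raise ValueError("need at least two populations of size > 1")
    freqs = allele_frequencies(ds, usable)
    _, point = _STAT_FUNCS[statistic](freqs, usable, per_locus=True)
    rng = np.random.default_rng(seed)
    pop_idx = {p: ds.population_indices(p) for p in usable}
    reps = np.full((n_boot, len(ds.loci)), np.nan)
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(pop_idx[p], size=len(pop_idx[p]), replace=True) for p in usable]
        )
        boot = ds.subset_individuals(take)
        bfreqs = allele_frequencies(boot, usable)
        try:
            _, per = _STAT_FUNCS[statistic](bfreqs, usable, per_locus=True)
        except ValueError:
            continue
        reps[b] = per.reindex(ds.loci).to_numpy()
    with np.errstate(all="ignore"):
        if bounds == "percentile" and n_boot > 1:
            lower = np.nanpercentile(reps, 2.5, axis=0)
            upper = np.nanpercentile(reps, 97.5, axis=0)
        else:
            lower = np.nanmin(reps, axis=0)
            upper = np.nanmax(reps, axis=0)
    return pd.DataFrame(
        {"point": point.reindex(ds.loci).to_numpy(), "lower": lower, "upper": upper},
        index=pd.Index(ds.loci, name="locus"),
    )


def pooled_group_frequencies(ds: GenotypeDataset, groups: Mapping[str, str]) -> GenotypeDataset:
    """Relabel populations by their group so each group pools into one unit."""
    pops = [groups[p] for p in ds.populations]
    return GenotypeDataset(
        individuals=list(ds.individuals),
        populations=pops,
        loci=list(ds.loci),
        calls=ds.calls,
    )


def locus_group_differentiation(
    ds: GenotypeDataset,
    groups: Mapping[str, str],
    statistic: str = "jost_d",
    n_boot: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-locus differentiation within each group and between the two groups.

    Within-group values treat the member populations as units; the
    between-group value pools each group's individuals into a single unit
    (k = 2).  With ``n_boot > 0`` bootstrap bounds are attached per column.
    """
    by_group: dict[str, list[str]] = {}
    for p in ds.population_ids:
        by_group.setdefault(groups[p], []).append(p)
    if len(by_group) != 2:
        raise ValueError("exactly two groups are required")
    (g1, pops1), (g2, pops2) = by_group.items()
    pooled = pooled_group_frequencies(ds, groups)
    out = {}
    specs = [
        (f"within_{g1}", ds, pops1),
        (f"within_{g2}", ds, pops2),
        ("between", pooled, [g1, g2]),
    ]
    rng = np.random.default_rng(seed)
    for name, data, pops in specs:
        if len(pops) < 2:
            out[name] = np.full(ds.n_loci, np.nan)  # single-population group
            continue
        freqs = allele_frequencies(data, pops)
        _, per = _STAT_FUNCS[statistic](freqs, pops, per_locus=True)
        out[name] = per.reindex(ds.loci).to_numpy()
        if n_boot:
            ci = bootstrap_ci(
                data, pops, statistic, n_boot, int(rng.integers(2**31 - 1))
            )
            out[f"{name}_lower"] = ci["lower"].to_numpy()
            out[f"{name}_upper"] = ci["upper"].to_numpy()
    return pd.DataFrame(out, index=pd.Index(ds.loci, name="locus"))


def block_summary(
    matrix: PairwiseDifferentiation | pd.DataFrame,
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Mean/min/max of pairwise values within and between two phenotype groups.

    Returns a DataFrame indexed by ``within_<g1>``, ``within_<g2>``,
    ``between`` with columns ``mean``, ``min``, ``max``, ``n_pairs``.  A group
    with fewer than two populations yields NaN for its within block.
    """
    M = matrix.matrix if isinstance(matrix, PairwiseDifferentiation) else matrix
    pops = list(M.index)
    unmapped = [p for p in pops if p not in groups]
    if unmapped:
        raise ValueError(f"populations not in group mapping: {unmapped}")
    labels = sorted(set(groups[p] for p in pops), key=[groups[p] for p in pops].index)
    if len(labels) != 2:
        raise ValueError("block summary requires exactly two groups")
    g1, g2 = labels
    blocks: dict[str, list[float]] = {f"within_{g1}": [], f"within_{g2}": [], "between": []}
    for i, p in enumerate(pops):
        for q in pops[:i]:
            v = float(M.loc[p, q])
            if groups[p] == groups[q]:
                blocks[f"within_{groups[p]}"].append(v)
            else:
                blocks["between"].append(v)
    rows = {}
    for name, vals in blocks.items():
        if vals:
            rows[name] = {
                "mean": float(np.mean(vals)),
                "min": float(np.min(vals)),
                "max": float(np.max(vals)),
                "n_pairs": len(vals),
            }
        else:
            rows[name] = {"mean": np.nan, "min": np.nan, "max": np.nan, "n_pairs": 0}
    return pd.DataFrame.from_dict(rows, orient="index")
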