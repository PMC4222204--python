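"""F_ST-outlier detection against a coalescent island-model null.

The scan follows the FDIST logic: simulate a large cloud of unlinked neutral
loci under a symmetric island model whose migration rate is tuned so the
expected multi-locus F_ST matches the observed one, summarize the cloud as
heterozygosity-conditional quantile curves (median and the 0.5%/99.5% bounds
of a 99% envelope), and flag observed loci whose (He, F_ST) falls outside the
envelope at their heterozygosity.

He here is the bias-corrected mean within-population gene diversity and F_ST
the bias-corrected G_ST -- the same estimators, applied identically to
simulated and observed loci, so the conditioning axis is consistent.

Because neighbouring populations are not independent observations, the scan
is run on three population sets (all populations, and each phenotype group
separately); a locus is called selection-associated when it is an outlier in
the whole set but in neither single-group set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _coalescent
from .differentiation import hs_ht
from .genotypes import GenotypeDataset, allele_frequencies

__all__ = [
    "OutlierScanSettings",
    "NeutralEnvelope",
    "simulate_neutral_cloud",
    "build_envelope",
    "observed_locus_stats",
    "classify_loci",
    "scan_population_set",
    "three_set_scan",
]


@dataclass
class OutlierScanSettings:
    """Simulation settings for the neutral envelope."""

    n_demes: int = 100           # island-model demes (sampled demes are a subset)
    n_loci: int = 20000          # neutral cloud size
    n_bins: int = 20             # equal-occupancy He bins for the quantile curves
    min_bin_points: int = 50
    mutation: str = "smm"        # "smm" (stepwise) or "iam" (infinite alleles)
    gsm_p: float = 0.0           # geometric step parameter of the stepwise model
    theta_range: tuple[float, float] = (0.05, 20.0)  # population-scaled, log-uniform
    calibrate: bool = True       # pilot-round tuning of the migration rate
    pilot_loci: int = 2000
    trim: bool = True            # one outlier-trimmed re-estimate of target F_ST
    seed: int = 0


@dataclass
class NeutralEnvelope:
    """Simulated (He, F_ST) cloud with binned quantile curves."""

    cloud: pd.DataFrame                 # columns he, fst
    bin_centers: np.ndarray
    lower: np.ndarray                   # 0.5% curve
    median: np.ndarray
    upper: np.ndarray                   # 99.5% curve
    settings: dict = field(default_factory=dict)

    def curves_at(self, he: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        he = np.asarray(he, dtype=float)
        lo = np.interp(he, self.bin_centers, self.lower)
        med = np.interp(he, self.bin_centers, self.median)
        hi = np.interp(he, self.bin_centers, self.upper)
        return lo, med, hi

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "he": self.bin_centers,
                "lower": self.lower,
                "median": self.median,
                "upper": self.upper,
            }
        ).to_csv(path, sep="\t", index=False)


def _migration_for_target(target_fst: float, n_demes: int) -> float:
    """Invert F_ST = 1 / (1 + M d / (d - 1)) for the scaled migration rate."""
    if target_fst <= 0.0:
        return 1e9  # effectively panmictic
    return (1.0 / target_fst - 1.0) * (n_demes - 1.0) / n_demes


def _locus_he_fst(alleles: np.ndarray, deme_of_gene: np.ndarray, n_per_deme: np.ndarray):
    """Bias-corrected (He, F_ST) for one simulated locus."""
    states, inv = np.unique(alleles, return_inverse=True)
    k = n_per_deme.shape[0]
    counts = np.zeros((k, states.size))
    np.add.at(counts, (deme_of_gene, inv), 1.0)
    P = counts / counts.sum(axis=1, keepdims=True)
    HS, HT = hs_ht(P, n_per_deme)
    fst = np.nan if HT <= 0 else (HT - HS) / HT
    return HS, fst


def _simulate_cloud_block(
    M: float,
    sample_sizes: np.ndarray,
    settings: OutlierScanSettings,
    n_loci: int,
    seed_seq: np.random.SeedSequence,
) -> pd.DataFrame:
    rng = np.random.default_rng(seed_seq)
    seeds = rng.integers(0, 2**31 - 1, size=n_loci).astype(np.int64)
    lo, hi = settings.theta_range
    thetas = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_loci))
    # theta is scaled to the whole population: mean within-deme pair time is
    # d (units of 2N), so a per-lineage rate theta/(2 d) yields expected
    # pairwise diversity theta.
    rates = thetas / (2.0 * settings.n_demes)
    genes = (2 * sample_sizes).astype(np.int64)
    mats = _coalescent.island_cloud(
        seeds, genes, M, settings.n_demes, rates,
        settings.mutation == "smm", settings.gsm_p,
    )
    deme_of_gene = np.repeat(np.arange(sample_sizes.size), genes)
    he = np.empty(n_loci)
    fst = np.empty(n_loci)
    for l in range(n_loci):
        he[l], fst[l] = _locus_he_fst(mats[l], deme_of_gene, sample_sizes)
    return pd.DataFrame({"he": he, "fst": fst})


def simulate_neutral_cloud(
    target_fst: float,
    sample_sizes: Sequence[int],
    settings: OutlierScanSettings | None = None,
    migration_rate: float | None = None,
) -> NeutralEnvelope:
    """Simulate the neutral (He, F_ST) cloud for a target mean F_ST.

    The migration rate starts from the analytic island-model inversion and,
    with ``settings.calibrate``, is refined by pilot simulation so the
    realized multi-locus F_ST of the cloud matches the target (mutation-model
    homoplasy slightly deflates heterozygosity-based F_ST relative to the
    branch-length expectation; the pilot round absorbs that).

    Returns a :class:`NeutralEnvelope` whose quantile curves are not yet
    built (see :func:`build_envelope`) -- the ``cloud`` field carries the
    points and ``settings`` the provenance.
    """
    settings = settings or OutlierScanSettings()
    sizes = np.asarray(sample_sizes, dtype=np.int64)
    if sizes.size < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 sampled demes with >= 2 diploids each")
    if not 0.0 <= target_fst < 1.0:
        raise ValueError("target_fst must be in [0, 1)")
    if settings.n_demes < sizes.size:
        raise ValueError("island model needs at least as many demes as sampled populations")
    seed_seq = np.random.SeedSequence(settings.seed)
    children = seed_seq.spawn(4)
    M = migration_rate if migration_rate is not None else _migration_for_target(
        target_fst, settings.n_demes)
    if migration_rate is None and settings.calibrate and target_fst > 0.0:
        for round_i in range(2):
            pilot = _simulate_cloud_block(M, sizes, settings, settings.pilot_loci, children[round_i])
            realized = _multilocus_fst_of_cloud(pilot)
            if realized <= 0 or abs(realized - target_fst) < 0.002:
                break
            M *= (1.0 / target_fst - 1.0) / (1.0 / realized - 1.0)
            M = max(M, 1e-3)
    cloud = _simulate_cloud_block(M, sizes, settings, settings.n_loci, children[3])
    recorded = {
        "target_fst": target_fst,
        "migration_rate": M,
        "n_demes": settings.n_demes,
        "sample_sizes": [int(s) for s in sizes],
        "mutation": settings.mutation,
        "n_loci": settings.n_loci,
        "theta_range": list(settings.theta_range),
        "seed": settings.seed,
    }
    return NeutralEnvelope(
        cloud=cloud,
        bin_centers=np.empty(0),
        lower=np.empty(0),
        median=np.empty(0),
        upper=np.empty(0),
        settings=recorded,
    )


def _multilocus_fst_of_cloud(cloud: pd.DataFrame) -> float:
    # ratio-of-sums aggregation, matching the multi-locus G_ST convention:
    # fst = (HT - HS)/HT and he = HS per locus, so HT = HS / (1 - fst)
    hs = cloud["he"].to_numpy()
    fst = cloud["fst"].to_numpy()
    ok = np.isfinite(fst) & (fst < 1.0)
    ht = hs[ok] / (1.0 - fst[ok])
    return float(np.sum(ht - hs[ok]) / np.sum(ht))


def build_envelope(envelope: NeutralEnvelope, n_bins: int | None = None,
                   min_bin_points: int = 50) -> NeutralEnvelope:
    """Bin the cloud into equal-occupancy He bins and attach quantile curves.

    Bins with fewer than ``min_bin_points`` points are merged with their
    neighbour.  Curves are interpolated piecewise-linearly between bin mean
    heterozygosities.
    """
    cloud = envelope.cloud.dropna()
    if cloud.empty:
        raise ValueError("empty cloud")
    n_bins = n_bins or 20
    if n_bins < 5:
        raise ValueError("n_bins must be >= 5")
    he = cloud["he"].to_numpy()
    fst = cloud["fst"].to_numpy()
    order = np.argsort(he, kind="stable")
    he, fst = he[order], fst[order]
    edges = np.linspace(0, he.size, n_bins + 1).astype(int)
    groups: list[np.ndarray] = []
    start = 0
    for b in range(n_bins):
        stop = edges[b + 1]
        if stop - start < min_bin_points and b < n_bins - 1:
            continue  # merge into the next bin
        idx = np.arange(start, stop)
        if idx.size < min_bin_points and groups:
            groups[-1] = np.concatenate([groups[-1], idx])
        elif idx.size:
            groups.append(idx)
        start = stop
    centers, lo, med, hi = [], [], [], []
    for idx in groups:
        centers.append(he[idx].mean())
        q = np.quantile(fst[idx], [0.005, 0.5, 0.995])
        lo.append(q[0])
        med.append(q[1])
        hi.append(q[2])
    envelope.bin_centers = np.asarray(centers)
    envelope.lower = np.asarray(lo)
    envelope.median = np.asarray(med)
    envelope.upper = np.asarray(hi)
    return envelope


def observed_locus_stats(
    ds: GenotypeDataset, populations: Sequence[str]
) -> pd.DataFrame:
    """Per-locus (He, F_ST) of the observed data for one population set."""
    freqs = allele_frequencies(ds, list(populations))
    rows = {}
    for locus in ds.loci:
        P, n, _ = freqs.frequency_matrix(locus, list(populations))
        if (n == 0).any() or P.shape[1] == 0:
            rows[locus] = {"he": np.nan, "fst": np.nan}
            continue
        HS, HT = hs_ht(P, n)
        rows[locus] = {"he": HS, "fst": np.nan if HT <= 0 else (HT - HS) / HT}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "locus"
    return df


def classify_loci(observed: pd.DataFrame, envelope: NeutralEnvelope) -> pd.DataFrame:
    """Classify observed loci against the envelope curves.

    Adds ``status`` (``outlier_high`` / ``outlier_low`` / ``neutral``) and an
    ``extrapolated`` flag for loci whose He lies outside the simulated bin
    range (they are judged against the nearest bin).
    """
    if envelope.bin_centers.size == 0:
        raise ValueError("envelope has no curves; call build_envelope first")
    if observed.empty:
        raise ValueError("no observed loci")
    he = observed["he"].to_numpy(dtype=float)
    fst = observed["fst"].to_numpy(dtype=float)
    lo, med, hi = envelope.curves_at(he)
    status = np.full(he.size, "neutral", dtype=object)
    with np.errstate(invalid="ignore"):
        status[fst > hi] = "outlier_high"
        status[fst < lo] = "outlier_low"
    out = observed.copy()
    out["status"] = status
    out["extrapolated"] = (he < envelope.bin_centers[0]) | (he > envelope.bin_centers[-1])
    out.loc[~np.isfinite(fst), "status"] = "neutral"
    return out


def _multilocus_target(observed: pd.DataFrame, exclude: Sequence[str] = ()) -> float:
    keep = observed.drop(index=list(exclude), errors="ignore").dropna()
    hs = keep["he"].to_numpy()
    ht = hs / (1.0 - keep["fst"].to_numpy())
    target = float(np.sum(ht - hs) / np.sum(ht))
    return max(target, 0.0)


def scan_population_set(
    ds: GenotypeDataset,
    populations: Sequence[str],
    settings: OutlierScanSettings | None = None,
) -> tuple[pd.DataFrame, NeutralEnvelope]:
    """Run the outlier scan on one population set.

    The null target F_ST is the observed multi-locus value; with
    ``settings.trim`` the scan runs once, drops flagged loci from the target,
    and re-runs with the trimmed target (the conventional single re-run).
    """
    settings = settings or OutlierScanSettings()
    observed = observed_locus_stats(ds, populations)
    sizes = [len(ds.population_indices(p)) for p in populations]
    target = _multilocus_target(observed)
    env = build_envelope(
        simulate_neutral_cloud(target, sizes, settings),
        settings.n_bins, settings.min_bin_points,
    )
    classified = classify_loci(observed, env)
    if settings.trim:
        flagged = classified.index[classified["status"] != "neutral"]
        if len(flagged):
            trimmed = _multilocus_target(observed, exclude=flagged)
            if abs(trimmed - target) > 1e-3:
                env = build_envelope(
                    simulate_neutral_cloud(trimmed, sizes, settings),
                    settings.n_bins, settings.min_bin_points,
                )
                classified = classify_loci(observed, env)
    return classified, env


def three_set_scan(
    ds: GenotypeDataset,
    groups: Mapping[str, str] | None = None,
    settings: OutlierScanSettings | None = None,
) -> pd.DataFrame:
    """Outlier scan on all populations and on each phenotype group.

    Returns a per-locus DataFrame with the three statuses and a boolean
    ``selection_associated`` column: outlier in the whole set AND neutral in
    both within-group scans (the decision rule that screens out loci whose
    signal comes from structure inside one group).
    """
    settings = settings or OutlierScanSettings()
    groups = groups if groups is not None else ds.groups
    if groups is None:
        raise ValueError("group mapping required")
    by_group: dict[str, list[str]] = {}
    for p in ds.population_ids:
        by_group.setdefault(groups[p], []).append(p)
    if len(by_group) != 2 or any(len(v) < 2 for v in by_group.values()):
        raise ValueError("need two groups with >= 2 populations each")
    (g1, pops1), (g2, pops2) = by_group.items()
    sets = {"all": ds.population_ids, g1: pops1, g2: pops2}
    seed_seq = np.random.SeedSequence(settings.seed).spawn(len(sets))
    out = pd.DataFrame(index=pd.Index(ds.loci, name="locus"))
    statuses = {}
    for (name, pops), child in zip(sets.items(), seed_seq):
        sub_settings = OutlierScanSettings(**{**settings.__dict__, "seed": int(child.generate_state(1)[0] % (2**31 - 1))})
        classified, _ = scan_population_set(ds, pops, sub_settings)
        statuses[name] = classified["status"]
        out[f"fst_{name}"] = classified["fst"]
        out[f"status_{name}"] = classified["status"]
    out["selection_associated"] = (
        (statuses["all"] != "neutral")
        & (statuses[g1] == "neutral")
        & (statuses[g2] == "neutral")
    )
    return out
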