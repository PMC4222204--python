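"""Bayesian admixture clustering and Evanno delta-K model selection.

A reduced-scale re-implementation of the classical admixture Gibbs sampler
for multi-locus genotype data: each allele copy carries a latent cluster
assignment ``z``; cluster allele frequencies get conjugate Dirichlet updates
(uniform lambda = 1), and each individual's admixture proportions ``q`` get a
Dirichlet update with a fixed uniform hyperparameter alpha = 1 (no alpha
sampling, no correlated-frequencies model -- deliberately the simplest
admixture variant).

The number of clusters is chosen with Evanno's second-difference statistic
over mean data log-likelihoods from repeated runs:

    delta_K = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd L(K)

which is undefined at the scan endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeDataset

__all__ = [
    "ClusteringResult",
    "fit_admixture",
    "run_k_scan",
    "evanno_delta_k",
    "choose_k",
    "match_clusters_to_groups",
    "assignment_agreement",
]


@dataclass
class ClusteringResult:
    """Posterior summaries of one admixture run at fixed K."""

    K: int
    Q: pd.DataFrame                 # posterior-mean memberships, rows sum to 1
    cluster_freqs: list[np.ndarray]  # per locus (K, n_alleles), rows sum to 1
    allele_states: list[np.ndarray]  # per locus the allele state of each column
    ln_likelihood: float            # mean post-burn-in log P(X | Q, F)
    ln_trace: np.ndarray            # per-iteration log-likelihood (post burn-in)
    settings: dict


def _encode(ds: GenotypeDataset):
    """Integer-code alleles per locus; missing copies masked."""
    n, L = ds.n_individuals, ds.n_loci
    codes = np.zeros((n, L, 2), dtype=np.int64)
    missing = np.zeros((n, L), dtype=bool)
    states: list[np.ndarray] = []
    for l in range(L):
        col = ds.calls[:, l, :]
        miss = col[:, 0] == MISSING
        missing[:, l] = miss
        st = np.unique(col[~miss].ravel()) if (~miss).any() else np.array([1])
        lookup = {int(a): j for j, a in enumerate(st)}
        states.append(st)
        for c in range(2):
            codes[~miss, l, c] = [lookup[int(a)] for a in col[~miss, c]]
    return codes, missing, states


def fit_admixture(
    ds: GenotypeDataset,
    K: int,
    burn_in: int = 1000,
    n_iter: int = 6000,
    seed: int = 0,
    alpha: float = 1.0,
    freq_lambda: float = 1.0,
) -> ClusteringResult:
    """Run the admixture Gibbs sampler at fixed K.

    ``n_iter`` is the total sweep count including ``burn_in``.  Returns
    posterior means over the retained sweeps; deterministic given ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > ds.n_individuals:
        raise ValueError("K cannot exceed the number of individuals")
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    rng = np.random.default_rng(seed)
    codes, missing, states = _encode(ds)
    n, L, _ = codes.shape
    a_max = max(s.size for s in states)
    valid = np.zeros((L, a_max), dtype=bool)
    for l, s in enumerate(states):
        valid[l, : s.size] = True
    obs = ~missing[:, :, None] & np.ones((n, L, 2), dtype=bool)
    n_obs_copies = int(obs.sum())

    # initial state: uniform Q, frequencies from pooled counts
    Q = np.full((n, K), 1.0 / K)
    F = np.zeros((K, L, a_max))
    for l, s in enumerate(states):
        pooled = np.bincount(codes[~missing[:, l], l, :].ravel(), minlength=s.size) + 1.0
        F[:, l, : s.size] = pooled / pooled.sum()

    lidx = np.arange(L)[None, :, None]
    Q_sum = np.zeros_like(Q)
    F_sum = np.zeros_like(F)
    trace = np.empty(n_iter - burn_in)
    kept = 0
    for sweep in range(n_iter):
        # P(z = k) for every allele copy: (n, L, 2, K)
        probs = F[:, lidx, codes].transpose(1, 2, 3, 0) * Q[:, None, None, :]
        total = probs.sum(axis=3)
        total = np.where(total > 0, total, 1.0)
        if K == 1:
            Z = np.zeros((n, L, 2), dtype=np.int64)
        else:
            cum = np.cumsum(probs, axis=3)
            u = rng.random((n, L, 2)) * total
            Z = (cum < u[..., None]).sum(axis=3)
            np.clip(Z, 0, K - 1, out=Z)
        # conjugate frequency update
        counts = np.zeros((K, L, a_max))
        sel = obs
        np.add.at(
            counts,
            (Z[sel], np.broadcast_to(lidx, Z.shape)[sel], codes[sel]),
            1.0,
        )
        g = rng.gamma(freq_lambda + counts)
        g[:, ~valid] = 0.0
        F = g / g.sum(axis=2, keepdims=True)
        # admixture update
        m = np.zeros((n, K))
        iidx = np.broadcast_to(np.arange(n)[:, None, None], Z.shape)
        np.add.at(m, (iidx[sel], Z[sel]), 1.0)
        gq = rng.gamma(alpha + m)
        Q = gq / gq.sum(axis=1, keepdims=True)
        if sweep >= burn_in:
            lnp = float(np.log(total[~missing]).sum())
            trace[kept] = lnp
            Q_sum += Q
            F_sum += F
            kept += 1
    Q_mean = Q_sum / kept
    F_mean = F_sum / kept
    Qdf = pd.DataFrame(
        Q_mean, index=pd.Index(ds.individuals, name="individual"),
        columns=[f"q{k+1}" for k in range(K)],
    )
    return ClusteringResult(
        K=K,
        Q=Qdf,
        cluster_freqs=[F_mean[:, l, : states[l].size] for l in range(L)],
        allele_states=states,
        ln_likelihood=float(trace.mean()),
        ln_trace=trace,
        settings={"burn_in": burn_in, "n_iter": n_iter, "seed": seed,
                  "alpha": alpha, "freq_lambda": freq_lambda,
                  "n_obs_copies": n_obs_copies},
    )


def run_k_scan(
    ds: GenotypeDataset,
    k_values=range(1, 7),
    n_runs: int = 5,
    burn_in: int = 1000,
    n_iter: int = 6000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[int, int], ClusteringResult]]:
    """Repeated admixture runs over a K range.

    Returns the runs-by-K mean log-likelihood table (rows = run index) and
    every fitted result keyed by ``(K, run)``.
    """
    ks = sorted(k_values)
    seeds = np.random.SeedSequence(seed).generate_state(len(ks) * n_runs) % (2**31 - 1)
    table = pd.DataFrame(index=pd.RangeIndex(n_runs, name="run"), columns=ks, dtype=float)
    results: dict[tuple[int, int], ClusteringResult] = {}
    si = 0
    for K in ks:
        for r in range(n_runs):
            res = fit_admixture(ds, K, burn_in, n_iter, int(seeds[si]))
            si += 1
            table.loc[r, K] = res.ln_likelihood
            results[(K, r)] = res
    return table, results


def evanno_delta_k(lnp_table: pd.DataFrame) -> pd.Series:
    """Evanno's delta-K from a runs-by-K log-likelihood table.

    Requires >= 3 consecutive K values and >= 2 runs per K.  A zero
    between-run standard deviation yields ``inf`` with a warning.
    """
    ks = sorted(int(k) for k in lnp_table.columns)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need at least three consecutive K values")
    if len(lnp_table) < 2:
        raise ValueError("need at least two runs per K")
    mean = lnp_table.mean(axis=0)
    sd = lnp_table.std(axis=0, ddof=1)
    out = {}
    for k in ks[1:-1]:
        second = abs(mean[k + 1] - 2.0 * mean[k] + mean[k - 1])
        if sd[k] == 0:
            warnings.warn(f"zero run-to-run sd at K={k}; delta-K reported as inf")
            out[k] = np.inf
        else:
            out[k] = second / sd[k]
    return pd.Series(out, name="delta_k").rename_axis("K")


def choose_k(lnp_table: pd.DataFrame) -> int:
    """K with the largest Evanno delta-K."""
    dk = evanno_delta_k(lnp_table)
    return int(dk.idxmax())


def match_clusters_to_groups(
    Q: pd.DataFrame, ds: GenotypeDataset
) -> dict[str, str]:
    """Greedy majority matching from cluster columns to group labels."""
    if ds.groups is None:
        raise ValueError("dataset has no group mapping")
    labels = np.array([ds.groups[p] for p in ds.populations], dtype=object)
    hard = Q.to_numpy().argmax(axis=1)
    mapping: dict[str, str] = {}
    contingency = pd.crosstab(hard, labels)
    for k in contingency.index:
        mapping[Q.columns[k]] = contingency.loc[k].idxmax()
    return mapping


def assignment_agreement(Q: pd.DataFrame, ds: GenotypeDataset) -> float:
    """Fraction of individuals whose modal cluster matches their group.

    Cluster labels are aligned to groups by the best label permutation, so
    the score is invariant to label swapping.
    """
    if ds.groups is None:
        raise ValueError("dataset has no group mapping")
    labels = np.array([ds.groups[p] for p in ds.populations], dtype=object)
    hard = Q.to_numpy().argmax(axis=1)
    groups = list(dict.fromkeys(labels))
    K = Q.shape[1]
    best = 0.0
    # exact search over injective cluster->group maps for small K
    from itertools import permutations, combinations

    for subset in combinations(range(K), min(K, len(groups))):
        for perm in permutations(groups, len(subset)):
            m = dict(zip(subset, perm))
            score = np.mean([m.get(h) == g for h, g in zip(hard, labels)])
            best = max(best, float(score))
    return best
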