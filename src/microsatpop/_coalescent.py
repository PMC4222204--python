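"""Coalescent simulation kernels (numba-compiled).

Two simulators back the stochastic parts of the pipeline:

``island_locus``
    One unlinked locus under a finite symmetric island model with ``d`` demes
    and scaled migration rate ``M = 4Nm``, using the many-demes two-phase
    approximation: an instantaneous within-deme "scattering" phase in which
    each sampled deme's lineages either coalesce (probability
    ``(j-1)/(j-1+M)`` per event) or escape, followed by a "collecting" phase
    in which the escaped lineages follow a Kingman coalescent with pair rate
    ``1 / (d + (d-1)/M)`` (time in units of ``2N`` generations).  Under this
    model the expected F_ST is ``1 / (1 + M d / (d - 1))``, which is the
    relation used to invert a target F_ST into a migration rate.

``divergence_locus``
    One locus under the two-population divergence scenarios: a derived
    population of size ``N_der`` that passes through a bottleneck of size
    ``Nb`` for ``db`` generations ending at the split time ``t1`` (looking
    back), then merges into the ancestral lineage.  Time is in generations
    with per-pair coalescence rate ``1/(2N)``.

Microsatellite mutation follows the generalized stepwise model: motif steps
of geometrically distributed size (parameter ``P``; ``P = 0`` is the strict
single-step model) in either direction, constrained to 40 contiguous motif
states by reflecting boundaries (implemented exactly by folding the free
walk), plus rare single-nucleotide indels that shift the fragment length off
the motif ladder by one base.  Allele states are reported as fragment lengths
in base pairs on a dinucleotide ladder.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: number of contiguous motif states available to the stepwise walk
MOTIF_STATES = 40
#: base-pair length of the shortest motif state (keeps states 3-digit safe)
BASE_LENGTH = 150
#: motif (repeat unit) size in base pairs
MOTIF_BP = 2


@njit(cache=True)
def _geom_step(P: float) -> int:
    """Step magnitude >= 1 with P(s) = (1-P) P^(s-1)."""
    if P <= 0.0:
        return 1
    u = np.random.random()
    return 1 + int(np.log(u) / np.log(P))


@njit(cache=True)
def _fold_motif(x: int) -> int:
    """Reflect a free walk position into [0, MOTIF_STATES - 1]."""
    period = 2 * (MOTIF_STATES - 1)
    m = x % period
    if m < 0:
        m += period
    if m > MOTIF_STATES - 1:
        m = period - m
    return m


@njit(cache=True)
def island_locus(
    seed: int,
    genes_per_deme: np.ndarray,  # int64[:] sampled gene copies per sampled deme
    M: float,
    n_demes: int,
    rate: float,  # mutations per lineage per 2N generations
    stepwise: bool,
    gsm_p: float,
) -> np.ndarray:
    """Simulate allele states for one locus; returns int32[n_genes]."""
    np.random.seed(seed)
    n = 0
    for g in genes_per_deme:
        n += g
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    next_node = n

    escaped = np.empty(n, dtype=np.int64)
    n_esc = 0
    pos = 0
    for di in range(genes_per_deme.shape[0]):
        j = genes_per_deme[di]
        loc = np.empty(j, dtype=np.int64)
        for x in range(j):
            loc[x] = pos + x
        pos += j
        while j > 1:
            if np.random.random() < (j - 1.0) / (j - 1.0 + M):
                i1 = np.random.randint(j)
                i2 = np.random.randint(j - 1)
                if i2 >= i1:
                    i2 += 1
                parent[loc[i1]] = next_node
                parent[loc[i2]] = next_node
                node_time[next_node] = 0.0
                loc[i1] = next_node
                loc[i2] = loc[j - 1]
                next_node += 1
                j -= 1
            else:
                i1 = np.random.randint(j)
                escaped[n_esc] = loc[i1]
                n_esc += 1
                loc[i1] = loc[j - 1]
                j -= 1
        if j == 1:
            escaped[n_esc] = loc[0]
            n_esc += 1

    lam = 1.0 / (n_demes + (n_demes - 1.0) / M)
    act = escaped[:n_esc].copy()
    k = n_esc
    t = 0.0
    while k > 1:
        total = 0.5 * k * (k - 1.0) * lam
        t += np.random.exponential(1.0 / total)
        i1 = np.random.randint(k)
        i2 = np.random.randint(k - 1)
        if i2 >= i1:
            i2 += 1
        parent[act[i1]] = next_node
        parent[act[i2]] = next_node
        node_time[next_node] = t
        act[i1] = next_node
        act[i2] = act[k - 1]
        next_node += 1
        k -= 1
    root = next_node - 1

    out = np.empty(n, dtype=np.int32)
    if stepwise:
        disp = np.zeros(n_nodes, dtype=np.int64)
        for node in range(root - 1, -1, -1):
            edge = node_time[parent[node]] - node_time[node]
            d = disp[parent[node]]
            if edge > 0.0:
                n_mut = np.random.poisson(rate * edge)
                for _ in range(n_mut):
                    s = _geom_step(gsm_p)
                    if np.random.random() < 0.5:
                        d += s
                    else:
                        d -= s
            disp[node] = d
        for leaf in range(n):
            out[leaf] = BASE_LENGTH + MOTIF_BP * _fold_motif(MOTIF_STATES // 2 + disp[leaf])
    else:
        # infinite-alleles: the newest mutation on the root-to-leaf path
        # defines the allele; mutation-free paths keep the root allele 0
        allele = np.zeros(n_nodes, dtype=np.int64)
        fresh = 1
        for node in range(root - 1, -1, -1):
            edge = node_time[parent[node]] - node_time[node]
            a = allele[parent[node]]
            if edge > 0.0 and np.random.poisson(rate * edge) > 0:
                a = fresh
                fresh += 1
            allele[node] = a
        for leaf in range(n):
            out[leaf] = BASE_LENGTH + allele[leaf]
    return out


@njit(cache=True)
def divergence_locus(
    seed: int,
    n1: int,  # sampled gene copies in population 1
    n2: int,  # sampled gene copies in population 2
    scenario: int,  # 0: single deme of size size1_0; 1/2/3: see module docstring
    size1_0: float,
    size2_0: float,
    size1_b: float,
    size2_b: float,
    size_anc: float,
    t_bottleneck_start: float,  # generations before present (t1 - db)
    t_merge: float,  # t1 in generations
    mu: float,  # motif mutations per locus per generation
    gsm_p: float,
    sni: float,  # single-nucleotide-indel mutations per locus per generation
) -> np.ndarray:
    """Simulate one locus under a divergence/bottleneck scenario.

    ``size*_0`` are the deme sizes from the present back to the bottleneck
    start, ``size*_b`` during the bottleneck, ``size_anc`` after the merge.
    Scenario semantics are resolved by the caller through these sizes; the
    kernel only distinguishes "two demes that merge at t_merge" (scenario
    1/2/3) from "one deme forever" (scenario 0).
    """
    np.random.seed(seed)
    n = n1 + n2
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    deme = np.empty(n_nodes, dtype=np.int64)
    act = np.empty(n, dtype=np.int64)
    for i in range(n):
        act[i] = i
        deme[i] = 0 if i < n1 else 1
    next_node = n
    k = n
    t = 0.0
    merged = scenario == 0
    while k > 1:
        # current deme sizes
        if merged:
            s1 = size_anc if scenario != 0 else size1_0
            s2 = s1
        elif t < t_bottleneck_start:
            s1, s2 = size1_0, size2_0
        else:
            s1, s2 = size1_b, size2_b
        k1 = 0
        for i in range(k):
            if deme[act[i]] == 0:
                k1 += 1
        k2 = k - k1
        if merged:
            rate_total = 0.5 * k * (k - 1.0) / (2.0 * s1)
            r1 = rate_total
        else:
            r1 = 0.5 * k1 * (k1 - 1.0) / (2.0 * s1)
            r2 = 0.5 * k2 * (k2 - 1.0) / (2.0 * s2)
            rate_total = r1 + r2
        # next epoch boundary
        if merged:
            boundary = np.inf
        elif t < t_bottleneck_start:
            boundary = t_bottleneck_start
        else:
            boundary = t_merge
        if rate_total <= 0.0:
            t = boundary
        else:
            dt = np.random.exponential(1.0 / rate_total)
            if t + dt >= boundary:
                t = boundary
            else:
                t = t + dt
                # choose deme, then a random pair within it
                target = 0
                if not merged and np.random.random() * rate_total >= r1:
                    target = 1
                idx = np.empty(k, dtype=np.int64)
                cnt = 0
                for i in range(k):
                    if merged or deme[act[i]] == target:
                        idx[cnt] = i
                        cnt += 1
                i1 = idx[np.random.randint(cnt)]
                i2 = idx[np.random.randint(cnt)]
                while i2 == i1:
                    i2 = idx[np.random.randint(cnt)]
                a, b = act[i1], act[i2]
                parent[a] = next_node
                parent[b] = next_node
                node_time[next_node] = t
                deme[next_node] = deme[a]
                act[i1] = next_node
                act[i2] = act[k - 1]
                next_node += 1
                k -= 1
                continue
        # reached a boundary without coalescing
        if not merged and t >= t_merge:
            merged = True
            for i in range(k):
                deme[act[i]] = 0
    root = next_node - 1

    motif = np.zeros(n_nodes, dtype=np.int64)
    indel = np.zeros(n_nodes, dtype=np.int64)
    for node in range(root - 1, -1, -1):
        edge = node_time[parent[node]] - node_time[node]
        dm = motif[parent[node]]
        di = indel[parent[node]]
        if edge > 0.0:
            for _ in range(np.random.poisson(mu * edge)):
                s = _geom_step(gsm_p)
                if np.random.random() < 0.5:
                    dm += s
                else:
                    dm -= s
            if sni > 0.0:
                for _ in range(np.random.poisson(sni * edge)):
                    if np.random.random() < 0.5:
                        di += 1
                    else:
                        di -= 1
        motif[node] = dm
        indel[node] = di
    out = np.empty(n, dtype=np.int32)
    for leaf in range(n):
        length = BASE_LENGTH + MOTIF_BP * _fold_motif(MOTIF_STATES // 2 + motif[leaf]) + indel[leaf]
        if length < 1:
            length = 1
        out[leaf] = length
    return out


@njit(cache=True)
def divergence_dataset(
    seeds: np.ndarray,  # int64[n_loci]
    n1: int,
    n2: int,
    scenario: int,
    size1_0: float,
    size2_0: float,
    size1_b: float,
    size2_b: float,
    size_anc: float,
    t_bottleneck_start: float,
    t_merge: float,
    mu: float,
    gsm_p: float,
    sni: float,
) -> np.ndarray:
    """All loci of one dataset; returns int32[n_loci, n1 + n2]."""
    L = seeds.shape[0]
    out = np.empty((L, n1 + n2), dtype=np.int32)
    for l in range(L):
        out[l] = divergence_locus(
            seeds[l], n1, n2, scenario,
            size1_0, size2_0, size1_b, size2_b, size_anc,
            t_bottleneck_start, t_merge, mu, gsm_p, sni,
        )
    return out


@njit(cache=True)
def island_cloud(
    seeds: np.ndarray,  # int64[n_loci]
    genes_per_deme: np.ndarray,
    M: float,
    n_demes: int,
    rates: np.ndarray,  # float64[n_loci] per-locus mutation rates
    stepwise: bool,
    gsm_p: float,
) -> np.ndarray:
    """Island-model alleles for many loci; returns int32[n_loci, n_genes]."""
    L = seeds.shape[0]
    n = 0
    for g in genes_per_deme:
        n += g
    out = np.empty((L, n), dtype=np.int32)
    for l in range(L):
        out[l] = island_locus(seeds[l], genes_per_deme, M, n_demes, rates[l], stepwise, gsm_p)
    return out
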