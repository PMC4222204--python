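"""Independent brute-force implementations of the differentiation formulas.

Deliberately written from the published definitions with no code shared with
the package: plain floats, explicit loops, no numpy vectorization.  These are
the oracles the package estimators are checked against.
"""

from __future__ import annotations


def oracle_hs_ht(freq_rows: list[list[float]], sample_sizes: list[int]) -> tuple[float, float]:
    """Nei-Chesser corrected HS, HT from per-population frequency lists."""
    k = len(freq_rows)
    inv_sum = 0.0
    for n in sample_sizes:
        inv_sum += 1.0 / n
    n_harm = k / inv_sum
    hs_raw = 0.0
    for row in freq_rows:
        s = 0.0
        for p in row:
            s += p * p
        hs_raw += 1.0 - s
    hs_raw /= k
    n_alleles = len(freq_rows[0])
    ht_raw = 1.0
    for a in range(n_alleles):
        pbar = 0.0
        for row in freq_rows:
            pbar += row[a]
        pbar /= k
        ht_raw -= pbar * pbar
    HS = (2.0 * n_harm / (2.0 * n_harm - 1.0)) * hs_raw
    HT = ht_raw + HS / (2.0 * n_harm * k)
    return HS, HT


def oracle_gst(freq_rows, sample_sizes) -> float:
    HS, HT = oracle_hs_ht(freq_rows, sample_sizes)
    return (HT - HS) / HT


def oracle_gst_max(freq_rows, sample_sizes) -> float:
    """Maximum attainable G_ST given within-population diversity."""
    k = len(freq_rows)
    HS, _ = oracle_hs_ht(freq_rows, sample_sizes)
    return (k - 1.0) * (1.0 - HS) / (k - 1.0 + HS)


def oracle_fst_prime(freq_rows, sample_sizes) -> float:
    """Standardized differentiation as the ratio G_ST / G_ST(max)."""
    return oracle_gst(freq_rows, sample_sizes) / oracle_gst_max(freq_rows, sample_sizes)


def oracle_jost_d(freq_rows, sample_sizes) -> float:
    k = len(freq_rows)
    HS, HT = oracle_hs_ht(freq_rows, sample_sizes)
    return (k / (k - 1.0)) * (HT - HS) / (1.0 - HS)
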