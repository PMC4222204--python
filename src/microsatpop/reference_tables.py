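"""Published summary tables from the original *Banksia attenuata* field study.

The genotype matrix behind the study was never deposited, but its printed
per-population diversity table and pairwise standardized-differentiation
matrix are public.  They are shipped here as plain TSV resources so block
summaries and group means can be recomputed and checked against the quoted
results, and so the synthetic-data generator has concrete targets to emulate.

Populations L1-L6 are the northern lignotuberous group; E1-E8 the southern
epicormic group.
"""

from __future__ import annotations

from importlib.resources import files

import numpy as np
import pandas as pd

__all__ = ["published_diversity", "published_fst_prime_matrix", "published_groups"]

_REF = files("microsatpop") / "refdata"


def published_diversity() -> pd.DataFrame:
    """Per-population A, Ae, Ho, He with group labels, indexed by population."""
    with (_REF / "diversity_by_population.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col="population")


def published_groups() -> dict[str, str]:
    """Population -> phenotype-group mapping for the 14 study populations."""
    df = published_diversity()
    return df["group"].to_dict()


def published_fst_prime_matrix() -> pd.DataFrame:
    """The printed pairwise F'_ST matrix as a full symmetric DataFrame."""
    with (_REF / "pairwise_fst_prime.tsv").open() as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    cols = lines[0].split("\t")[1:]
    rows = [l.split("\t") for l in lines[1:]]
    pops = cols + [rows[-1][0]]
    M = pd.DataFrame(np.nan, index=pops, columns=pops)
    for parts in rows:
        r = parts[0]
        for j, cell in enumerate(parts[1:]):
            M.loc[r, cols[j]] = M.loc[cols[j], r] = float(cell)
    return M
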