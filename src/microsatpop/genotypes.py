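"""Data model and I/O for diploid microsatellite genotypes.

The central container is :class:`GenotypeDataset`: an ``(n_individuals,
n_loci, 2)`` integer array of allele states (repeat-unit-scaled fragment
lengths, as read from the genotyping pipeline) together with individual ids,
per-individual population labels, locus names, and an optional mapping of
populations to phenotype groups (e.g. ``lignotuberous`` / ``epicormic``).

Allele states are positive integers; ``0`` marks a missing call.  A call is
always both-present or both-missing -- half-missing genotypes are rejected at
load time.

Supported formats:

* GenePop (2- or 3-digit allele coding, ``POP``-delimited blocks);
* a plain TSV dialect with columns ``individual``, ``population`` and one
  column per locus holding ``a1/a2`` cells (``./.`` for missing);
* a two-column population-to-group mapping TSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "AlleleFrequencyTable",
    "GenepopParseError",
    "GenepopEncodeError",
    "read_genepop",
    "write_genepop",
    "read_table",
    "write_table",
    "read_group_map",
    "attach_groups",
    "write_group_map",
    "allele_frequencies",
    "standardize_sample",
]

#: Sentinel allele state for a missing call.
MISSING = 0


class GenepopParseError(ValueError):
    """Malformed GenePop input; carries the offending line number."""


class GenepopEncodeError(ValueError):
    """Dataset cannot be represented in 3-digit GenePop coding."""


@dataclass
class GenotypeDataset:
    """Diploid codominant genotype calls for one or more populations.

    Parameters
    ----------
    individuals
        Individual identifiers, one per sampled plant.
    populations
        Population label per individual (parallel to ``individuals``).
    loci
        Locus names.
    calls
        Integer array ``(n_individuals, n_loci, 2)``; 0 encodes missing.
    groups
        Optional mapping from population label to phenotype-group label.
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    calls: np.ndarray
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        n, L = len(self.individuals), len(self.loci)
        if n < 1 or L < 1:
            raise ValueError("dataset needs at least one individual and one locus")
        if len(self.populations) != n:
            raise ValueError("populations must parallel individuals")
        if self.calls.shape != (n, L, 2):
            raise ValueError(f"calls must have shape ({n}, {L}, 2), got {self.calls.shape}")
        if (self.calls < 0).any():
            raise ValueError("allele states must be positive (0 = missing)")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing call for individual {self.individuals[i]!r} at locus {self.loci[l]!r}"
            )
        if self.groups is not None:
            missing = [p for p in self.population_ids if p not in self.groups]
            if missing:
                raise ValueError(f"groups mapping lacks populations: {missing}")

    # -- basic structure ---------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_ids(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.populations, dtype=object) == population)
        if idx.size == 0:
            raise KeyError(f"unknown population {population!r}")
        return idx

    def population_sizes(self) -> dict[str, int]:
        return {p: len(self.population_indices(p)) for p in self.population_ids}

    def subset_individuals(self, indices: Sequence[int]) -> "GenotypeDataset":
        idx = np.asarray(indices, dtype=int)
        return GenotypeDataset(
            individuals=[self.individuals[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            loci=list(self.loci),
            calls=self.calls[idx].copy(),
            groups=None if self.groups is None else dict(self.groups),
        )

    def subset_populations(self, populations: Iterable[str]) -> "GenotypeDataset":
        keep = list(populations)
        for p in keep:
            self.population_indices(p)  # raises on unknown
        idx = [i for i, p in enumerate(self.populations) if p in set(keep)]
        ds = self.subset_individuals(idx)
        if ds.groups is not None:
            ds.groups = {p: g for p, g in ds.groups.items() if p in set(keep)}
        return ds

    def subset_loci(self, loci: Iterable[str]) -> "GenotypeDataset":
        keep = list(loci)
        pos = [self.loci.index(l) for l in keep]
        return GenotypeDataset(
            individuals=list(self.individuals),
            populations=list(self.populations),
            loci=keep,
            calls=self.calls[:, pos].copy(),
            groups=None if self.groups is None else dict(self.groups),
        )

    def with_groups(self, groups: Mapping[str, str]) -> "GenotypeDataset":
        return replace(self, groups=dict(groups))

    def group_populations(self) -> dict[str, list[str]]:
        """Populations keyed by group label, in first-appearance order."""
        if self.groups is None:
            raise ValueError("dataset has no group mapping")
        out: dict[str, list[str]] = {}
        for p in self.population_ids:
            out.setdefault(self.groups[p], []).append(p)
        return out

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class AlleleFrequencyTable:
    """Per (population, locus) allele relative frequencies with sample sizes.

    ``n`` counts non-missing *diploid individuals*; frequencies are computed
    over the ``2 n`` observed allele copies.  A (population, locus) with no
    non-missing calls has ``n = 0`` and an empty frequency map, which
    downstream statistics treat as *undefined* (never as zero diversity).
    """

    populations: list[str]
    loci: list[str]
    freqs: dict[tuple[str, str], dict[int, float]]
    counts: dict[tuple[str, str], int]

    def freq(self, population: str, locus: str) -> dict[int, float]:
        return self.freqs[(population, locus)]

    def n(self, population: str, locus: str) -> int:
        return self.counts[(population, locus)]

    def alleles(self, locus: str) -> list[int]:
        """Union of allele states observed at a locus, sorted."""
        out: set[int] = set()
        for p in self.populations:
            out.update(self.freqs[(p, locus)])
        return sorted(out)

    def frequency_matrix(self, locus: str, populations: Sequence[str] | None = None):
        """Dense ``(n_pops, n_alleles)`` frequency matrix and sample sizes.

        Returns ``(P, n, alleles)`` where rows of ``P`` sum to 1 for defined
        populations and to 0 where ``n == 0``.
        """
        pops = list(populations) if populations is not None else self.populations
        alleles = self.alleles(locus)
        index = {a: j for j, a in enumerate(alleles)}
        P = np.zeros((len(pops), len(alleles)))
        n = np.zeros(len(pops), dtype=int)
        for i, p in enumerate(pops):
            n[i] = self.counts[(p, locus)]
            for a, f in self.freqs[(p, locus)].items():
                P[i, index[a]] = f
        return P, n, alleles


# ---------------------------------------------------------------------------
# GenePop I/O
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(path: str | Path, pop_names: str = "auto") -> GenotypeDataset:
    """Parse a GenePop file into a :class:`GenotypeDataset`.

    Both 2- and 3-digit allele codings are accepted (inferred from token
    width); ``00``/``000`` codes map to missing.  Individual labels may be
    separated from genotypes by a comma or a tab.

    Parameters
    ----------
    pop_names
        ``"auto"`` names POP blocks ``pop1..popK``; ``"last-label"`` uses the
        label of the last individual in each block (a common GenePop habit).
    """
    if pop_names not in ("auto", "last-label"):
        raise ValueError("pop_names must be 'auto' or 'last-label'")
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError("empty file (line 1)")
    # Header: title line, then locus names until the first POP.
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            loci.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise GenepopParseError("no POP line found")
    if not loci:
        raise GenepopParseError("no locus names before first POP (line 2)")

    blocks: list[list[tuple[str, list[str], int]]] = []
    current: list[tuple[str, list[str], int]] | None = None
    for lineno in range(i, len(lines)):
        line = lines[lineno]
        if _POP_RE.match(line):
            current = []
            blocks.append(current)
            continue
        if not line.strip():
            continue
        if current is None:
            raise GenepopParseError(f"genotype data before POP (line {lineno + 1})")
        if "," in line:
            label, _, rest = line.partition(",")
        elif "\t" in line:
            label, _, rest = line.partition("\t")
        else:
            raise GenepopParseError(
                f"no comma/tab separator after individual label (line {lineno + 1})"
            )
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise GenepopParseError(
                f"expected {len(loci)} genotypes, found {len(tokens)} (line {lineno + 1})"
            )
        current.append((label.strip(), tokens, lineno + 1))
    if not any(blocks):
        raise GenepopParseError("no individuals found")

    # Allele code width: per-file, from token length (4 -> 2-digit, 6 -> 3).
    widths = {len(t) for block in blocks for _, toks, _ in block for t in toks}
    if not widths <= {4, 6}:
        bad = sorted(widths - {4, 6})
        raise GenepopParseError(f"genotype tokens must be 4 or 6 digits wide, got width(s) {bad}")
    if len(widths) > 1:
        raise GenepopParseError("mixed 2- and 3-digit allele coding in one file")
    half = widths.pop() // 2

    individuals: list[str] = []
    populations: list[str] = []
    rows: list[list[list[int]]] = []
    for b, block in enumerate(blocks):
        if not block:
            raise GenepopParseError(f"empty POP block {b + 1}")
        name = f"pop{b + 1}" if pop_names == "auto" else block[-1][0]
        for label, tokens, lineno in block:
            calls_row: list[list[int]] = []
            for tok in tokens:
                if not tok.isdigit():
                    raise GenepopParseError(f"non-numeric genotype {tok!r} (line {lineno})")
                a1, a2 = int(tok[:half]), int(tok[half:])
                if (a1 == 0) != (a2 == 0):
                    # GenePop allows half-missing; collapse to fully missing.
                    a1 = a2 = MISSING
                calls_row.append([a1, a2])
            individuals.append(label)
            populations.append(name)
            rows.append(calls_row)
    return GenotypeDataset(
        individuals=individuals,
        populations=populations,
        loci=loci,
        calls=np.asarray(rows, dtype=np.int32),
    )


def write_genepop(ds: GenotypeDataset, path: str | Path, title: str = "microsatpop export") -> None:
    """Write 3-digit GenePop; missing calls as ``000000``.

    One POP block is emitted per population in dataset order.
    """
    if ds.calls.max(initial=0) > 999:
        raise GenepopEncodeError("allele state > 999 cannot be written in 3-digit GenePop")
    out = [title]
    out.extend(ds.loci)
    for pop in ds.population_ids:
        out.append("POP")
        for i in ds.population_indices(pop):
            geno = " ".join(f"{a1:03d}{a2:03d}" for a1, a2 in ds.calls[i])
            out.append(f"{ds.individuals[i]} ,  {geno}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Plain TSV dialect
# ---------------------------------------------------------------------------

def read_table(path: str | Path) -> GenotypeDataset:
    """Read the plain TSV genotype dialect.

    Columns: ``individual``, ``population``, then one column per locus with
    ``a1/a2`` cells and ``./.`` for missing.
    """
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    header = lines[0].split("\t")
    if header[:2] != ["individual", "population"]:
        raise ValueError("TSV must start with columns 'individual', 'population'")
    loci = header[2:]
    individuals, populations, rows = [], [], []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ValueError(f"row width mismatch (line {lineno})")
        individuals.append(parts[0])
        populations.append(parts[1])
        row = []
        for cell in parts[2:]:
            if cell in ("./.", ".", ""):
                row.append([MISSING, MISSING])
            else:
                a1, _, a2 = cell.partition("/")
                row.append([int(a1), int(a2)])
        rows.append(row)
    return GenotypeDataset(individuals, populations, loci, np.asarray(rows, dtype=np.int32))


def write_table(ds: GenotypeDataset, path: str | Path) -> None:
    out = ["\t".join(["individual", "population", *ds.loci])]
    for i, ind in enumerate(ds.individuals):
        cells = [
            "./." if a1 == MISSING else f"{a1}/{a2}" for a1, a2 in ds.calls[i]
        ]
        out.append("\t".join([ind, ds.populations[i], *cells]))
    Path(path).write_text("\n".join(out) + "\n")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``population<TAB>group`` mapping (header optional)."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"expected two tab-separated columns (line {lineno})")
        if lineno == 1 and parts[0].lower() in ("population", "pop"):
            continue
        mapping[parts[0].strip()] = parts[1].strip()
    if not mapping:
        raise ValueError("empty group mapping")
    return mapping


def write_group_map(groups: Mapping[str, str], path: str | Path) -> None:
    out = ["population\tgroup"]
    out += [f"{p}\t{g}" for p, g in groups.items()]
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Frequencies and standardization
# ---------------------------------------------------------------------------

def attach_groups(ds: GenotypeDataset, mapping: Mapping[str, str]) -> GenotypeDataset:
    """Attach a population->group sidecar mapping to a dataset.

    GenePop does not standardize population naming, so blocks read from it
    are auto-numbered.  If the mapping's keys match the dataset's population
    ids they are used directly; otherwise, when the mapping has exactly one
    entry per population, its keys (in file order) *rename* the POP blocks
    and its values supply the groups.
    """
    pops = ds.population_ids
    if set(mapping) >= set(pops):
        return ds.with_groups({p: mapping[p] for p in pops})
    if len(mapping) != len(pops):
        raise ValueError(
            f"group mapping has {len(mapping)} entries for {len(pops)} populations")
    rename = dict(zip(pops, mapping.keys()))
    renamed = GenotypeDataset(
        individuals=list(ds.individuals),
        populations=[rename[p] for p in ds.populations],
        loci=list(ds.loci),
        calls=ds.calls.copy(),
    )
    return renamed.with_groups(dict(mapping))


def allele_frequencies(
    ds: GenotypeDataset, populations: Sequence[str] | None = None
) -> AlleleFrequencyTable:
    """Per-(population, locus) allele relative frequencies.

    Counts run over the ``2n`` non-missing allele copies; ``n`` records the
    number of non-missing diploid individuals.
    """
    pops = list(populations) if populations is not None else ds.population_ids
    freqs: dict[tuple[str, str], dict[int, float]] = {}
    counts: dict[tuple[str, str], int] = {}
    for pop in pops:
        idx = ds.population_indices(pop)
        sub = ds.calls[idx]  # (n, L, 2)
        for l, locus in enumerate(ds.loci):
            col = sub[:, l, :]
            defined = col[:, 0] != MISSING
            n = int(defined.sum())
            counts[(pop, locus)] = n
            if n == 0:
                freqs[(pop, locus)] = {}
                continue
            copies = col[defined].ravel()
            states, cnt = np.unique(copies, return_counts=True)
            freqs[(pop, locus)] = {
                int(a): c / (2 * n) for a, c in zip(states, cnt)
            }
    return AlleleFrequencyTable(pops, list(ds.loci), freqs, counts)


def standardize_sample(ds: GenotypeDataset, n_per_pop: int, seed: int) -> GenotypeDataset:
    """Subsample every population to exactly ``n_per_pop`` individuals.

    Individuals are drawn without replacement; the draw is deterministic for a
    given ``seed``.  This mirrors the common practice of comparing diversity
    on equal sample sizes.
    """
    if n_per_pop < 1:
        raise ValueError("n_per_pop must be positive")
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for pop in ds.population_ids:
        idx = ds.population_indices(pop)
        if idx.size < n_per_pop:
            raise ValueError(
                f"population {pop!r} has {idx.size} individuals, fewer than {n_per_pop}"
            )
        chosen = rng.choice(idx, size=n_per_pop, replace=False)
        keep.extend(sorted(int(i) for i in chosen))
    return ds.subset_individuals(keep)
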