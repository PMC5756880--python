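"""Core data model and I/O for diploid co-dominant microsatellite genotypes.

A :class:`GenotypeDataset` holds one species' multilocus genotypes, grouped
into population samples.  Allele calls are positive integers on a fragment
length (or repeat count) ladder; ``0`` is the reserved missing code.  A
genotype is either fully observed (both alleles positive) or fully missing
(both zero) — half calls are rejected at parse time, since co-dominant
scoring yields both alleles or neither.

Supported serialisations: the GenePop text format in its 2- and 3-digit
dialects, and a simple CSV dialect with one row per individual and ``a1/a2``
locus columns (``.`` for missing).
"""

from __future__ import annotations

import copy
import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MISSING = 0  # reserved allele code for a missing call


class GenotypeParseError(ValueError):
    """Malformed genotype file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class GenotypeEncodeError(ValueError):
    """Dataset cannot be written in the requested dialect."""


@dataclass
class PopulationSample:
    """One sampled location: individual ids and an (n, L, 2) allele array."""

    id: str
    individual_ids: list[str]
    genotypes: np.ndarray  # int array, shape (n_individuals, n_loci, 2)
    location_name: str = ""

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (n, n_loci, 2)")
        if self.genotypes.shape[0] != len(self.individual_ids):
            raise ValueError("individual_ids length does not match genotypes")
        if self.genotypes.shape[0] < 1:
            raise ValueError("a population sample needs at least one individual")
        half = (self.genotypes == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-missing genotype call (one allele 0)")
        if (self.genotypes < 0).any():
            raise ValueError("allele codes must be non-negative integers")
        if not self.location_name:
            self.location_name = self.id

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class GenotypeDataset:
    """Diploid multilocus genotypes for one species across populations."""

    species_label: str
    locus_names: list[str]
    populations: list[PopulationSample]
    ploidy: int = 2

    def __post_init__(self):
        if self.ploidy != 2:
            raise ValueError("only diploid data are supported")
        seen: set[str] = set()
        for pop in self.populations:
            if pop.id in seen:
                raise ValueError(f"duplicate population label {pop.id!r}")
            seen.add(pop.id)
            if pop.n_loci != len(self.locus_names):
                raise ValueError(
                    f"population {pop.id!r} has {pop.n_loci} loci, "
                    f"expected {len(self.locus_names)}"
                )

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def population_ids(self) -> list[str]:
        return [p.id for p in self.populations]

    def population(self, pop_id: str) -> PopulationSample:
        for p in self.populations:
            if p.id == pop_id:
                return p
        raise KeyError(pop_id)

    def subset(self, pop_ids: Sequence[str]) -> "GenotypeDataset":
        """Dataset restricted to the given populations, in the given order."""
        pops = [copy.deepcopy(self.population(pid)) for pid in pop_ids]
        return GenotypeDataset(self.species_label, list(self.locus_names), pops)

    def locus_index(self, locus: str) -> int:
        return self.locus_names.index(locus)

    def copy(self) -> "GenotypeDataset":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# GenePop dialect
# ---------------------------------------------------------------------------

def _decode_call(token: str, allele_digits: int, line: int) -> tuple[int, int]:
    if len(token) != 2 * allele_digits or not token.isdigit():
        raise GenotypeParseError(
            f"genotype token {token!r} is not {2 * allele_digits} digits", line
        )
    a1 = int(token[:allele_digits])
    a2 = int(token[allele_digits:])
    if (a1 == 0) != (a2 == 0):
        raise GenotypeParseError(f"half-missing call {token!r}", line)
    return a1, a2


def read_genepop(path: str | Path, allele_digits: int = 3,
                 species_label: str | None = None) -> GenotypeDataset:
    """Parse a GenePop file (title line, locus names, ``Pop`` blocks).

    Locus names may be one per line or comma-separated on one line.  The
    population id is the name of the *last* individual in each block, the
    GenePop convention.
    """
    if allele_digits not in (2, 3):
        raise GenotypeParseError(f"unsupported allele digit width {allele_digits}")
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GenotypeParseError("file too short for GenePop layout", len(lines))
    title = lines[0].strip()

    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        locus_names.extend(chunk)
        i += 1
    if i == len(lines):
        raise GenotypeParseError("no 'Pop' separator found", len(lines))
    if not locus_names:
        raise GenotypeParseError("no locus names before first 'Pop'", i + 1)

    blocks: list[list[tuple[str, list[tuple[int, int]]]]] = []
    current: list[tuple[str, list[tuple[int, int]]]] | None = None
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        if not raw.strip():
            continue
        if raw.strip().lower() == "pop":
            if current is not None and not current:
                raise GenotypeParseError("empty Pop block", lineno + 1)
            current = []
            blocks.append(current)
            continue
        if current is None:
            raise GenotypeParseError("individual row before first 'Pop'", lineno + 1)
        if "," not in raw:
            raise GenotypeParseError("individual row lacks ',' separator", lineno + 1)
        name, _, rest = raw.partition(",")
        tokens = rest.split()
        if len(tokens) != len(locus_names):
            raise GenotypeParseError(
                f"{len(tokens)} genotype tokens for {len(locus_names)} loci",
                lineno + 1,
            )
        calls = [_decode_call(t, allele_digits, lineno + 1) for t in tokens]
        current.append((name.strip(), calls))
    if current is not None and not current:
        raise GenotypeParseError("empty trailing Pop block", len(lines))

    pops = []
    seen_ids: set[str] = set()
    for k, block in enumerate(blocks):
        names = [n for n, _ in block]
        geno = np.array([c for _, c in block], dtype=np.int64)
        pop_id = names[-1]
        if pop_id in seen_ids:  # fall back to a unique synthetic label
            pop_id = f"{pop_id}_{k + 1}"
        seen_ids.add(pop_id)
        pops.append(PopulationSample(pop_id, names, geno))
    return GenotypeDataset(species_label or title, locus_names, pops)


def write_genepop(ds: GenotypeDataset, path: str | Path,
                  allele_digits: int = 3, title: str | None = None) -> None:
    """Write GenePop text that :func:`read_genepop` parses back identically.

    Individual names are rewritten so that the last individual of each block
    carries the population id (how GenePop denotes population labels).
    """
    if allele_digits not in (2, 3):
        raise GenotypeEncodeError(f"unsupported allele digit width {allele_digits}")
    limit = 10 ** allele_digits - 1
    if any(p.genotypes.max(initial=0) > limit for p in ds.populations):
        raise GenotypeEncodeError(
            f"allele code exceeds {allele_digits}-digit width"
        )
    out = [title or ds.species_label or "coevmosaic dataset"]
    out.extend(ds.locus_names)
    for pop in ds.populations:
        out.append("Pop")
        n = pop.n_individuals
        for i in range(n):
            name = pop.id if i == n - 1 else f"{pop.id}-{i + 1}"
            tokens = [
                f"{a1:0{allele_digits}d}{a2:0{allele_digits}d}"
                for a1, a2 in pop.genotypes[i]
            ]
            out.append(f"{name} , " + " ".join(tokens))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# CSV dialect: id, population, then one column per locus holding "a1/a2"
# ---------------------------------------------------------------------------

def read_csv(path: str | Path, species_label: str | None = None) -> GenotypeDataset:
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise GenotypeParseError("empty CSV file")
    header = rows[0]
    if len(header) < 3 or header[0] != "id" or header[1] != "population":
        raise GenotypeParseError("CSV header must start with id,population,<loci…>", 1)
    locus_names = header[2:]
    by_pop: dict[str, list[tuple[str, list[tuple[int, int]]]]] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != len(header):
            raise GenotypeParseError(
                f"{len(row)} columns for {len(header)} header fields", lineno
            )
        ind, pop = row[0], row[1]
        calls = []
        for cell in row[2:]:
            cell = cell.strip()
            if cell in (".", "./.", ""):
                calls.append((MISSING, MISSING))
                continue
            a, sep, b = cell.partition("/")
            if not sep or not a.strip().isdigit() or not b.strip().isdigit():
                raise GenotypeParseError(f"bad genotype cell {cell!r}", lineno)
            a1, a2 = int(a), int(b)
            if (a1 == 0) != (a2 == 0):
                raise GenotypeParseError(f"half-missing cell {cell!r}", lineno)
            calls.append((a1, a2))
        by_pop.setdefault(pop, []).append((ind, calls))
    pops = [
        PopulationSample(pid, [n for n, _ in block],
                         np.array([c for _, c in block], dtype=np.int64))
        for pid, block in by_pop.items()
    ]
    return GenotypeDataset(species_label or path.stem, locus_names, pops)


def write_csv(ds: GenotypeDataset, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "population"] + list(ds.locus_names))
        for pop in ds.populations:
            for i, ind in enumerate(pop.individual_ids):
                cells = [
                    "." if a1 == MISSING else f"{a1}/{a2}"
                    for a1, a2 in pop.genotypes[i]
                ]
                w.writerow([ind, pop.id] + cells)


# ---------------------------------------------------------------------------
# Clone handling
# ---------------------------------------------------------------------------

@dataclass
class CloneRemovalLog:
    removed: list[tuple[str, str, str]] = field(default_factory=list)
    """(population id, removed individual, retained representative) triples."""


def deduplicate_clones(ds: GenotypeDataset) -> tuple[GenotypeDataset, CloneRemovalLog]:
    """Collapse identical multilocus genotypes within each population.

    Missing is treated as a distinct state: two individuals are clones only
    if their full allele arrays match exactly.  The first individual of each
    clone group is retained.  Off by default in the pipeline — the field
    design (few individuals per tree) already limits clonality — so every
    removal is logged.
    """
    log = CloneRemovalLog()
    new_pops = []
    for pop in ds.populations:
        keep: list[int] = []
        rep: dict[bytes, int] = {}
        for i in range(pop.n_individuals):
            key = pop.genotypes[i].tobytes()
            if key in rep:
                log.removed.append(
                    (pop.id, pop.individual_ids[i], pop.individual_ids[rep[key]])
                )
            else:
                rep[key] = i
                keep.append(i)
        new_pops.append(
            PopulationSample(
                pop.id,
                [pop.individual_ids[i] for i in keep],
                pop.genotypes[keep].copy(),
                pop.location_name,
            )
        )
    return GenotypeDataset(ds.species_label, list(ds.locus_names), new_pops), log
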