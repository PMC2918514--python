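"""Data model and I/O for binary food webs.

A food web with S species is an S×S connection matrix A in which entry
(i, j) = 1 means consumer i eats resource j (rows are consumers, columns
are resources).  Species are identified by name; an optional vector of
average body masses (grams) supports the allometric niche model.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FoodWeb",
    "WebStats",
    "read_web",
    "write_web",
    "read_body_masses",
    "web_stats",
]


@dataclass
class FoodWeb:
    """A binary consumer–resource web.

    Parameters
    ----------
    species
        Ordered, unique species names.
    A
        S×S matrix of 0/1; ``A[i, j] == 1`` iff consumer ``i`` eats
        resource ``j``.  Diagonal entries (cannibalism) are legal.
    body_mass
        Optional per-species average body mass in grams (all positive).
    """

    species: list[str]
    A: np.ndarray
    body_mass: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.species = [str(s) for s in self.species]
        self.A = np.asarray(self.A)
        S = len(self.species)
        if S < 2:
            raise ValueError(f"a food web needs at least 2 species, got {S}")
        if len(set(self.species)) != S:
            raise ValueError("duplicate species names")
        if self.A.shape != (S, S):
            raise ValueError(
                f"connection matrix shape {self.A.shape} does not match "
                f"{S} species"
            )
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("connection matrix entries must be 0 or 1")
        self.A = self.A.astype(np.int8)
        if self.body_mass is not None:
            m = np.asarray(self.body_mass, dtype=float)
            if m.shape != (S,):
                raise ValueError("body_mass length does not match species")
            if not (np.isfinite(m) & (m > 0)).all():
                raise ValueError("body masses must be positive and finite")
            self.body_mass = m

    @property
    def S(self) -> int:
        return len(self.species)

    def index(self, name: str) -> int:
        return self.species.index(name)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FoodWeb):
            return NotImplemented
        same_mass = (
            (self.body_mass is None) == (other.body_mass is None)
            and (
                self.body_mass is None
                or np.allclose(self.body_mass, other.body_mass)
            )
        )
        return (
            self.species == other.species
            and np.array_equal(self.A, other.A)
            and same_mass
        )


@dataclass
class WebStats:
    """Summary counts for a web: S, L, connectance and degree vectors."""

    S: int
    L: int
    C: float                      # directed connectance L / S^2
    links_per_species: float      # L / S
    R: np.ndarray                 # per-species prey counts (row sums)
    Cn: np.ndarray                # per-species predator counts (column sums)
    basal: set[str] = field(default_factory=set)       # R_i = 0
    specialists: set[str] = field(default_factory=set)  # R_i = 1


def web_stats(web: FoodWeb) -> WebStats:
    """Compute link counts, connectance and basal/specialist sets."""
    R = web.A.sum(axis=1).astype(int)
    Cn = web.A.sum(axis=0).astype(int)
    L = int(web.A.sum())
    S = web.S
    return WebStats(
        S=S,
        L=L,
        C=L / S**2,
        links_per_species=L / S,
        R=R,
        Cn=Cn,
        basal={s for s, r in zip(web.species, R) if r == 0},
        specialists={s for s, r in zip(web.species, R) if r == 1},
    )


def _detect_format(path: Path) -> str:
    return "edgelist-tsv" if path.suffix.lower() in {".tsv", ".txt"} else "adjacency-csv"


def read_web(path: str | Path, format: str | None = None) -> FoodWeb:
    """Read a food web from an adjacency CSV or edge-list TSV.

    Adjacency dialect: first row and first column hold species names and
    cells are 0/1.  Edge-list dialect: one ``consumer<TAB>resource`` pair
    per line; a line with a single name declares a species with no edges
    (so isolated species survive the round trip).  The species universe of
    an edge list is the union of all names, in order of first appearance.
    """
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "adjacency-csv":
        df = pd.read_csv(path, index_col=0)
        if df.shape[0] != df.shape[1]:
            raise ValueError(
                f"adjacency matrix in {path} is not square: {df.shape}"
            )
        rows = [str(r) for r in df.index]
        cols = [str(c) for c in df.columns]
        if rows != cols:
            raise ValueError("row and column species names differ")
        return FoodWeb(species=rows, A=df.to_numpy())
    if fmt == "edgelist-tsv":
        species: list[str] = []
        seen: set[str] = set()
        edges: list[tuple[str, str]] = []

        def add(name: str) -> None:
            if name not in seen:
                seen.add(name)
                species.append(name)

        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                row = [c.strip() for c in row if c.strip()]
                if not row:
                    continue
                if len(row) == 1:
                    add(row[0])
                elif len(row) == 2:
                    add(row[0])
                    add(row[1])
                    edges.append((row[0], row[1]))
                else:
                    raise ValueError(f"edge-list row has {len(row)} fields: {row}")
        S = len(species)
        idx = {s: i for i, s in enumerate(species)}
        A = np.zeros((S, S), dtype=np.int8)
        for consumer, resource in edges:
            A[idx[consumer], idx[resource]] = 1
        return FoodWeb(species=species, A=A)
    raise ValueError(f"unknown web format {fmt!r}")


def write_web(web: FoodWeb, path: str | Path, format: str | None = None) -> None:
    """Write a web in the adjacency-csv or edgelist-tsv dialect."""
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "adjacency-csv":
        pd.DataFrame(web.A, index=web.species, columns=web.species).to_csv(path)
    elif fmt == "edgelist-tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            # declare every species up front so the ordering (and any
            # isolated species) survives the round trip
            for s in web.species:
                w.writerow([s])
            for i, consumer in enumerate(web.species):
                for j, resource in enumerate(web.species):
                    if web.A[i, j]:
                        w.writerow([consumer, resource])
    else:
        raise ValueError(f"unknown web format {fmt!r}")


def read_body_masses(path: str | Path, web: FoodWeb) -> np.ndarray:
    """Read a species-attribute CSV (columns name, body_mass_g) aligned to a web."""
    df = pd.read_csv(path)
    name_col, mass_col = df.columns[0], df.columns[1]
    table = dict(zip(df[name_col].astype(str), df[mass_col].astype(float)))
    missing = [s for s in web.species if s not in table]
    if missing:
        raise ValueError(f"body mass missing for species: {missing}")
    return np.array([table[s] for s in web.species])
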