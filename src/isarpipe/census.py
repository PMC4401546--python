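"""Census table ingest, validation, size stratification, and target selection.

A plot census is one row per stem: a stable identifier, a species code,
planar coordinates in meters, and diameter at breast height (DBH) in cm.
The mapped window is supplied by configuration, never inferred from the
data, so that an empty corner of the plot is not silently cropped away.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Window",
    "MarkedPointSet",
    "TargetSet",
    "SchemaError",
    "CensusValidationError",
    "read_census",
    "write_census",
    "stratify_by_size",
    "select_targets",
]

#: Census threshold: stems below 1 cm DBH are not mapped.
MIN_DBH_CM = 1.0

REQUIRED_COLUMNS = ("stem_id", "species", "x", "y", "dbh")

ADULT = "adult"
SAPLING = "sapling"


class SchemaError(ValueError):
    """The census table is missing required columns."""


class CensusValidationError(ValueError):
    """A census row violates a structural invariant (window, DBH, codes)."""


@dataclass(frozen=True)
class Window:
    """Closed rectangular observation window, coordinates in meters."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate window: [{self.x_min}, {self.x_max}] x "
                f"[{self.y_min}, {self.y_max}]"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized closed-window membership (border stems are inside)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min)
            & (x <= self.x_max)
            & (y >= self.y_min)
            & (y <= self.y_max)
        )


@dataclass
class MarkedPointSet:
    """Stems of a mapped community: coordinates, species codes, DBH marks.

    ``data`` holds the columns ``stem_id, species, x, y, dbh`` and, after
    :func:`stratify_by_size`, a ``size_class`` column.  Row order carries no
    meaning; every downstream statistic is invariant under permutation.
    """

    data: pd.DataFrame
    window: Window

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"census table missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)
        _validate_rows(self.data, self.window)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def species(self) -> np.ndarray:
        """Sorted unique species codes present."""
        return np.sort(self.data["species"].unique())

    @property
    def n_species(self) -> int:
        return self.data["species"].nunique()

    @property
    def has_size_class(self) -> bool:
        return "size_class" in self.data.columns

    def coords(self) -> np.ndarray:
        """(n, 2) coordinate array in row order."""
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "MarkedPointSet":
        return MarkedPointSet(self.data.loc[np.asarray(mask)].copy(), self.window)

    def of_species(self, species: str) -> pd.DataFrame:
        return self.data[self.data["species"] == species]

    def species_coords(self, species: str, size_class: str | None = None) -> np.ndarray:
        """(n_t, 2) coordinates of one species, optionally one size class."""
        rows = self.of_species(species)
        if size_class is not None:
            if not self.has_size_class:
                raise CensusValidationError(
                    "size_class requested but stems are not stratified; "
                    "call stratify_by_size first"
                )
            rows = rows[rows["size_class"] == size_class]
        return rows[["x", "y"]].to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame) -> "MarkedPointSet":
        return MarkedPointSet(data, self.window)

    def copy(self) -> "MarkedPointSet":
        return MarkedPointSet(self.data.copy(), self.window)


@dataclass(frozen=True)
class TargetSet:
    """Species retained as analysis targets, ranked by adult abundance.

    ``table`` has columns ``species, abundance, rank`` with rank 1 the most
    abundant; ties are broken by lexicographic species code so reports are
    deterministic.
    """

    table: pd.DataFrame = field(repr=False)
    min_abundance: int = 50
    basis: str = ADULT

    @property
    def species(self) -> list[str]:
        return list(self.table["species"])

    def rank_of(self, species: str) -> int:
        row = self.table[self.table["species"] == species]
        if row.empty:
            raise KeyError(f"{species!r} is not a target species")
        return int(row["rank"].iloc[0])

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self):
        return iter(self.species)


def _validate_rows(df: pd.DataFrame, window: Window) -> None:
    for col in ("x", "y", "dbh"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.loc[vals.isna(), "stem_id"]
        if len(bad):
            raise CensusValidationError(
                f"non-numeric {col} for stem_id(s): {list(bad[:5])}"
            )
        df[col] = vals.astype(float)
    empty = df["species"].astype(str).str.len() == 0
    if empty.any():
        raise CensusValidationError(
            f"empty species code for stem_id(s): {list(df.loc[empty, 'stem_id'][:5])}"
        )
    outside = ~window.contains(df["x"].to_numpy(), df["y"].to_numpy())
    if outside.any():
        raise CensusValidationError(
            "coordinates outside window for stem_id(s): "
            f"{list(df.loc[outside, 'stem_id'][:5])}"
        )
    small = df["dbh"].to_numpy() < MIN_DBH_CM
    if small.any():
        raise CensusValidationError(
            f"dbh below census threshold ({MIN_DBH_CM} cm) for stem_id(s): "
            f"{list(df.loc[small, 'stem_id'][:5])}"
        )


def read_census(path: str | Path, window: Window) -> MarkedPointSet:
    """Read and validate a census CSV (columns ``stem_id,species,x,y,dbh``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"stem_id": str, "species": str})
    return MarkedPointSet(df, window)


def write_census(points: MarkedPointSet, path: str | Path) -> None:
    """Write the census back to CSV in the canonical column order."""
    cols = list(REQUIRED_COLUMNS)
    if points.has_size_class:
        cols.append("size_class")
    points.data[cols].to_csv(path, index=False)


def stratify_by_size(
    points: MarkedPointSet, adult_threshold_cm: float = 10.0
) -> MarkedPointSet:
    """Assign ``size_class``: adult iff dbh > threshold, else sapling.

    A stem at exactly the threshold is a sapling: the sapling class is the
    closed interval [1, threshold] cm, adults are strictly above it.  The
    partition is exhaustive and exclusive for any threshold > 1.
    """
    if adult_threshold_cm <= MIN_DBH_CM:
        raise ValueError("adult threshold must exceed the 1 cm census threshold")
    df = points.data.copy()
    df["size_class"] = np.where(df["dbh"] > adult_threshold_cm, ADULT, SAPLING)
    return points.with_data(df)


def select_targets(
    points: MarkedPointSet,
    min_abundance: int = 50,
    basis: str = ADULT,
) -> TargetSet:
    """Select target species whose abundance is strictly above ``min_abundance``.

    Abundance is counted on adults by default (``basis="adult"``) because the
    targets of the main analysis are adult individuals of major species; pass
    ``basis="all"`` to count every stem.  Species are ranked by descending
    abundance, ties broken by species code (rank 1 = most abundant).
    """
    if basis == ADULT:
        if not points.has_size_class:
            raise CensusValidationError(
                "adult-basis target selection requires size_class; "
                "call stratify_by_size first"
            )
        pool = points.data[points.data["size_class"] == ADULT]
    elif basis == "all":
        pool = points.data
    else:
        raise ValueError(f"unknown abundance basis {basis!r}")
    counts = pool.groupby("species").size()
    counts = counts[counts > min_abundance]
    table = (
        counts.rename("abundance")
        .reset_index()
        .sort_values(["abundance", "species"], ascending=[False, True])
        .reset_index(drop=True)
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return TargetSet(table=table, min_abundance=min_abundance, basis=basis)
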