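"""Nearest-neighbor distribution functions and ISAR curves.

The individual species-area relationship of a target species t,

    ISAR_t(r) = sum_{j != t} D_tj(r),

is the mean number of other species found within distance r of the
individuals of t.  D_tj(r) is the cumulative nearest-neighbor distribution:
the proportion of target individuals whose nearest individual of species j
lies within Euclidean distance r (closed disc, "within" = <= r).

No edge correction is applied.  Bivariate patterns of two species need not
be homogeneous, which breaks the assumptions of the standard corrections,
and the small bias from focal individuals near the border cancels in the
comparison because observed and null-model curves share it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .census import ADULT, SAPLING, MarkedPointSet

__all__ = [
    "RadiusGrid",
    "NNDistribution",
    "ISARCurve",
    "ISAREvaluator",
    "nn_distribution",
    "isar_curve",
    "neighbor_pool",
]

# above this many target x neighbor pairs, switch from one dense distance
# matrix to per-species k-d tree queries to bound memory
_DENSE_PAIR_LIMIT = 20_000_000


@dataclass(frozen=True)
class RadiusGrid:
    """Strictly increasing neighborhood radii in meters (default 1..50 m)."""

    radii: np.ndarray = field(default_factory=lambda: np.arange(1.0, 51.0))

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        if r.ndim != 1 or len(r) == 0:
            raise ValueError("radius grid must be a non-empty 1-d sequence")
        if not (np.all(np.diff(r) > 0) and r[0] > 0):
            raise ValueError("radii must be strictly increasing and positive")
        object.__setattr__(self, "radii", r)

    @classmethod
    def regular(cls, r_max: float = 50.0, step: float = 1.0) -> "RadiusGrid":
        return cls(np.arange(step, r_max + step / 2, step))

    def __len__(self) -> int:
        return len(self.radii)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RadiusGrid) and np.array_equal(
            self.radii, other.radii
        )

    def index_of(self, r: float) -> int:
        idx = np.nonzero(np.isclose(self.radii, r))[0]
        if len(idx) == 0:
            raise ValueError(f"radius {r} is not on the grid")
        return int(idx[0])


@dataclass(frozen=True)
class NNDistribution:
    """D_tj(r): proportion of t-individuals with nearest j-neighbor within r."""

    target: str
    neighbor: str
    grid: RadiusGrid
    values: np.ndarray


@dataclass(frozen=True)
class ISARCurve:
    """ISAR_t(r) on a radius grid, with the sizes that bound it."""

    target: str
    grid: RadiusGrid
    values: np.ndarray
    n_targets: int
    n_species: int  # total species in the community, S

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if len(v) != len(self.grid):
            raise ValueError("curve length does not match the radius grid")
        object.__setattr__(self, "values", v)


class ISAREvaluator:
    """Reusable ISAR engine for one fixed heterospecific neighbor pool.

    Null-model ensembles relocate only the target individuals, so the
    neighbor pool — and any spatial index built on it — can be shared by
    the observed curve and all Monte Carlo replicates.  ``curve(xy)``
    returns ISAR values for an arbitrary set of target coordinates.

    The defining computation is exhaustive: for each target individual and
    each neighbor species, the nearest-neighbor distance; the curve is the
    mean per-radius count of species within the closed disc.  Dense distance
    matrices (grouped by species with a segmented minimum) are used when
    they fit comfortably in memory, per-species k-d trees otherwise; both
    produce identical integer counts.
    """

    def __init__(self, neighbor_xy: np.ndarray, neighbor_species: np.ndarray):
        neighbor_xy = np.asarray(neighbor_xy, dtype=float).reshape(-1, 2)
        neighbor_species = np.asarray(neighbor_species)
        if len(neighbor_xy) != len(neighbor_species):
            raise ValueError("coordinate and species arrays differ in length")
        order = np.argsort(neighbor_species, kind="stable")
        self._xy = neighbor_xy[order]
        sp = neighbor_species[order]
        self.species, self._starts = np.unique(sp, return_index=True)
        self._trees: list[cKDTree] | None = None

    @property
    def n_neighbor_species(self) -> int:
        return len(self.species)

    @property
    def n_neighbors(self) -> int:
        return len(self._xy)

    def nn_distances(self, target_xy: np.ndarray) -> np.ndarray:
        """(n_t, K) matrix of nearest-neighbor distances per neighbor species."""
        target_xy = np.asarray(target_xy, dtype=float).reshape(-1, 2)
        if len(target_xy) == 0:
            raise ValueError("target point set is empty")
        if self.n_neighbors == 0:
            return np.empty((len(target_xy), 0))
        if len(target_xy) * self.n_neighbors <= _DENSE_PAIR_LIMIT:
            d = cdist(target_xy, self._xy)
            return np.minimum.reduceat(d, self._starts, axis=1)
        if self._trees is None:
            ends = np.append(self._starts[1:], len(self._xy))
            self._trees = [
                cKDTree(self._xy[s:e]) for s, e in zip(self._starts, ends)
            ]
        out = np.empty((len(target_xy), len(self._trees)))
        for k, tree in enumerate(self._trees):
            out[:, k] = tree.query(target_xy, k=1)[0]
        return out

    def curve(self, target_xy: np.ndarray, grid: RadiusGrid) -> np.ndarray:
        """ISAR values: mean count of neighbor species within each radius."""
        nnd = self.nn_distances(target_xy)
        n_t = nnd.shape[0]
        if nnd.shape[1] == 0:
            return np.zeros(len(grid))
        # counts are integers, so the summation order cannot change the result
        counts = (nnd[:, :, None] <= grid.radii).sum(axis=(0, 1))
        return counts / n_t


def nn_distribution(
    target_xy: np.ndarray,
    neighbor_xy: np.ndarray,
    grid: RadiusGrid,
    target: str = "t",
    neighbor: str = "j",
) -> NNDistribution:
    """Cumulative nearest-neighbor distribution D_tj(r), no edge correction.

    An empty neighbor set gives the identically-zero distribution (the
    species is never found within any radius); an empty target set is an
    error because the proportion is undefined.
    """
    target_xy = np.asarray(target_xy, dtype=float).reshape(-1, 2)
    neighbor_xy = np.asarray(neighbor_xy, dtype=float).reshape(-1, 2)
    if len(target_xy) == 0:
        raise ValueError("target point set is empty; D_tj is undefined")
    if len(neighbor_xy) == 0:
        values = np.zeros(len(grid))
    else:
        d = cKDTree(neighbor_xy).query(target_xy, k=1)[0]
        values = (d[:, None] <= grid.radii).mean(axis=0)
    return NNDistribution(target=target, neighbor=neighbor, grid=grid, values=values)


def neighbor_pool(
    community: MarkedPointSet, target: str, mode: str = "all"
) -> tuple[np.ndarray, np.ndarray]:
    """Heterospecific neighbor coordinates and species codes for one analysis.

    mode "all": every heterospecific stem.
    mode "large_large": heterospecific adults (adult-adult analysis).
    mode "large_small": heterospecific saplings (adults as targets, saplings
    as neighborhood species).
    """
    df = community.data
    mask = df["species"].to_numpy() != target
    if mode == "all":
        pass
    elif mode in ("large_large", "large_small"):
        if not community.has_size_class:
            raise ValueError(f"mode {mode!r} requires size-stratified stems")
        wanted = ADULT if mode == "large_large" else SAPLING
        mask &= df["size_class"].to_numpy() == wanted
    else:
        raise ValueError(f"unknown analysis mode {mode!r}")
    sub = df.loc[mask]
    return sub[["x", "y"]].to_numpy(dtype=float), sub["species"].to_numpy()


def isar_curve(
    community: MarkedPointSet,
    target: str,
    grid: RadiusGrid,
    mode: str = "all",
    target_size: str | None = None,
) -> ISARCurve:
    """Observed ISAR_t(r) of ``target`` within ``community``.

    Conspecifics never contribute to the curve.  ``target_size`` restricts
    the focal individuals to one size class (``"adult"`` for the large-large
    and large-small analyses); the large-* modes default to adult targets.
    """
    if target not in community.data["species"].values:
        raise KeyError(f"target species {target!r} absent from the community")
    if target_size is None and mode in ("large_large", "large_small"):
        target_size = ADULT
    txy = community.species_coords(target, size_class=target_size)
    if len(txy) == 0:
        raise ValueError(
            f"no focal individuals of {target!r} (size class {target_size!r})"
        )
    nxy, nsp = neighbor_pool(community, target, mode)
    evaluator = ISAREvaluator(nxy, nsp)
    values = evaluator.curve(txy, grid)
    return ISARCurve(
        target=target,
        grid=grid,
        values=values,
        n_targets=len(txy),
        n_species=community.n_species,
    )
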