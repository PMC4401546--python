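"""Poisson null models and Monte Carlo ISAR ensembles.

Two null models relocate the individuals of one target species while every
other stem stays exactly where the census mapped it:

* homogeneous Poisson — targets are redistributed uniformly over the whole
  window (complete spatial randomness).  Deviations measure whether the
  target sits in locally richer or poorer neighborhoods than the plot-wide
  species-area relationship predicts, whatever the cause.
* heterogeneous Poisson — targets are redistributed according to a kernel
  estimate of their own spatially varying intensity, so large-scale habitat
  association is preserved and only structure below the kernel radius is
  randomized away.  Deviations then isolate the signal of individual
  interactions, under the separation-of-scales assumption that habitat acts
  above the kernel radius (50 m by default) and interactions below it.

The intensity estimate is a distance-weighted moving window: an
Epanechnikov kernel k_R(d) = max(0, 1 - (d/R)^2) summed over target
locations on a regular cell grid and renormalized so that no kernel mass is
lost over the window border.  Replicates draw each point independently from
the normalized surface (an inhomogeneous Poisson process conditioned on the
observed abundance), uniformly within the chosen cell.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .census import ADULT, MarkedPointSet, Window
from .core import ISAREvaluator, RadiusGrid, neighbor_pool

__all__ = [
    "IntensitySurface",
    "NullEnsemble",
    "estimate_intensity",
    "simulate_homogeneous",
    "simulate_heterogeneous",
    "run_null_ensemble",
    "HOMOGENEOUS",
    "HETEROGENEOUS",
]

HOMOGENEOUS = "homogeneous"
HETEROGENEOUS = "heterogeneous"

DEFAULT_BANDWIDTH_M = 50.0
DEFAULT_CELL_M = 5.0
DEFAULT_N_SIM = 199


@dataclass(frozen=True)
class IntensitySurface:
    """Gridded kernel estimate of a species' intensity lambda_t(x).

    ``lam`` is indexed [iy, ix]; cell (ix, iy) covers
    [x_edges[ix], x_edges[ix+1]) x [y_edges[iy], y_edges[iy+1]).
    Total mass (sum of lam times cell area) equals the number of points the
    surface was estimated from.
    """

    window: Window
    x_edges: np.ndarray
    y_edges: np.ndarray
    lam: np.ndarray
    bandwidth: float
    kernel: str = "epanechnikov"

    @property
    def cell_area(self) -> np.ndarray:
        dx = np.diff(self.x_edges)
        dy = np.diff(self.y_edges)
        return np.outer(dy, dx)

    @property
    def mass(self) -> float:
        return float(np.sum(self.lam * self.cell_area))

    def to_frame(self):
        """Long-format export: one row per cell (x_cell, y_cell, lambda)."""
        import pandas as pd

        xc = (self.x_edges[:-1] + self.x_edges[1:]) / 2
        yc = (self.y_edges[:-1] + self.y_edges[1:]) / 2
        gx, gy = np.meshgrid(xc, yc)
        return pd.DataFrame(
            {"x_cell": gx.ravel(), "y_cell": gy.ravel(), "lambda": self.lam.ravel()}
        )


def _epanechnikov(d: np.ndarray, bandwidth: float) -> np.ndarray:
    u = d / bandwidth
    return np.maximum(0.0, 1.0 - u * u)


_KERNELS = {
    "epanechnikov": _epanechnikov,
    "uniform": lambda d, bw: (d <= bw).astype(float),
    "gaussian": lambda d, bw: np.exp(-0.5 * (d / (bw / 2)) ** 2),
}


def estimate_intensity(
    target_xy: np.ndarray,
    window: Window,
    bandwidth: float = DEFAULT_BANDWIDTH_M,
    cell: float = DEFAULT_CELL_M,
    kernel: str = "epanechnikov",
) -> IntensitySurface:
    """Kernel intensity surface of one species on a regular cell grid.

    lambda(cell) = sum_i k_R(||x_cell - x_i||) evaluated at cell centers,
    renormalized so the surface mass equals the number of points: border
    cells lose no mass, which keeps the conditional simulation exact.
    """
    if bandwidth <= 0:
        raise ValueError("kernel bandwidth must be positive")
    if cell <= 0:
        raise ValueError("cell size must be positive")
    try:
        kfun = _KERNELS[kernel]
    except KeyError:
        raise ValueError(f"unknown kernel {kernel!r}") from None
    target_xy = np.asarray(target_xy, dtype=float).reshape(-1, 2)
    n = len(target_xy)
    if n == 0:
        raise ValueError("cannot estimate an intensity from zero points")
    x_edges = _edges(window.x_min, window.x_max, cell)
    y_edges = _edges(window.y_min, window.y_max, cell)
    xc = (x_edges[:-1] + x_edges[1:]) / 2
    yc = (y_edges[:-1] + y_edges[1:]) / 2
    gx, gy = np.meshgrid(xc, yc)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    # kernel sum over points; chunk the points to bound the distance block
    lam = np.zeros(len(centers))
    step = max(1, int(5_000_000 / max(len(centers), 1)))
    for s in range(0, n, step):
        block = target_xy[s : s + step]
        d = np.sqrt(
            (centers[:, 0:1] - block[:, 0]) ** 2
            + (centers[:, 1:2] - block[:, 1]) ** 2
        )
        lam += kfun(d, bandwidth).sum(axis=1)
    lam = lam.reshape(len(yc), len(xc))
    area = np.outer(np.diff(y_edges), np.diff(x_edges))
    total = float(np.sum(lam * area))
    if total <= 0:
        raise ValueError(
            "kernel surface is identically zero; bandwidth too small for the grid"
        )
    lam = lam * (n / total)
    return IntensitySurface(
        window=window,
        x_edges=x_edges,
        y_edges=y_edges,
        lam=lam,
        bandwidth=float(bandwidth),
        kernel=kernel,
    )


def _edges(lo: float, hi: float, cell: float) -> np.ndarray:
    n = max(1, int(np.ceil((hi - lo) / cell - 1e-9)))
    return np.linspace(lo, hi, n + 1)


def uniform_coords(n: int, window: Window, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. uniform locations in the window."""
    x = rng.uniform(window.x_min, window.x_max, n)
    y = rng.uniform(window.y_min, window.y_max, n)
    return np.column_stack([x, y])


def sample_from_surface(
    surface: IntensitySurface, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n independent draws from the normalized surface, uniform within cells."""
    w = (surface.lam * surface.cell_area).ravel()
    total = w.sum()
    if total <= 0:
        raise ValueError("intensity surface has zero total mass")
    idx = rng.choice(len(w), size=n, p=w / total)
    iy, ix = np.unravel_index(idx, surface.lam.shape)
    x = rng.uniform(surface.x_edges[ix], surface.x_edges[ix + 1])
    y = rng.uniform(surface.y_edges[iy], surface.y_edges[iy + 1])
    return np.column_stack([x, y])


def _relocate(
    community: MarkedPointSet, target: str, new_xy: np.ndarray, target_size: str | None
) -> MarkedPointSet:
    df = community.data.copy()
    mask = (df["species"] == target).to_numpy()
    if target_size is not None:
        mask &= (df["size_class"] == target_size).to_numpy()
    if mask.sum() != len(new_xy):
        raise ValueError("replacement coordinates do not match the target count")
    df.loc[mask, "x"] = new_xy[:, 0]
    df.loc[mask, "y"] = new_xy[:, 1]
    return community.with_data(df)


def simulate_homogeneous(
    community: MarkedPointSet,
    target: str,
    rng: np.random.Generator,
    target_size: str | None = None,
) -> MarkedPointSet:
    """Relocate the target's individuals uniformly; all other stems fixed."""
    n = len(community.species_coords(target, size_class=target_size))
    if n == 0:
        raise KeyError(f"target species {target!r} absent from the community")
    return _relocate(
        community, target, uniform_coords(n, community.window, rng), target_size
    )


def simulate_heterogeneous(
    community: MarkedPointSet,
    target: str,
    surface: IntensitySurface,
    rng: np.random.Generator,
    target_size: str | None = None,
) -> MarkedPointSet:
    """Relocate the target's individuals by its intensity surface; others fixed."""
    n = len(community.species_coords(target, size_class=target_size))
    if n == 0:
        raise KeyError(f"target species {target!r} absent from the community")
    return _relocate(
        community, target, sample_from_surface(surface, n, rng), target_size
    )


@dataclass(frozen=True)
class NullEnsemble:
    """Observed ISAR curve plus its Monte Carlo replicates under one null.

    ``curves`` has shape (n_sim + 1, n_radii); row 0 is the observed curve,
    rows 1..n_sim the simulations.
    """

    target: str
    model: str
    grid: RadiusGrid
    curves: np.ndarray
    n_targets: int
    seed: int
    n_species: int = 0

    @property
    def n_sim(self) -> int:
        return self.curves.shape[0] - 1

    @property
    def observed(self) -> np.ndarray:
        return self.curves[0]

    @property
    def simulated(self) -> np.ndarray:
        return self.curves[1:]

    def to_frame(self):
        import pandas as pd

        n, m = self.curves.shape
        return pd.DataFrame(
            {
                "sim_index": np.repeat(np.arange(n), m),
                "r": np.tile(self.grid.radii, n),
                "isar": self.curves.ravel(),
            }
        )


def substream(seed: int, target: str, sim_index: int) -> np.random.Generator:
    """Independent RNG stream for one (target species, simulation index).

    Streams are keyed, not sequential, so evaluating species or replicates
    in any order — or in parallel — cannot change a single coordinate.
    """
    key = zlib.crc32(str(target).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, key, sim_index]))


def run_null_ensemble(
    community: MarkedPointSet,
    target: str,
    model: str = HOMOGENEOUS,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
    grid: RadiusGrid | None = None,
    mode: str = "all",
    bandwidth: float = DEFAULT_BANDWIDTH_M,
    cell: float = DEFAULT_CELL_M,
    kernel: str = "epanechnikov",
    surface: IntensitySurface | None = None,
) -> NullEnsemble:
    """Observed curve plus ``n_sim`` null-model ISAR curves for one species.

    Only the target individuals move between replicates, so the
    heterospecific neighbor pool and its spatial index are computed once.
    For the heterogeneous model the intensity surface is estimated from the
    observed focal coordinates unless one is supplied.  Deterministic given
    (seed, inputs); see :func:`substream`.
    """
    if model not in (HOMOGENEOUS, HETEROGENEOUS):
        raise ValueError(f"unknown null model {model!r}")
    if n_sim < 1:
        raise ValueError("n_sim must be at least 1")
    grid = grid or RadiusGrid()
    target_size = ADULT if mode in ("large_large", "large_small") else None
    txy = _focal_coords(community, target, target_size)
    nxy, nsp = neighbor_pool(community, target, mode)
    evaluator = ISAREvaluator(nxy, nsp)

    if model == HETEROGENEOUS and surface is None:
        surface = estimate_intensity(
            txy, community.window, bandwidth=bandwidth, cell=cell, kernel=kernel
        )

    n_t = len(txy)
    curves = np.empty((n_sim + 1, len(grid)))
    curves[0] = evaluator.curve(txy, grid)
    for i in range(1, n_sim + 1):
        rng = substream(seed, target, i)
        if model == HOMOGENEOUS:
            xy = uniform_coords(n_t, community.window, rng)
        else:
            xy = sample_from_surface(surface, n_t, rng)
        curves[i] = evaluator.curve(xy, grid)
    return NullEnsemble(
        target=target,
        model=model,
        grid=grid,
        curves=curves,
        n_targets=n_t,
        seed=seed,
        n_species=community.n_species,
    )


def _focal_coords(
    community: MarkedPointSet, target: str, target_size: str | None
) -> np.ndarray:
    if target not in community.data["species"].values:
        raise KeyError(f"target species {target!r} absent from the community")
    txy = community.species_coords(target, size_class=target_size)
    if len(txy) == 0:
        raise ValueError(
            f"no focal individuals of {target!r} in size class {target_size!r}"
        )
    return txy
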