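"""Synthetic multispecies stem maps with known ground truth.

Real forest-dynamics-plot censuses are access-restricted, and — more
importantly for testing — their true generating process is unknown.  This
module builds marked point patterns whose structure is known exactly, so
every stage of the ISAR pipeline can be checked against ground truth:

* CSR communities — each species an independent uniform pattern; nothing
  should be detected.
* Habitat communities — species intensities proportional to
  exp(beta_s * z(x)) for a covariate z smooth at scales of ~100 m; the
  homogeneous null should flag positive deviations, the heterogeneous null
  (which preserves habitat association) mostly should not.
* Thomas-cluster communities — within-species clustering (parent points
  with Gaussian offspring), the typical aggregation of real stem maps.
* Interaction overlays — constructed accumulators (heterospecific recruits
  seeded around targets within an interaction distance, the
  Janzen-Connell-flavored mechanism) and repellers (heterospecific stems
  near targets thinned), creating a signal at a known distance.

DBH marks are drawn as 1 cm plus a lognormal, with the location parameter
solved so that the expected adult share (dbh > 10 cm) matches
``adult_fraction`` exactly; the default 0.16 mirrors the roughly one-adult-
in-six stem structure of mapped subtropical forest censuses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import norm

from .census import MarkedPointSet, Window, stratify_by_size

__all__ = [
    "ScenarioConfig",
    "gen_csr_community",
    "gen_habitat_community",
    "gen_thomas_community",
    "gen_interaction_overlay",
    "assign_dbh",
    "gaussian_bump_covariate",
    "generate_community",
]

DEFAULT_WINDOW = Window(0.0, 500.0, 0.0, 500.0)
DEFAULT_ADULT_FRACTION = 0.16
DEFAULT_DBH_SIGMA = 1.0
ADULT_DBH_CM = 10.0


@dataclass
class ScenarioConfig:
    """Recipe for one synthetic community.

    ``abundance`` is either one count shared by all species or a sequence of
    per-species counts.  ``structure`` chooses the spatial law (csr, thomas,
    habitat); ``interaction`` optionally overlays an accumulator or repeller
    around ``interaction_target`` at distance ``d_int`` with the given
    strength.  All randomness flows from ``seed``.
    """

    window: Window = field(default_factory=lambda: DEFAULT_WINDOW)
    n_species: int = 100
    abundance: int | list[int] = 300
    structure: str = "csr"
    interaction: str = "none"
    interaction_target: str | None = None
    d_int: float = 10.0
    strength: float = 0.0
    recruits_per_target: float = 5.0
    adult_fraction: float = DEFAULT_ADULT_FRACTION
    dbh_sigma: float = DEFAULT_DBH_SIGMA
    habitat_beta: float | list[float] = 0.0
    habitat_length_scale: float = 100.0
    habitat_n_bumps: int = 3
    thomas_parent_count: int = 10
    thomas_sigma: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("need at least one species")
        if np.any(np.asarray(self.abundance) < 1):
            raise ValueError("abundances must be >= 1")
        if self.interaction not in ("none", "accumulator", "repeller"):
            raise ValueError(f"unknown interaction {self.interaction!r}")
        if self.interaction != "none" and self.d_int <= 0:
            raise ValueError("interaction distance d_int must be positive")
        if self.interaction == "repeller" and not 0 <= self.strength <= 1:
            raise ValueError("repeller thinning strength must lie in [0, 1]")

    def abundances(self) -> np.ndarray:
        a = np.asarray(self.abundance)
        if a.ndim == 0:
            return np.full(self.n_species, int(a))
        if len(a) != self.n_species:
            raise ValueError("per-species abundance list has the wrong length")
        return a.astype(int)

    def species_codes(self) -> list[str]:
        return [f"sp{i + 1:03d}" for i in range(self.n_species)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window"] = asdict(self.window)
        return d


def _assemble(
    config: ScenarioConfig,
    coords: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> MarkedPointSet:
    frames = []
    offset = 0
    for sp in config.species_codes():
        xy = coords[sp]
        frames.append(
            pd.DataFrame(
                {
                    "stem_id": [f"s{offset + k:06d}" for k in range(len(xy))],
                    "species": sp,
                    "x": xy[:, 0],
                    "y": xy[:, 1],
                }
            )
        )
        offset += len(xy)
    df = pd.concat(frames, ignore_index=True)
    df["dbh"] = _draw_dbh(
        len(df), config.adult_fraction, config.dbh_sigma, rng
    )
    return stratify_by_size(MarkedPointSet(df, config.window))


def gen_csr_community(config: ScenarioConfig) -> MarkedPointSet:
    """Every species an independent uniform (CSR) pattern; exact counts."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    w = config.window
    coords = {}
    for sp, n in zip(config.species_codes(), config.abundances()):
        coords[sp] = np.column_stack(
            [rng.uniform(w.x_min, w.x_max, n), rng.uniform(w.y_min, w.y_max, n)]
        )
    return _assemble(config, coords, rng)


def gaussian_bump_covariate(
    window: Window,
    n_bumps: int = 3,
    length_scale: float = 100.0,
    seed: int = 0,
):
    """Smooth habitat covariate: a sum of Gaussian bumps, scaled to [0, 1].

    The 100 m default length scale keeps all covariate structure comfortably
    above a 50 m separation scale, so the heterogeneous null's assumption
    holds by construction in habitat scenarios.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    cx = rng.uniform(window.x_min, window.x_max, n_bumps)
    cy = rng.uniform(window.y_min, window.y_max, n_bumps)
    amp = rng.uniform(0.5, 1.0, n_bumps)

    def z(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(np.broadcast(x, y).shape)
        for k in range(n_bumps):
            d2 = (x - cx[k]) ** 2 + (y - cy[k]) ** 2
            out += amp[k] * np.exp(-0.5 * d2 / length_scale**2)
        return out / amp.sum()

    return z


def _linear_gradient(window: Window):
    """One-sided covariate: 0 at x_min rising linearly to 1 at x_max."""

    def z(x, y):
        x = np.asarray(x, dtype=float)
        return np.broadcast_to(
            (x - window.x_min) / window.width, np.broadcast(x, y).shape
        ).copy()

    return z


def gen_habitat_community(
    config: ScenarioConfig, covariate=None
) -> MarkedPointSet:
    """Species placed with intensity proportional to exp(beta_s * z(x)).

    beta_s = 0 reduces exactly to CSR.  Sampling is by rejection against the
    covariate maximum, so the target abundance is met exactly.
    """
    if covariate is None:
        covariate = gaussian_bump_covariate(
            config.window,
            n_bumps=config.habitat_n_bumps,
            length_scale=config.habitat_length_scale,
            seed=config.seed,
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    betas = np.asarray(config.habitat_beta, dtype=float)
    if betas.ndim == 0:
        betas = np.full(config.n_species, float(betas))
    if len(betas) != config.n_species:
        raise ValueError("per-species beta list has the wrong length")
    w = config.window
    # covariate maximum on a fine probe grid bounds the rejection envelope
    px, py = np.meshgrid(
        np.linspace(w.x_min, w.x_max, 101), np.linspace(w.y_min, w.y_max, 101)
    )
    z_max = float(covariate(px, py).max())
    coords = {}
    for sp, n, beta in zip(config.species_codes(), config.abundances(), betas):
        if beta == 0:
            coords[sp] = np.column_stack(
                [rng.uniform(w.x_min, w.x_max, n), rng.uniform(w.y_min, w.y_max, n)]
            )
            continue
        pts = np.empty((0, 2))
        while len(pts) < n:
            m = max(4 * n, 64)
            x = rng.uniform(w.x_min, w.x_max, m)
            y = rng.uniform(w.y_min, w.y_max, m)
            # acceptance ratio relative to the intensity maximum; beta < 0
            # inverts the preference, so the envelope sits at z = 0 there
            expo = beta * (covariate(x, y) - (z_max if beta > 0 else 0.0))
            keep = rng.uniform(size=m) < np.exp(expo)
            pts = np.vstack([pts, np.column_stack([x, y])[keep]])
        coords[sp] = pts[:n]
    return _assemble(config, coords, rng)


def gen_thomas_community(config: ScenarioConfig) -> MarkedPointSet:
    """Within-species clustering: a Thomas process conditioned on abundance.

    Each species gets ``thomas_parent_count`` uniform parents; every stem is
    a Gaussian displacement (sd ``thomas_sigma``) from a uniformly chosen
    parent, resampled until it falls inside the window.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    w = config.window
    coords = {}
    for sp, n in zip(config.species_codes(), config.abundances()):
        parents = np.column_stack(
            [
                rng.uniform(w.x_min, w.x_max, config.thomas_parent_count),
                rng.uniform(w.y_min, w.y_max, config.thomas_parent_count),
            ]
        )
        pts = np.empty((0, 2))
        while len(pts) < n:
            m = max(2 * n, 64)
            pick = parents[rng.integers(0, len(parents), m)]
            xy = pick + rng.normal(0.0, config.thomas_sigma, (m, 2))
            inside = w.contains(xy[:, 0], xy[:, 1])
            pts = np.vstack([pts, xy[inside]])
        coords[sp] = pts[:n]
    return _assemble(config, coords, rng)


def generate_community(config: ScenarioConfig) -> MarkedPointSet:
    """Dispatch on structure and apply any configured interaction overlay."""
    builders = {
        "csr": gen_csr_community,
        "habitat": gen_habitat_community,
        "thomas": gen_thomas_community,
    }
    try:
        community = builders[config.structure](config)
    except KeyError:
        raise ValueError(f"unknown structure {config.structure!r}") from None
    if config.interaction != "none":
        target = config.interaction_target or config.species_codes()[0]
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
        community = gen_interaction_overlay(
            community,
            target,
            config.interaction,
            d_int=config.d_int,
            strength=config.strength,
            rng=rng,
            recruits_per_target=config.recruits_per_target,
        )
    return community


def gen_interaction_overlay(
    community: MarkedPointSet,
    target: str,
    interaction: str,
    d_int: float,
    strength: float,
    rng: np.random.Generator,
    recruits_per_target: float = 5.0,
    target_size: str | None = "adult",
    recruit_dbh_range: tuple[float, float] = (1.0, 10.0),
) -> MarkedPointSet:
    """Plant an accumulator or repeller signal at a known distance.

    accumulator: ``round(strength * recruits_per_target * n_targets)``
    heterospecific recruits are added, each uniform in the d_int-disc around
    a randomly chosen target individual (clipped to the window by
    resampling), with species drawn uniformly from the non-target codes so
    no single species' abundance rank is confounded.  Recruits get sapling
    DBH by default (the Janzen-Connell reading: adults accumulate
    heterospecific juveniles).

    repeller: every heterospecific stem within d_int of any target
    individual is deleted independently with probability ``strength``;
    strength 1 empties the d_int-neighborhoods completely.

    Stems farther than d_int from every target are never touched.
    """
    if interaction not in ("accumulator", "repeller"):
        raise ValueError(f"unknown interaction {interaction!r}")
    if d_int <= 0:
        raise ValueError("d_int must be positive")
    if target not in community.data["species"].values:
        raise KeyError(f"target species {target!r} absent from the community")
    if target_size is not None and not community.has_size_class:
        target_size = None
    txy = community.species_coords(target, size_class=target_size)
    if len(txy) == 0:
        txy = community.species_coords(target)
    df = community.data

    if interaction == "repeller":
        if not 0 <= strength <= 1:
            raise ValueError("repeller thinning strength must lie in [0, 1]")
        if strength == 0 or len(df) == 0:
            return community.copy()
        d_near, _ = cKDTree(txy).query(df[["x", "y"]].to_numpy(), k=1)
        hetero = (df["species"] != target).to_numpy()
        at_risk = hetero & (d_near <= d_int)
        doomed = at_risk & (rng.uniform(size=len(df)) < strength)
        return community.with_data(df.loc[~doomed].copy())

    n_recruits = int(round(strength * recruits_per_target * len(txy)))
    if n_recruits == 0:
        return community.copy()
    centers = txy[rng.integers(0, len(txy), n_recruits)]
    xy = _uniform_in_discs(centers, d_int, community.window, rng)
    others = [s for s in community.species if s != target]
    if not others:
        raise ValueError("accumulator overlay needs at least one other species")
    recruits = pd.DataFrame(
        {
            "stem_id": [f"r{k:06d}" for k in range(n_recruits)],
            "species": rng.choice(others, n_recruits),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "dbh": rng.uniform(*recruit_dbh_range, n_recruits),
        }
    )
    if community.has_size_class:
        recruits["size_class"] = np.where(
            recruits["dbh"] > ADULT_DBH_CM, "adult", "sapling"
        )
    return community.with_data(pd.concat([df, recruits], ignore_index=True))


def _uniform_in_discs(
    centers: np.ndarray, radius: float, window: Window, rng: np.random.Generator
) -> np.ndarray:
    """One uniform draw in the disc around each center, resampled into the window."""
    out = np.empty_like(centers)
    todo = np.arange(len(centers))
    while len(todo):
        u = rng.uniform(size=len(todo))
        theta = rng.uniform(0, 2 * np.pi, len(todo))
        rr = radius * np.sqrt(u)
        xy = centers[todo] + np.column_stack([rr * np.cos(theta), rr * np.sin(theta)])
        ok = window.contains(xy[:, 0], xy[:, 1])
        out[todo[ok]] = xy[ok]
        todo = todo[~ok]
    return out


def _draw_dbh(
    n: int, adult_fraction: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """dbh = 1 + lognormal(mu, sigma) with P(dbh > 10) = adult_fraction exactly."""
    if not 0 < adult_fraction < 1:
        raise ValueError("adult_fraction must lie in (0, 1)")
    # solve P(exp(mu + sigma Z) > 9) = f  =>  mu = ln 9 - sigma * z_{1-f}
    mu = np.log(ADULT_DBH_CM - 1.0) - sigma * norm.ppf(1.0 - adult_fraction)
    return 1.0 + rng.lognormal(mean=mu, sigma=sigma, size=n)


def assign_dbh(
    points: MarkedPointSet,
    adult_fraction: float = DEFAULT_ADULT_FRACTION,
    dbh_sigma: float = DEFAULT_DBH_SIGMA,
    rng: np.random.Generator | None = None,
) -> MarkedPointSet:
    """Redraw DBH marks with the stated expected adult share; restratifies."""
    rng = rng or np.random.default_rng(0)
    df = points.data.copy()
    df["dbh"] = _draw_dbh(len(df), adult_fraction, dbh_sigma, rng)
    return stratify_by_size(points.with_data(df))
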