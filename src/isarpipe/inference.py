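"""Envelopes, goodness-of-fit rank tests, and species classification.

Significance is Monte Carlo throughout.  Two complementary devices:

* pointwise envelopes — at each radius, the band between the k-th smallest
  and k-th largest of the simulated ISAR values (k = 5 of 199 gives a
  two-sided 95% band); used for per-radius diagnostics and curve plots.
* interval goodness-of-fit (GoF) test — the accumulated squared deviation

      u_i = sum_{r in interval} (H_i(r) - Hbar_i(r))^2,

  where H_i is the i-th curve (i = 0 observed) and Hbar_i the mean of all
  *other* curves (leave-one-out, so every u_i is exchangeable under the
  null).  The observed statistic's ascending rank among all n_sim + 1
  values is the test: reject at level alpha when rank > (1-alpha)(n_sim+1)
  — rank > 190 for alpha = 0.05 with 199 simulations.  Pooling radii into
  intervals is the anti-inflation device: one test per interval instead of
  fifty per radius; no further multiple-testing correction is applied
  across species or intervals.

Classification: a species significant with positive summed deviation is an
accumulator (heterogeneous null) or a positive deviation from the SAR
(homogeneous null); negative gives repeller / negative; otherwise
no-effect / none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import RadiusGrid
from .nulls import HETEROGENEOUS, HOMOGENEOUS, NullEnsemble

__all__ = [
    "EnvelopeSet",
    "DistanceInterval",
    "GoFResult",
    "SpeciesClassification",
    "default_intervals",
    "pointwise_envelope",
    "gof_statistic",
    "gof_statistics",
    "gof_rank_test",
    "critical_rank",
    "classify_species",
    "summarize",
    "LABELS",
]

POSITIVE = "positive"
NEGATIVE = "negative"
NONE = "none"
ACCUMULATOR = "accumulator"
REPELLER = "repeller"
NO_EFFECT = "no_effect"

#: label vocabulary per null model, ordered (significant-positive,
#: significant-negative, not-significant)
LABELS = {
    HOMOGENEOUS: (POSITIVE, NEGATIVE, NONE),
    HETEROGENEOUS: (ACCUMULATOR, REPELLER, NO_EFFECT),
}


class DegenerateDeviationError(ValueError):
    """Significant GoF result with exactly zero summed deviation."""


@dataclass(frozen=True)
class DistanceInterval:
    """Inclusive radius interval [r_min, r_max]; both ends on the grid."""

    r_min: float
    r_max: float

    def __post_init__(self) -> None:
        if self.r_min > self.r_max:
            raise ValueError("r_min must not exceed r_max")

    def mask(self, grid: RadiusGrid) -> np.ndarray:
        r = grid.radii
        m = (r >= self.r_min - 1e-9) & (r <= self.r_max + 1e-9)
        if not m.any():
            raise ValueError(f"interval {self} contains no grid radius")
        on_grid = np.isclose(r, self.r_min).any() and np.isclose(r, self.r_max).any()
        if not on_grid:
            raise ValueError(f"interval {self} endpoints are not on the radius grid")
        return m

    @property
    def label(self) -> str:
        return f"{self.r_min:g}-{self.r_max:g}m"


def default_intervals() -> list[DistanceInterval]:
    """The five 10 m distance classes: 1-10, 11-20, 21-30, 31-40, 41-50 m."""
    return [
        DistanceInterval(1.0, 10.0),
        DistanceInterval(11.0, 20.0),
        DistanceInterval(21.0, 30.0),
        DistanceInterval(31.0, 40.0),
        DistanceInterval(41.0, 50.0),
    ]


@dataclass(frozen=True)
class EnvelopeSet:
    """Two-sided pointwise envelope from order statistics of the simulations."""

    grid: RadiusGrid
    lower: np.ndarray
    upper: np.ndarray
    observed: np.ndarray
    k: int

    @property
    def outside(self) -> np.ndarray:
        """Boolean flags where the observed curve exits the band."""
        return (self.observed < self.lower) | (self.observed > self.upper)

    @property
    def exit_radii(self) -> np.ndarray:
        return self.grid.radii[self.outside]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r": self.grid.radii,
                "observed": self.observed,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def pointwise_envelope(ensemble: NullEnsemble, k: int = 5) -> EnvelopeSet:
    """k-th smallest / k-th largest simulated ISAR at every radius.

    With 199 simulations and k = 5 the observed curve falls outside the band
    at a fixed radius with probability 2k/(n_sim+1) = 0.05 under the null.
    """
    n_sim = ensemble.n_sim
    if n_sim < 20:
        raise ValueError("envelopes need at least 20 simulations")
    if not (1 <= k <= n_sim // 2):
        raise ValueError(f"envelope rank k={k} out of range for {n_sim} simulations")
    sims = np.sort(ensemble.simulated, axis=0)
    return EnvelopeSet(
        grid=ensemble.grid,
        lower=sims[k - 1],
        upper=sims[n_sim - k],
        observed=ensemble.observed.copy(),
        k=k,
    )


def gof_statistics(ensemble: NullEnsemble, interval: DistanceInterval) -> np.ndarray:
    """u_i for every curve i = 0..n_sim, with leave-one-out ensemble means."""
    m = interval.mask(ensemble.grid)
    h = ensemble.curves[:, m]
    n = h.shape[0]
    if n < 2:
        raise ValueError("need at least one simulated curve")
    loo_mean = (h.sum(axis=0) - h) / (n - 1)
    return ((h - loo_mean) ** 2).sum(axis=1)


def gof_statistic(i: int, ensemble: NullEnsemble, interval: DistanceInterval) -> float:
    """Accumulated squared deviation of curve i from the mean of the others."""
    if not 0 <= i <= ensemble.n_sim:
        raise IndexError(f"curve index {i} out of range")
    return float(gof_statistics(ensemble, interval)[i])


def critical_rank(alpha: float, n_sim: int) -> float:
    """Rejection threshold: reject when rank(u_0) exceeds (1-alpha)(n_sim+1)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return (1.0 - alpha) * (n_sim + 1)


@dataclass(frozen=True)
class GoFResult:
    """Outcome of the interval GoF rank test for one ensemble."""

    interval: DistanceInterval
    u: np.ndarray = field(repr=False)  # u_0 .. u_n_sim
    rank: int
    alpha: float
    significant: bool
    direction: str  # positive | negative
    deviation_sum: float
    model: str

    @property
    def u0(self) -> float:
        return float(self.u[0])

    @property
    def critical_rank(self) -> float:
        return critical_rank(self.alpha, len(self.u) - 1)


def gof_rank_test(
    ensemble: NullEnsemble,
    interval: DistanceInterval,
    alpha: float = 0.05,
) -> GoFResult:
    """Rank of u_0 among all u_i; significant iff rank > (1-alpha)(n_sim+1).

    Ties give the observed statistic the smallest rank in its tie group, the
    conservative choice (fewer rejections).  The direction of a departure is
    the sign of the summed raw deviation of the observed curve from the
    simulation mean over the interval; u itself is sign-blind.
    """
    u = gof_statistics(ensemble, interval)
    rank = 1 + int(np.sum(u[1:] < u[0]))
    significant = rank > critical_rank(alpha, ensemble.n_sim)
    m = interval.mask(ensemble.grid)
    h = ensemble.curves[:, m]
    dev = float((h[0] - h[1:].mean(axis=0)).sum())
    direction = POSITIVE if dev >= 0 else NEGATIVE
    return GoFResult(
        interval=interval,
        u=u,
        rank=rank,
        alpha=alpha,
        significant=significant,
        direction=direction,
        deviation_sum=dev,
        model=ensemble.model,
    )


@dataclass(frozen=True)
class SpeciesClassification:
    """Per-interval labels of one target species under one null model."""

    species: str
    model: str
    labels: dict[DistanceInterval, str]
    results: dict[DistanceInterval, GoFResult] = field(repr=False)
    abundance_rank: int | None = None

    def label(self, interval: DistanceInterval) -> str:
        return self.labels[interval]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for interval, lab in self.labels.items():
            res = self.results[interval]
            rows.append(
                {
                    "species": self.species,
                    "abundance_rank": self.abundance_rank,
                    "model": self.model,
                    "interval": interval.label,
                    "label": lab,
                    "u0": res.u0,
                    "rank": res.rank,
                }
            )
        return pd.DataFrame(rows)


def classify_species(
    species: str,
    gof_results: list[GoFResult],
    model: str,
    abundance_rank: int | None = None,
) -> SpeciesClassification:
    """Map per-interval GoF results to accumulator/repeller/no-effect labels.

    Exactly one label per interval.  A significant result whose summed
    deviation is exactly zero has no defensible direction and is reported as
    an error rather than silently assigned.
    """
    pos, neg, none = LABELS[model]
    labels: dict[DistanceInterval, str] = {}
    results: dict[DistanceInterval, GoFResult] = {}
    for res in gof_results:
        if res.interval in labels:
            raise ValueError(f"duplicate GoF result for interval {res.interval}")
        if not res.significant:
            lab = none
        elif res.deviation_sum > 0:
            lab = pos
        elif res.deviation_sum < 0:
            lab = neg
        else:
            raise DegenerateDeviationError(
                f"{species}: significant departure on {res.interval.label} with "
                "exactly zero summed deviation"
            )
        labels[res.interval] = lab
        results[res.interval] = res
    return SpeciesClassification(
        species=species,
        model=model,
        labels=labels,
        results=results,
        abundance_rank=abundance_rank,
    )


def summarize(
    classifications: list[SpeciesClassification],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts/proportions per (model, interval, label), plus a species table.

    The first frame is the headline summary (every label reported, zeros
    included, proportions summing to 1 within each model x interval); the
    second lists every species with its abundance rank and per-interval
    label, for abundance-rank diagrams.
    """
    if not classifications:
        raise ValueError("nothing to summarize")
    species_df = pd.concat(
        [c.to_frame() for c in classifications], ignore_index=True
    ).sort_values(
        ["model", "abundance_rank", "species", "interval"], na_position="last"
    ).reset_index(drop=True)

    rows = []
    for (model, interval), grp in species_df.groupby(["model", "interval"]):
        n = len(grp)
        for lab in LABELS[model]:
            count = int((grp["label"] == lab).sum())
            rows.append(
                {
                    "model": model,
                    "interval": interval,
                    "label": lab,
                    "count": count,
                    "proportion": count / n,
                }
            )
    return pd.DataFrame(rows), species_df
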