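import numpy as np
import pandas as pd
import pytest

from isarpipe.census import MarkedPointSet, Window, stratify_by_size


def make_community(
    rng: np.random.Generator,
    n_species: int = 5,
    n_per: int = 20,
    window: Window = Window(0.0, 100.0, 0.0, 100.0),
    stratified: bool = True,
) -> MarkedPointSet:
    """Small uniform multispecies community for unit tests."""
    n = n_species * n_per
    df = pd.DataFrame(
        {
            "stem_id": [f"s{i:05d}" for i in range(n)],
            "species": np.repeat([f"sp{k + 1:03d}" for k in range(n_species)], n_per),
            "x": rng.uniform(window.x_min, window.x_max, n),
            "y": rng.uniform(window.y_min, window.y_max, n),
            "dbh": rng.uniform(1.0, 30.0, n),
        }
    )
    points = MarkedPointSet(df, window)
    return stratify_by_size(points) if stratified else points


def disc_count_oracle(community, target, radii, target_size=None):
    """Exhaustive ISAR oracle: per-target census of distinct heterospecific
    species within each closed disc, averaged over target individuals.

    Pure loops over all pairs; no spatial index, no shared code path with
    the implementation under test.
    """
    df = community.data
    rows = df[df["species"] == target]
    if target_size is not None:
        rows = rows[rows["size_class"] == target_size]
    txy = rows[["x", "y"]].to_numpy(dtype=float)
    others = df[df["species"] != target]
    oxy = others[["x", "y"]].to_numpy(dtype=float)
    osp = others["species"].to_numpy()
    values = []
    for r in radii:
        total = 0
        for tx, ty in txy:
            d = np.sqrt((oxy[:, 0] - tx) ** 2 + (oxy[:, 1] - ty) ** 2)
            total += len(set(osp[d <= r]))
        values.append(total / len(txy))
    return np.array(values)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def square_window():
    return Window(0.0, 100.0, 0.0, 100.0)
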