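"""Shared fixtures and data-construction helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stemtaper import synthetic_data, taper_models
from stemtaper.stem_geometry import StemMeasurement, StemProfile, Tree

#: Generating parameters used by the noise-free recovery tests; heights are
#: randomised around the allometry so log-scale predictors are not collinear.
RECOVERY_BETAS = {
    "demaerschalk": (0.05, 0.95, 0.85, 0.8),
    "biging": (1.08, 0.35),
    "bi": (0.9, 0.1, 0.05, 0.05, 0.001, 0.01, -0.02),
    "lee": (1.05, 0.98, 0.8, -1.2, 0.7),
    "kozak": (1.0, 0.98, 0.02, 0.4, -0.3, 0.5, 2.0, 0.04, -0.4),
    "metcalf": (0.05,),
}


def model_rows(model_name: str, beta, n_trees: int = 30, per_tree: int = 12,
               noise_sd: float = 0.0, seed: int = 42) -> pd.DataFrame:
    """Observations generated exactly from one taper law (plus optional
    additive Gaussian noise in cm)."""
    spec = taper_models.get_model(model_name)
    rng = np.random.default_rng(seed)
    records = []
    dbhs = rng.uniform(8, 60, n_trees) if noise_sd > 0 else np.linspace(8, 60, n_trees)
    for dbh in dbhs:
        ht = min(2.2 * dbh**0.55 * np.exp(rng.uniform(-0.25, 0.25)), 30.0)
        for h in np.linspace(0.1, 0.95 * ht, per_tree):
            records.append((dbh, ht, h))
    rows = pd.DataFrame(records, columns=["dbh", "ht", "h"])
    d = taper_models._raw_predict(
        spec, np.asarray(beta, float), rows["dbh"].to_numpy(),
        rows["ht"].to_numpy(), rows["h"].to_numpy())
    assert np.all(np.isfinite(d)) and np.all(d > 0)
    if noise_sd > 0:
        d = d + rng.normal(0.0, noise_sd, len(d))
    rows["d"] = d
    return rows


def pure_scenarios(**overrides) -> dict[str, synthetic_data.ForestScenario]:
    """Default scenarios stripped of every noise source (exact taper truth)."""
    from dataclasses import replace

    out = {}
    for forest, sc in synthetic_data.default_scenarios().items():
        out[forest] = replace(
            sc, noise_sd=0.0, tree_scale_sd=0.0, tree_taper_sd=0.0,
            butt_swell_prob=0.0, multi_stem_prob=0.0, census_n=5, **overrides)
    return out


def small_scenarios(n_trees: int = 10) -> dict[str, synthetic_data.ForestScenario]:
    from dataclasses import replace

    return {
        forest: replace(sc, n_trees=n_trees, census_n=10)
        for forest, sc in synthetic_data.default_scenarios().items()
    }


def cylinder_tree(d: float = 20.0, top: float = 5.1, ht: float = 6.0,
                  tree_id: str = "cyl") -> Tree:
    """A constant-diameter test tree with measurements every metre."""
    hs = [0.1 + i for i in range(int(top))] + [top]
    stems = (StemProfile("s1", tuple(StemMeasurement(h, d) for h in sorted(set(hs)))),)
    return Tree(tree_id, "cerrado", "sp", dbh=d, ht=ht, stems=stems)


@pytest.fixture(scope="session")
def inventory_small():
    """30-tree three-site inventory with all noise sources active."""
    trees, _ = synthetic_data.generate_inventory(small_scenarios(), seed=11)
    return trees


@pytest.fixture(scope="session")
def inventory_default():
    """The full default 160-tree inventory (used by acceptance tests)."""
    trees, census = synthetic_data.generate_inventory(seed=202)
    return trees, census
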