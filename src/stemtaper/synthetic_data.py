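"""Synthetic three-site forest inventories with known taper ground truth.

Emulates the field protocol the pipeline expects: three forest types with
realistic tree counts and dbh/ht ranges, stem diameters measured at 0.1, 0.3,
0.7 and 1.3 m and then at 1-m steps until the true diameter falls below 5 cm,
a conic tip above the last measurement, multi-stemmed trees in the savanna
site and optional basal flare (butt swell) in the rainforest site.  True
profiles are drawn from a configurable taper law with multiplicative Gaussian
measurement noise, so the generating parameters are recoverable and every
downstream stage can be tested against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import taper_models
from .stem_geometry import (FOREST_TYPES, StemMeasurement, StemProfile, Tree,
                            equivalent_diameter)

__all__ = [
    "ForestScenario",
    "default_scenarios",
    "generate_tree",
    "generate_inventory",
    "measurement_heights",
]

#: Measurement protocol: fixed lower heights, then 1-m steps from 1.3 m.
_BASE_HEIGHTS = (0.1, 0.3, 0.7, 1.3)
_TOP_DIAMETER = 5.0  # cm; stems are measured up to this minimum diameter


@dataclass(frozen=True)
class ForestScenario:
    """Generating configuration for one forest type."""

    forest_type: str
    n_trees: int
    dbh_range: tuple[float, float]
    ht_range: tuple[float, float]
    height_a: float  # ht = height_a * dbh**height_b * lognormal noise
    height_b: float
    height_sd: float  # sd of the log-scale height noise
    taper_model: str = "lee"
    taper_beta: tuple[float, ...] = (1.05, 0.98, 0.8, -1.2, 0.7)
    noise_sd: float = 0.02  # multiplicative diameter noise, relative
    tree_scale_sd: float = 0.05  # per-tree lognormal form-factor variation
    tree_taper_sd: float = 0.05  # per-tree jitter of the last taper exponent
    multi_stem_prob: float = 0.0
    butt_swell_prob: float = 0.0
    butt_swell_max: float = 0.25  # max relative flare at the stump
    dbh_meanlog: float | None = None
    dbh_sdlog: float = 0.7
    census_n: int = 500

    def __post_init__(self):
        if self.forest_type not in FOREST_TYPES:
            raise ValueError(f"unknown forest_type {self.forest_type!r}")
        lo, hi = self.dbh_range
        if not (0 < lo < hi):
            raise ValueError("dbh_range must be positive and ordered")
        lo, hi = self.ht_range
        if not (0 < lo < hi):
            raise ValueError("ht_range must be positive and ordered")
        if hi <= 1.4:
            raise ValueError("ht_range upper bound must exceed 1.4 m")
        if not (0 <= self.multi_stem_prob <= 1):
            raise ValueError("multi_stem_prob must be in [0, 1]")
        if not (0 <= self.butt_swell_prob <= 1):
            raise ValueError("butt_swell_prob must be in [0, 1]")


def default_scenarios() -> dict[str, ForestScenario]:
    """Three-site defaults: tree counts and size ranges of the study design.

    The savanna site is short, small-diameter and frequently multi-stemmed;
    the rainforest site is tall with occasional buttressed bases.
    """
    return {
        "cerrado": ForestScenario(
            forest_type="cerrado", n_trees=52,
            dbh_range=(5.0, 52.0), ht_range=(1.7, 17.0),
            height_a=1.8, height_b=0.5, height_sd=0.15,
            taper_beta=(1.1, 0.97, 0.9, -1.4, 0.8),
            multi_stem_prob=0.25, dbh_meanlog=np.log(12.0), census_n=531,
        ),
        "semideciduous": ForestScenario(
            forest_type="semideciduous", n_trees=53,
            dbh_range=(5.0, 135.0), ht_range=(2.0, 24.0),
            height_a=3.0, height_b=0.45, height_sd=0.15,
            taper_beta=(1.05, 0.98, 0.8, -1.2, 0.7),
            dbh_meanlog=np.log(14.0), census_n=446,
        ),
        "rainforest": ForestScenario(
            forest_type="rainforest", n_trees=55,
            dbh_range=(5.1, 157.0), ht_range=(1.4, 26.0),
            height_a=3.2, height_b=0.45, height_sd=0.18,
            taper_beta=(1.15, 0.96, 1.0, -1.5, 0.9),
            butt_swell_prob=0.3, dbh_meanlog=np.log(14.0), census_n=540,
        ),
    }


def _truncated_lognormal(rng, meanlog, sdlog, lo, hi):
    for _ in range(10_000):
        x = rng.lognormal(meanlog, sdlog)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated lognormal rejection sampling failed")


def _draw_height(rng, scenario: ForestScenario, dbh: float) -> float:
    ht = scenario.height_a * dbh**scenario.height_b * np.exp(
        rng.normal(0.0, scenario.height_sd))
    lo, hi = scenario.ht_range
    ht = float(np.clip(ht, max(lo, 1.5), hi))
    return ht


def measurement_heights(true_d, ht: float) -> list[float]:
    """Protocol heights: 0.1, 0.3, 0.7, 1.3 m, then 1-m steps while the true
    diameter stays at or above 5 cm; all heights strictly below ``ht``.

    ``true_d`` maps a height to the noise-free diameter.
    """
    heights = [h for h in _BASE_HEIGHTS if h < ht]
    h = 1.3 + 1.0
    while h < ht and true_d(h) >= _TOP_DIAMETER:
        heights.append(h)
        h += 1.0
    return heights


def _stem_profile(rng, scenario: ForestScenario, stem_id: str, stem_dbh: float,
                  ht: float, swell: float, beta: np.ndarray,
                  tree_scale: float) -> StemProfile:
    spec = taper_models.get_model(scenario.taper_model)

    def true_d(h):
        d = tree_scale * float(
            taper_models.predict_diameter(spec, beta, stem_dbh, ht, h))
        if swell > 0 and h < 1.3:
            d *= 1.0 + swell * (1.3 - h) / 1.2
        return d

    heights = measurement_heights(true_d, ht)
    measurements = []
    for h in heights:
        d = true_d(h)
        if scenario.noise_sd > 0:
            d *= 1.0 + rng.normal(0.0, scenario.noise_sd)
        measurements.append(StemMeasurement(h, max(d, 0.0)))
    return StemProfile(stem_id, tuple(measurements), nominal_dbh=stem_dbh)


def generate_tree(scenario: ForestScenario, rng: np.random.Generator,
                  tree_id: str = "t1", species: str = "sp") -> Tree:
    """Draw one tree: size from the scenario's allometry, profile from its
    taper law, measurement heights from the field protocol.

    Multi-stem trees (probability ``multi_stem_prob``) split the tree's basal
    area over 2-3 stems so the equivalent diameter of the stem breast-height
    diameters reproduces the drawn tree dbh exactly.

    Per-tree form variability — a lognormal whole-profile scale factor
    (``tree_scale_sd``) and a jitter on the taper law's constant exponent
    term (``tree_taper_sd``) — makes held-out trees genuinely harder than
    training trees, giving every method a positive generalization gap under
    tree-level splitting.  Set both to zero for exact-recovery scenarios.
    """
    meanlog = (scenario.dbh_meanlog if scenario.dbh_meanlog is not None
               else float(np.log(np.sqrt(np.prod(scenario.dbh_range)))))
    dbh = _truncated_lognormal(rng, meanlog, scenario.dbh_sdlog,
                               *scenario.dbh_range)
    ht = _draw_height(rng, scenario, dbh)

    swell = 0.0
    if scenario.butt_swell_prob > 0 and rng.random() < scenario.butt_swell_prob:
        swell = float(rng.uniform(0.05, scenario.butt_swell_max))

    tree_scale = 1.0
    if scenario.tree_scale_sd > 0:
        tree_scale = float(np.exp(rng.normal(0.0, scenario.tree_scale_sd)))
    beta = np.asarray(scenario.taper_beta, dtype=float).copy()
    if scenario.tree_taper_sd > 0:
        beta[-1] += rng.normal(0.0, scenario.tree_taper_sd)

    n_stems = 1
    if scenario.multi_stem_prob > 0 and rng.random() < scenario.multi_stem_prob:
        n_stems = int(rng.integers(2, 4))

    if n_stems == 1:
        stem_dbhs = [dbh]
    else:
        # split basal area: dbh_i = dbh * sqrt(w_i), sum w_i = 1
        w = rng.dirichlet(np.full(n_stems, 3.0))
        stem_dbhs = list(dbh * np.sqrt(w))

    stems = tuple(
        _stem_profile(rng, scenario, f"{tree_id}-s{i + 1}", sd, ht, swell,
                      beta, tree_scale)
        for i, sd in enumerate(stem_dbhs)
    )
    return Tree(tree_id=tree_id, forest_type=scenario.forest_type,
                species=species, dbh=dbh, ht=ht, stems=stems)


def generate_inventory(
    scenarios: dict[str, ForestScenario] | None = None,
    seed: int = 0,
) -> tuple[list[Tree], pd.DataFrame]:
    """Deterministic multi-site inventory plus a census table.

    Returns the taper-measured tree set (one entry per scenario tree) and a
    larger census DataFrame (forest_type, dbh_cm, ht_m) for summary-table
    analogues.  Identical seeds give identical output.
    """
    scenarios = scenarios or default_scenarios()
    rng = np.random.default_rng(seed)
    trees: list[Tree] = []
    census_records = []
    for forest in sorted(scenarios):
        scenario = scenarios[forest]
        for i in range(scenario.n_trees):
            tree_id = f"{forest[:3]}-{i + 1:03d}"
            species = f"sp{int(rng.integers(1, 73)):02d}"
            trees.append(generate_tree(scenario, rng, tree_id, species))
        meanlog = (scenario.dbh_meanlog if scenario.dbh_meanlog is not None
                   else float(np.log(np.sqrt(np.prod(scenario.dbh_range)))))
        for _ in range(scenario.census_n):
            dbh = _truncated_lognormal(rng, meanlog, scenario.dbh_sdlog,
                                       *scenario.dbh_range)
            ht = _draw_height(rng, scenario, dbh)
            census_records.append((forest, dbh, ht))
    census = pd.DataFrame(census_records,
                          columns=["forest_type", "dbh_cm", "ht_m"])
    return trees, census
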