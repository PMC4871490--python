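"""Cross-validated comparison of taper equations against ML regressors.

The protocol: trees (not rows) are split 75/25 into training and validation,
stratified by forest type; the site-specific taper equation — the AICc winner
per forest, selected once on the full data — is refitted per iteration on the
training trees of its forest, while the neural network and random forest are
trained on the pooled training rows of all forests.  Diameter and accumulated
volume are evaluated on both partitions with RMSE, mean bias
(predicted - observed, positive = over-prediction) and model efficiency
(1 - SSE/SST); the split is repeated ``n_iter`` times and the per-iteration
metric stream is retained so distributional claims stay inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import ml_models, taper_models
from .stem_geometry import STUMP_HEIGHT, Tree, accumulated_volume_profile

__all__ = [
    "MetricSet",
    "CVRun",
    "CVResult",
    "rmse",
    "bias",
    "efficiency",
    "metric_set",
    "build_observation_rows",
    "split_trees",
    "select_site_models",
    "cross_validate",
    "summarize",
    "runs_to_frame",
    "residual_table",
    "profile_prediction",
]


def _check_lengths(observed, predicted):
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise ValueError("empty metric input")
    return obs, pred


def rmse(observed, predicted) -> float:
    """Root mean squared error, in the units of the target."""
    obs, pred = _check_lengths(observed, predicted)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def bias(observed, predicted) -> float:
    """Mean of (predicted - observed); positive means over-prediction."""
    obs, pred = _check_lengths(observed, predicted)
    return float(np.mean(pred - obs))


def efficiency(observed, predicted) -> float:
    """Model efficiency 1 - SSE/SST, with SST about the observed mean."""
    obs, pred = _check_lengths(observed, predicted)
    if obs.size < 2:
        raise ValueError("efficiency needs at least 2 points")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ValueError("efficiency undefined: observed values are all equal")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


@dataclass(frozen=True)
class MetricSet:
    rmse: float
    bias: float
    ef: float


def metric_set(observed, predicted) -> MetricSet:
    return MetricSet(rmse(observed, predicted), bias(observed, predicted),
                     efficiency(observed, predicted))


@dataclass
class CVRun:
    """Metrics of one method on one target in one CV iteration."""

    iteration: int
    method: str
    target: str
    train: MetricSet
    val: MetricSet
    flagged: bool = False
    note: str = ""


@dataclass
class CVResult:
    runs: list[CVRun]
    site_model_names: dict[str, str]
    n_tm_excluded: int
    splits: list[tuple[frozenset, frozenset]] = field(default_factory=list)
    predictions: list[dict] = field(default_factory=list)


def build_observation_rows(trees: Iterable[Tree]) -> pd.DataFrame:
    """One modelling record per stem measurement.

    Columns: tree_id, forest_type, dbh, ht, h, d, vac.  The predictor ``dbh``
    and ``ht`` are tree-level (equivalent diameter for multi-stem trees);
    ``vac`` is the per-stem Smalian ground truth, zero at the stump.
    Only heights in ``[0.1, ht)`` are kept.
    """
    records = []
    for tree in trees:
        for stem in tree.stems:
            profile = accumulated_volume_profile(stem, tree.ht)
            for meas, point in zip(stem.measurements, profile):
                if not (STUMP_HEIGHT <= meas.h < tree.ht):
                    continue
                records.append(
                    (tree.tree_id, tree.forest_type, tree.dbh, tree.ht,
                     meas.h, meas.d, point.vac)
                )
    return pd.DataFrame(
        records, columns=["tree_id", "forest_type", "dbh", "ht", "h", "d", "vac"]
    )


def split_trees(
    trees: Sequence[Tree], val_frac: float, rng: np.random.Generator,
    stratify: bool = True,
) -> tuple[frozenset, frozenset]:
    """Random tree-level train/validation split, stratified by forest type."""
    if not (0 < val_frac < 1):
        raise ValueError("val_frac must be in (0, 1)")
    val_ids: set[str] = set()
    groups: dict[str, list[str]]
    if stratify:
        groups = {}
        for t in trees:
            groups.setdefault(t.forest_type, []).append(t.tree_id)
    else:
        groups = {"all": [t.tree_id for t in trees]}
    for ids in groups.values():
        n_val = max(1, round(val_frac * len(ids)))
        if n_val >= len(ids):
            raise ValueError("group too small to split")
        chosen = rng.choice(len(ids), size=n_val, replace=False)
        val_ids.update(ids[i] for i in chosen)
    train_ids = frozenset(t.tree_id for t in trees) - val_ids
    return frozenset(train_ids), frozenset(val_ids)


def select_site_models(
    rows: pd.DataFrame, inits: Mapping[str, Sequence[float]] | None = None
) -> tuple[dict[str, str], dict[str, dict[str, taper_models.TaperFit]],
           taper_models.ModelSelectionTally]:
    """Fit all taper equations per forest on the full data; pick AICc winners.

    Returns (winner name per forest, all fits per forest, the win tally).
    """
    fits: dict[str, dict[str, taper_models.TaperFit]] = {}
    for forest, sub in rows.groupby("forest_type"):
        fits[forest] = taper_models.fit_all_models(sub, forest_type=forest,
                                                   inits=inits)
    tally = taper_models.select_best_model(
        f for by_model in fits.values() for f in by_model.values()
    )
    site_best = {forest: names[0] for forest, names in tally.winners.items()}
    return site_best, fits, tally


def _tm_predict(rows: pd.DataFrame, fits: Mapping[str, taper_models.TaperFit],
                target: str) -> np.ndarray:
    out = np.full(len(rows), np.nan)
    pos = {forest: np.flatnonzero(rows["forest_type"].to_numpy() == forest)
           for forest in fits}
    for forest, fit in fits.items():
        idx = pos[forest]
        if idx.size == 0:
            continue
        sub = rows.iloc[idx]
        if target == "d":
            out[idx] = taper_models.predict_diameter(
                fit.spec, fit.beta, sub["dbh"].to_numpy(), sub["ht"].to_numpy(),
                sub["h"].to_numpy())
        else:
            out[idx] = taper_models.taper_volume_batch(
                fit.spec, fit.beta, sub["dbh"].to_numpy(), sub["ht"].to_numpy(),
                sub["h"].to_numpy())
    return out


def cross_validate(
    trees: Sequence[Tree],
    n_iter: int = 500,
    val_frac: float = 0.25,
    seed: int = 0,
    methods: Sequence[str] = ("nn", "rf", "tm"),
    targets: Sequence[str] = ("d", "vac"),
    nn_config: ml_models.NNConfig | None = None,
    rf_config: ml_models.RFConfig | None = None,
    site_models: Mapping[str, str] | None = None,
    stratify: bool = True,
    record_splits: bool = False,
    store_predictions: bool = False,
) -> CVResult:
    """Repeated 75/25 tree-level cross-validation of TM, NN and RF.

    ``site_models`` (forest -> taper-model name) may be supplied to skip the
    initial full-data AICc selection.  Iterations in which any forest's taper
    refit fails to converge have their TM records flagged; flagged records
    are kept in the stream but excluded by :func:`summarize`.
    """
    trees = list(trees)
    counts: dict[str, int] = {}
    for t in trees:
        counts[t.forest_type] = counts.get(t.forest_type, 0) + 1
    for forest, n in counts.items():
        if n < 8:
            raise ValueError(
                f"forest {forest!r} has only {n} trees; >= 8 required for a "
                f"non-degenerate split"
            )
    rows = build_observation_rows(trees)
    if "tm" in methods and site_models is None:
        site_models, _, _ = select_site_models(rows)
    site_models = dict(site_models or {})

    rng = np.random.default_rng(seed)
    nn_config = nn_config or ml_models.NNConfig()
    rf_config = rf_config or ml_models.RFConfig()

    runs: list[CVRun] = []
    splits: list[tuple[frozenset, frozenset]] = []
    predictions: list[dict] = []
    n_tm_excluded = 0

    tree_ids = rows["tree_id"].to_numpy()
    X_all = ml_models.build_input_matrix(rows)

    for it in range(1, n_iter + 1):
        train_ids, val_ids = split_trees(trees, val_frac, rng, stratify=stratify)
        in_train = np.isin(tree_ids, list(train_ids))
        train_rows = rows[in_train]
        val_rows = rows[~in_train]
        X_train, X_val = X_all[in_train], X_all[~in_train]
        if record_splits:
            splits.append((train_ids, val_ids))
        pred_store: dict = {"iteration": it}

        tm_fits: dict[str, taper_models.TaperFit] = {}
        tm_ok = True
        tm_note = ""
        if "tm" in methods:
            for forest, model_name in site_models.items():
                sub = train_rows[train_rows["forest_type"] == forest]
                fit = taper_models.gauss_newton_fit(
                    taper_models.get_model(model_name), sub, forest_type=forest
                )
                tm_fits[forest] = fit
                if not fit.converged:
                    tm_ok = False
                    tm_note = f"{model_name} did not converge for {forest}"

        for target in targets:
            y_train = train_rows[target].to_numpy(float)
            y_val = val_rows[target].to_numpy(float)
            for method in methods:
                if method == "nn":
                    sub_seed = int(rng.integers(2**31))
                    model = ml_models.train_nn(X_train, y_train, nn_config,
                                               seed=sub_seed)
                    p_train = ml_models.predict(model, X_train, target)
                    p_val = ml_models.predict(model, X_val, target)
                    flagged, note = False, ""
                elif method == "rf":
                    sub_seed = int(rng.integers(2**31))
                    model = ml_models.train_rf(X_train, y_train, rf_config,
                                               seed=sub_seed)
                    p_train = ml_models.predict(model, X_train, target)
                    p_val = ml_models.predict(model, X_val, target)
                    flagged, note = False, ""
                elif method == "tm":
                    if tm_ok:
                        p_train = _tm_predict(train_rows, tm_fits, target)
                        p_val = _tm_predict(val_rows, tm_fits, target)
                        flagged, note = False, ""
                    else:
                        p_train = np.full(len(train_rows), np.nan)
                        p_val = np.full(len(val_rows), np.nan)
                        flagged, note = True, tm_note
                else:
                    raise ValueError(f"unknown method {method!r}")

                if flagged:
                    nan = MetricSet(float("nan"), float("nan"), float("nan"))
                    runs.append(CVRun(it, method, target, nan, nan, True, note))
                else:
                    runs.append(CVRun(
                        it, method, target,
                        metric_set(y_train, p_train),
                        metric_set(y_val, p_val),
                        False, note,
                    ))
                if store_predictions and not flagged:
                    pred_store[(method, target)] = {
                        "y_train": y_train, "p_train": p_train,
                        "y_val": y_val, "p_val": p_val,
                    }
        if any(r.flagged and r.iteration == it for r in runs):
            n_tm_excluded += 1
        if store_predictions:
            predictions.append(pred_store)

    return CVResult(runs, site_models, n_tm_excluded, splits, predictions)


def runs_to_frame(runs: Iterable[CVRun]) -> pd.DataFrame:
    """Tidy per-iteration metric stream (one row per partition)."""
    records = []
    for r in runs:
        for partition, m in (("training", r.train), ("validation", r.val)):
            records.append((r.iteration, r.method, r.target, partition,
                            m.rmse, m.bias, m.ef, r.flagged))
    return pd.DataFrame(records, columns=[
        "iteration", "method", "target", "partition", "rmse", "bias", "ef",
        "flagged",
    ])


def summarize(runs: Iterable[CVRun]) -> pd.DataFrame:
    """Mean RMSE/bias/EF per method, target and partition over iterations.

    Flagged (non-converged TM) iterations are excluded; their count is
    reported in the ``n_excluded`` column.
    """
    frame = runs_to_frame(runs)
    ok = frame[~frame["flagged"]]
    out = (
        ok.groupby(["method", "target", "partition"], sort=True)
        .agg(rmse=("rmse", "mean"), bias=("bias", "mean"), ef=("ef", "mean"),
             n_iterations=("iteration", "count"))
        .reset_index()
    )
    excluded = (
        frame[frame["flagged"]]
        .groupby(["method", "target", "partition"])["iteration"].count()
    )
    out["n_excluded"] = [
        int(excluded.get((m, t, p), 0))
        for m, t, p in zip(out["method"], out["target"], out["partition"])
    ]
    return out


def residual_table(
    rows: pd.DataFrame,
    nn=None,
    rf=None,
    tm_fits: Mapping[str, taper_models.TaperFit] | None = None,
    targets: Sequence[str] = ("d", "vac"),
) -> pd.DataFrame:
    """Residuals (predicted - observed) versus observed diameter.

    One record per observation, method and target; the layout behind
    per-method residual panels.
    """
    X = ml_models.build_input_matrix(rows)
    obs_d = rows["d"].to_numpy(float)
    records = []
    methods = []
    if nn is not None:
        methods.append(("nn", {t: ml_models.predict(nn[t], X, t) for t in targets}
                        if isinstance(nn, Mapping)
                        else {targets[0]: ml_models.predict(nn, X, targets[0])}))
    if rf is not None:
        methods.append(("rf", {t: ml_models.predict(rf[t], X, t) for t in targets}
                        if isinstance(rf, Mapping)
                        else {targets[0]: ml_models.predict(rf, X, targets[0])}))
    if tm_fits is not None:
        methods.append(("tm", {t: _tm_predict(rows, tm_fits, t) for t in targets}))
    for method, preds in methods:
        for target, p in preds.items():
            y = rows[target].to_numpy(float)
            for forest, od, resid in zip(rows["forest_type"], obs_d, p - y):
                records.append((forest, method, target, od, resid))
    return pd.DataFrame(
        records,
        columns=["forest_type", "method", "target", "observed_d", "residual"],
    )


def profile_prediction(
    tree: Tree,
    nn=None,
    rf=None,
    tm_fit: taper_models.TaperFit | None = None,
) -> pd.DataFrame:
    """Measured vs predicted diameters along one tree's stem(s).

    Heights outside ``[0.1, ht)`` are excluded.  Columns present depend on
    the models supplied.
    """
    rows = build_observation_rows([tree])
    out = rows[["h", "d"]].rename(columns={"d": "d_measured"}).copy()
    X = ml_models.build_input_matrix(rows)
    if nn is not None:
        out["d_nn"] = ml_models.predict(nn, X, "d")
    if rf is not None:
        out["d_rf"] = ml_models.predict(rf, X, "d")
    if tm_fit is not None:
        out["d_tm"] = taper_models.predict_diameter(
            tm_fit.spec, tm_fit.beta, rows["dbh"].to_numpy(),
            rows["ht"].to_numpy(), rows["h"].to_numpy())
    return out.reset_index(drop=True)
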