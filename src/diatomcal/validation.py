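"""Cross-validation, performance statistics and spatial diagnostics.

A transfer function's headline skill is its cross-validated RMSEP; here the
jackknife (leave-one-out) scheme refits the whole model — taxon response
estimation included — without each site in turn.  The module also provides
the apparent/LOO performance grid over the standard model family
(WA variants and WAPLS components, with and without Hellinger transform),
residual-based outlier screening, and the random/neighbor/environment (RNE)
deletion analysis that detects inflation of cross-validated skill by
spatial autocorrelation in the training set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationModel, fit_wa, fit_wapls, predict
from .data_model import AbundanceMatrix, DataError, SiteCoords, hellinger

__all__ = [
    "ModelSpec",
    "DEFAULT_GRID",
    "PerformanceStats",
    "RNEResult",
    "loo_predictions",
    "performance_stats",
    "model_selection_table",
    "outlier_screen",
    "rne_analysis",
]


@dataclass(frozen=True)
class ModelSpec:
    """Recipe for one transfer-function variant."""

    model_type: str  # wa | wapls
    deshrink: str = "inverse"  # wa only
    tolerance_dw: bool = False  # wa only
    n_components: int = 1  # wapls only

    @property
    def label(self) -> str:
        if self.model_type == "wapls":
            return f"WAPLS({self.n_components})"
        name = "WA_tol" if self.tolerance_dw else "WA"
        return f"{name}_{'inv' if self.deshrink == 'inverse' else 'cla'}"

    def fit(self, species: AbundanceMatrix, x) -> CalibrationModel:
        if self.model_type == "wa":
            return fit_wa(species, x, self.deshrink, self.tolerance_dw)
        if self.model_type == "wapls":
            return fit_wapls(species, x, self.n_components)
        raise DataError(f"unknown model type {self.model_type!r}")


#: the standard seven-model family evaluated in the selection grid
DEFAULT_GRID: tuple[ModelSpec, ...] = (
    ModelSpec("wa", "inverse", False),
    ModelSpec("wa", "classical", False),
    ModelSpec("wa", "inverse", True),
    ModelSpec("wa", "classical", True),
    ModelSpec("wapls", n_components=1),
    ModelSpec("wapls", n_components=2),
    ModelSpec("wapls", n_components=3),
)


@dataclass
class PerformanceStats:
    """Apparent or cross-validated skill of a transfer function."""

    rmse: float
    r2: float
    avg_bias: float
    max_bias: float
    n_segments: int
    n: int

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "r2": self.r2,
            "avg_bias": self.avg_bias,
            "max_bias": self.max_bias,
        }


@dataclass
class RNEResult:
    """Cross-validated r2 under random / neighbor / environment deletion."""

    radii: list[float]
    table: pd.DataFrame  # columns: radius, scheme, r2, n_deleted_mean

    def r2(self, scheme: str, radius: float) -> float:
        t = self.table
        row = t[(t["scheme"] == scheme) & (t["radius"] == radius)]
        return float(row["r2"].iloc[0])


def _drop_empty_taxa(species: AbundanceMatrix, keep_rows: np.ndarray) -> AbundanceMatrix:
    sub = species.values.iloc[keep_rows]
    present = sub.columns[sub.to_numpy(dtype=float).sum(axis=0) > 0]
    return AbundanceMatrix(sub[list(present)], species.transform_state)


def loo_predictions(spec: ModelSpec, species: AbundanceMatrix, x) -> pd.DataFrame:
    """Jackknife predictions: each site predicted by a model refit without it.

    Taxa absent from a fold's reduced training set are dropped for that
    fold; a fold whose test assemblage has no coverage left yields NaN.
    Returns a DataFrame with columns ``observed``, ``predicted``,
    ``coverage``.
    """
    n = len(species.sites)
    if n < 4:
        raise DataError("leave-one-out needs at least 4 sites")
    xv = np.asarray(x, dtype=float)
    preds = np.full(n, np.nan)
    cover = np.zeros(n)
    idx = np.arange(n)
    for i in range(n):
        train_rows = idx[idx != i]
        train = _drop_empty_taxa(species, train_rows)
        model = spec.fit(train, xv[train_rows])
        test = AbundanceMatrix(species.values.iloc[[i]], species.transform_state)
        res = predict(model, test, quiet=True)
        preds[i] = res.predicted.iloc[0]
        cover[i] = res.coverage.iloc[0]
    return pd.DataFrame(
        {"observed": xv, "predicted": preds, "coverage": cover}, index=species.values.index
    )


def performance_stats(observed, predicted, n_segments: int = 10) -> PerformanceStats:
    """RMSE(P), r2, average bias and maximum segment-wise bias.

    r2 is the squared Pearson correlation of predicted vs observed;
    maximum bias is the largest |mean residual| over ``n_segments``
    equal-width segments of the observed gradient (empty segments are
    skipped).  Non-finite prediction pairs are dropped.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise DataError("observed and predicted lengths differ")
    ok = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[ok], pred[ok]
    if obs.size < 3:
        raise DataError("need at least 3 finite (observed, predicted) pairs")
    resid = pred - obs
    rmse = float(np.sqrt(np.mean(resid**2)))
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        r2 = np.nan
    else:
        r2 = float(stats.pearsonr(obs, pred)[0] ** 2)
    avg_bias = float(resid.mean())
    edges = np.linspace(obs.min(), obs.max(), n_segments + 1)
    max_bias = 0.0
    for s in range(n_segments):
        hi_incl = s == n_segments - 1
        in_seg = (obs >= edges[s]) & ((obs <= edges[s + 1]) if hi_incl else (obs < edges[s + 1]))
        if in_seg.any():
            max_bias = max(max_bias, abs(float(resid[in_seg].mean())))
    return PerformanceStats(rmse, r2, avg_bias, float(max_bias), n_segments, int(obs.size))


def _evaluate(spec: ModelSpec, species: AbundanceMatrix, x, n_segments: int = 10) -> dict:
    model = spec.fit(species, x)
    app = performance_stats(x, model.fitted.to_numpy(), n_segments)
    loo = loo_predictions(spec, species, x)
    cv = performance_stats(loo["observed"], loo["predicted"], n_segments)
    return {
        "rmse": app.rmse,
        "r2": app.r2,
        "rmsep": cv.rmse,
        "r2_jack": cv.r2,
        "avg_bias": cv.avg_bias,
        "max_bias": cv.max_bias,
    }


def model_selection_table(
    rel: AbundanceMatrix,
    x,
    specs: tuple[ModelSpec, ...] = DEFAULT_GRID,
    transforms: tuple[str, ...] = ("hellinger", "none"),
    n_segments: int = 10,
) -> pd.DataFrame:
    """Apparent and LOO performance grid over models x transforms.

    ``rel`` must be untransformed proportions; the Hellinger variant is
    derived internally.  The selected row maximises cross-validated r2,
    breaking ties by lower RMSEP then lower maximum bias — the grid is
    always returned in full so a human can override the rule.
    """
    if rel.transform_state != "none":
        raise DataError("model_selection_table expects untransformed proportions")
    if not specs:
        raise DataError("no model specs supplied")
    mats = {}
    for t in transforms:
        if t == "none":
            mats[t] = rel
        elif t == "hellinger":
            mats[t] = hellinger(rel)
        else:
            raise DataError(f"unknown transform {t!r}")
    rows = []
    for spec in specs:
        for t, mat in mats.items():
            stats_row = _evaluate(spec, mat, x, n_segments)
            rows.append({"model": spec.label, "transform": t, **stats_row})
    table = pd.DataFrame(rows)
    order = np.lexsort((table["max_bias"], table["rmsep"], -table["r2_jack"]))
    table["selected"] = False
    table.loc[table.index[order[0]], "selected"] = True
    return table


def outlier_screen(
    spec: ModelSpec, species: AbundanceMatrix, x, k_sd: float = 2.5
) -> dict:
    """Flag sites with extreme jackknife residuals and report the refit.

    Sites whose LOO residual deviates from the mean residual by more than
    ``k_sd`` residual SDs are flagged;
    performance with and without them is reported, but nothing is removed
    automatically — exclusion is a user decision.
    """
    loo = loo_predictions(spec, species, x)
    resid = (loo["predicted"] - loo["observed"]).to_numpy()
    finite = np.isfinite(resid)
    sd = resid[finite].std(ddof=1)
    centered = np.abs(resid - resid[finite].mean())
    flagged = [] if sd == 0 else list(loo.index[finite & (centered > k_sd * sd)])
    before = performance_stats(loo["observed"], loo["predicted"])
    after = None
    if flagged:
        keep = ~species.values.index.isin(flagged)
        sub = _drop_empty_taxa(species, np.where(keep)[0])
        loo2 = loo_predictions(spec, sub, np.asarray(x, dtype=float)[keep])
        after = performance_stats(loo2["observed"], loo2["predicted"])
    return {"flagged": flagged, "before": before, "after": after, "k_sd": k_sd, "residual_sd": float(sd)}


def rne_analysis(
    spec: ModelSpec,
    species: AbundanceMatrix,
    x,
    coords: SiteCoords,
    radii: list[float] = (0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 40.0),
    n_random_reps: int = 10,
    seed: int = 0,
) -> RNEResult:
    """Random / neighbor / environment deletion cross-validation.

    For each radius d, the neighbor scheme removes from every LOO fold all
    training sites within d km of the test site; the environment scheme
    removes the same number of training sites closest to the test site in
    the target variable; the random scheme removes that number uniformly
    at random (r2 averaged over ``n_random_reps``).  Spatial
    autocorrelation shows up as neighbor r2 decaying faster than random.
    """
    if coords.sites != species.sites:
        raise DataError("coordinates and species site orderings differ")
    rng = np.random.default_rng(seed)
    xv = np.asarray(x, dtype=float)
    n = len(xv)
    D = coords.distance_matrix()
    env_dist = np.abs(xv[:, None] - xv[None, :])
    idx = np.arange(n)

    def fold_prediction(i: int, removed: np.ndarray) -> float:
        train_rows = idx[(idx != i) & ~removed]
        if train_rows.size < 3:
            return np.nan
        train = _drop_empty_taxa(species, train_rows)
        try:
            model = spec.fit(train, xv[train_rows])
        except DataError:
            return np.nan
        test = AbundanceMatrix(species.values.iloc[[i]], species.transform_state)
        return float(predict(model, test, quiet=True).predicted.iloc[0])

    def scheme_r2(pred: np.ndarray) -> float:
        ok = np.isfinite(pred)
        if ok.sum() < 3 or np.ptp(xv[ok]) == 0:
            return np.nan
        return float(stats.pearsonr(xv[ok], pred[ok])[0] ** 2)

    rows = []
    for d in radii:
        n_del = np.zeros(n, dtype=int)
        pred_nb = np.full(n, np.nan)
        pred_env = np.full(n, np.nan)
        pred_rand = np.full((n_random_reps, n), np.nan)
        for i in range(n):
            # d = 0 must reduce every scheme to plain LOO, even with
            # co-located sites, so the deletion ball is empty there
            neighbors = (D[i] <= d) & (idx != i) if d > 0 else np.zeros(n, dtype=bool)
            n_del[i] = int(neighbors.sum())
            pred_nb[i] = fold_prediction(i, neighbors)
            # same-size deletion of the environmentally closest sites
            others = idx[idx != i]
            order = others[np.argsort(env_dist[i, others], kind="stable")]
            env_removed = np.zeros(n, dtype=bool)
            env_removed[order[: n_del[i]]] = True
            pred_env[i] = fold_prediction(i, env_removed)
            for rep in range(n_random_reps):
                rand_removed = np.zeros(n, dtype=bool)
                if n_del[i] > 0:
                    rand_removed[rng.choice(others, n_del[i], replace=False)] = True
                pred_rand[rep, i] = fold_prediction(i, rand_removed)
        r2_rand = float(np.nanmean([scheme_r2(pred_rand[rep]) for rep in range(n_random_reps)]))
        rows.append({"radius": d, "scheme": "random", "r2": r2_rand, "n_deleted_mean": float(n_del.mean())})
        rows.append({"radius": d, "scheme": "neighbor", "r2": scheme_r2(pred_nb), "n_deleted_mean": float(n_del.mean())})
        rows.append({"radius": d, "scheme": "environment", "r2": scheme_r2(pred_env), "n_deleted_mean": float(n_del.mean())})
    return RNEResult(list(radii), pd.DataFrame(rows))
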