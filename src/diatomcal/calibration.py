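"""Weighted-averaging and WAPLS transfer-function engines.

The transfer function maps an assemblage (a row of relative abundances or
their Hellinger transform) to an environmental value.  Weighted averaging
(WA) estimates each taxon's optimum u_k as the abundance-weighted mean of
the environment over the training sites and predicts a new site as the
abundance-weighted mean of the optima of the taxa present; because the
double averaging shrinks the range, a deshrinking regression (inverse or
classical) is applied.  Tolerance down-weighting gives narrow-niche taxa
more say.  Weighted-averaging partial least squares (WAPLS) generalises
WA: successive components are built from weighted averages of the current
residual of x, orthogonalised with site-total weights, and x is regressed
on all components; with a single component and inverse deshrinking the
predictions coincide with plain WA whenever the site totals are constant
(e.g. proportion matrices).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import AbundanceMatrix, DataError

__all__ = [
    "TaxonResponse",
    "CalibrationModel",
    "PredictionResult",
    "estimate_responses",
    "fit_wa",
    "fit_wapls",
    "predict",
]

_EPS_TOL = 0.01  # floor on tolerances, as a fraction of the gradient span


@dataclass
class TaxonResponse:
    """Weighted-averaging summary of one taxon's response to the gradient."""

    taxon: str
    optimum: float
    tolerance: float
    n2: float  # Hill's effective number of occurrences
    occurrences: int


@dataclass
class PredictionResult:
    """Per-site predictions plus the assemblage coverage they rest on."""

    predicted: pd.Series
    coverage: pd.Series  # fraction of each assemblage made of training taxa

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"predicted": self.predicted, "coverage": self.coverage})


@dataclass
class CalibrationModel:
    """A fitted WA or WAPLS transfer function.

    All coefficients needed to predict new assemblages are stored:
    for WA the taxon optima (and tolerance weights) plus the deshrinking
    line; for WAPLS the per-component taxon score chains with their
    orthogonalisation, standardisation and regression coefficients.
    """

    model_type: str  # WA_inv | WA_cla | WA_tol_inv | WA_tol_cla | WAPLS
    taxa: list[str]
    training_transform: str
    gradient_range: tuple[float, float]
    fitted: pd.Series
    # WA fields
    optima: np.ndarray | None = None
    tol_weights: np.ndarray | None = None  # 1/t*^2, None when not down-weighted
    deshrink: tuple[float, float] | None = None  # (intercept, slope)
    # WAPLS fields
    n_components: int = 0
    taxon_scores: np.ndarray | None = None  # taxa x components
    ortho_coefs: list[list[float]] | None = None
    comp_means: np.ndarray | None = None
    comp_sds: np.ndarray | None = None
    reg_coefs: np.ndarray | None = None  # regression weights per component
    x_mean: float = 0.0

    # -- prediction -------------------------------------------------------
    def predict(self, new_species: AbundanceMatrix) -> PredictionResult:
        return predict(self, new_species)

    # -- serialisation ----------------------------------------------------
    def to_json(self) -> str:
        def enc(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, pd.Series):
                return {"index": list(v.index), "values": v.tolist()}
            return v

        doc = {"format_version": 1}
        for k, v in self.__dict__.items():
            doc[k] = enc(v)
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        doc = json.loads(text)
        doc.pop("format_version", None)
        doc["fitted"] = pd.Series(doc["fitted"]["values"], index=doc["fitted"]["index"])
        for k in ("optima", "tol_weights", "taxon_scores", "comp_means", "comp_sds", "reg_coefs"):
            if doc.get(k) is not None:
                doc[k] = np.asarray(doc[k], dtype=float)
        doc["gradient_range"] = tuple(doc["gradient_range"])
        if doc.get("deshrink") is not None:
            doc["deshrink"] = tuple(doc["deshrink"])
        return cls(**doc)


def _align(species: AbundanceMatrix, x) -> tuple[np.ndarray, np.ndarray]:
    Y = species.values.to_numpy(dtype=float)
    xv = np.asarray(x, dtype=float)
    if len(xv) != Y.shape[0]:
        raise DataError("environmental vector length does not match site count")
    return Y, xv


def estimate_responses(species: AbundanceMatrix, x) -> pd.DataFrame:
    """Abundance-weighted optima, tolerances, Hill's N2 and occurrences.

    optimum  u_k = sum_i y_ik x_i / sum_i y_ik
    tolerance t_k = sqrt(sum_i y_ik (x_i - u_k)^2 / sum_i y_ik)
    N2_k = (sum_i y_ik)^2 / sum_i y_ik^2
    """
    Y, xv = _align(species, x)
    colsum = Y.sum(axis=0)
    if np.any(colsum <= 0):
        bad = species.taxa[int(np.argmax(colsum <= 0))]
        raise DataError(f"taxon {bad!r} has zero total abundance")
    opt = (Y * xv[:, None]).sum(axis=0) / colsum
    tol = np.sqrt((Y * (xv[:, None] - opt[None, :]) ** 2).sum(axis=0) / colsum)
    n2 = colsum**2 / (Y**2).sum(axis=0)
    occ = (Y > 0).sum(axis=0)
    return pd.DataFrame(
        {"optimum": opt, "tolerance": tol, "n2": n2, "occurrences": occ},
        index=pd.Index(species.taxa, name="taxon"),
    )


def _effective_tolerances(tol: np.ndarray, occ: np.ndarray, span: float) -> np.ndarray:
    """Floor tolerances so down-weighting cannot produce infinite weights.

    Single-occurrence taxa have tolerance 0 by construction; they get the
    mean finite tolerance of the other taxa, and every tolerance is floored
    at 1% of the gradient span.
    """
    t = tol.copy()
    single = occ <= 1
    finite = t[~single]
    fill = finite.mean() if finite.size else span * _EPS_TOL
    t[single] = fill
    return np.maximum(t, span * _EPS_TOL if span > 0 else _EPS_TOL)


def fit_wa(
    species: AbundanceMatrix,
    x,
    deshrink: str = "inverse",
    tolerance_dw: bool = False,
) -> CalibrationModel:
    """Fit a weighted-averaging transfer function.

    ``deshrink`` is ``"inverse"`` (OLS of x on the WA estimates; fitted
    line is the prediction) or ``"classical"`` (OLS of the estimates on x,
    inverted).  With ``tolerance_dw`` the site average weights each taxon
    by y/t*^2.
    """
    if deshrink not in ("inverse", "classical"):
        raise DataError(f"unknown deshrinking {deshrink!r}")
    Y, xv = _align(species, x)
    if Y.shape[0] < 3:
        raise DataError("WA needs at least 3 sites")
    resp = estimate_responses(species, xv)
    opt = resp["optimum"].to_numpy()
    span = float(np.ptp(xv))
    tw = None
    W = Y
    if tolerance_dw:
        t_eff = _effective_tolerances(resp["tolerance"].to_numpy(), resp["occurrences"].to_numpy(), span)
        tw = 1.0 / t_eff**2
        W = Y * tw[None, :]
    x0 = (W * opt[None, :]).sum(axis=1) / W.sum(axis=1)
    if np.ptp(x0) <= 0:
        raise DataError("initial WA estimates have zero variance; cannot deshrink")
    if deshrink == "inverse":
        slope, intercept = np.polyfit(x0, xv, 1)
        fitted = intercept + slope * x0
    else:
        slope, intercept = np.polyfit(xv, x0, 1)
        fitted = (x0 - intercept) / slope
    name = {"inverse": "WA_inv", "classical": "WA_cla"}[deshrink]
    if tolerance_dw:
        name = name.replace("WA_", "WA_tol_")
    return CalibrationModel(
        model_type=name,
        taxa=species.taxa,
        training_transform=species.transform_state,
        gradient_range=(float(xv.min()), float(xv.max())),
        fitted=pd.Series(fitted, index=species.sites),
        optima=opt,
        tol_weights=tw,
        deshrink=(float(intercept), float(slope)),
    )


def fit_wapls(species: AbundanceMatrix, x, n_components: int) -> CalibrationModel:
    """Fit a weighted-averaging partial least squares transfer function.

    Components are built iteratively: taxon scores are weighted averages
    of the current residual of x, raw site scores are weighted averages of
    the taxon scores, each component is orthogonalised against earlier
    ones under site-total weights and standardised to zero weighted mean
    and unit weighted SD, and x is regressed on all components (weighted
    least squares, site totals as weights).  Predictions are invariant to
    the standardisation, which only conditions the regression.
    """
    if n_components < 1:
        raise DataError("n_components must be >= 1")
    Y, xv = _align(species, x)
    n = Y.shape[0]
    rank = int(np.linalg.matrix_rank(Y - Y.mean(axis=0)))
    if n_components > rank:
        raise DataError(f"requested {n_components} components; at most {rank} usable")
    w = Y.sum(axis=1)
    if np.any(w <= 0):
        raise DataError("site with zero total abundance")
    r = w / w.sum()
    colsum = Y.sum(axis=0)
    if np.any(colsum <= 0):
        bad = species.taxa[int(np.argmax(colsum <= 0))]
        raise DataError(f"taxon {bad!r} has zero total abundance")

    x_mean = float(np.sum(r * xv))
    e = xv - x_mean
    comps: list[np.ndarray] = []
    taxon_scores = np.zeros((Y.shape[1], n_components))
    ortho: list[list[float]] = []
    means, sds, betas = [], [], []
    fitted = np.full(n, x_mean)
    for a in range(n_components):
        u = (Y * e[:, None]).sum(axis=0) / colsum
        s = (Y @ u) / w
        coefs = []
        for f in comps:
            c = float(np.sum(r * s * f))
            s = s - c * f
            coefs.append(c)
        m = float(np.sum(r * s))
        sd = float(np.sqrt(np.sum(r * (s - m) ** 2)))
        if sd < 1e-12:
            # degenerate (e.g. constant x): stop with the components so far
            break
        comp = (s - m) / sd
        comps.append(comp)
        taxon_scores[:, a] = u
        ortho.append(coefs)
        means.append(m)
        sds.append(sd)
        # components are r-orthonormal, so coefficients are simple projections
        betas = [float(np.sum(r * xv * f)) for f in comps]
        fitted = x_mean + sum(b * f for b, f in zip(betas, comps))
        e = xv - fitted
    k = len(comps)
    return CalibrationModel(
        model_type="WAPLS",
        taxa=species.taxa,
        training_transform=species.transform_state,
        gradient_range=(float(xv.min()), float(xv.max())),
        fitted=pd.Series(fitted, index=species.sites),
        n_components=k,
        taxon_scores=taxon_scores[:, :k],
        ortho_coefs=ortho,
        comp_means=np.asarray(means),
        comp_sds=np.asarray(sds),
        reg_coefs=np.asarray(betas) if k else np.zeros(0),
        x_mean=x_mean,
    )


def predict(model: CalibrationModel, new_species: AbundanceMatrix, quiet: bool = False) -> PredictionResult:
    """Apply a fitted model to new assemblages.

    Taxa absent from the training set are dropped (with the remaining
    fraction of each assemblage reported as coverage); a site whose
    assemblage contains no training taxa gets a NaN prediction rather
    than a silently extrapolated number.  ``quiet`` suppresses the
    dropped-taxa warning (used by cross-validation folds, where reduced
    training sets make drops routine).
    """
    vals = new_species.values
    known = [t for t in model.taxa if t in vals.columns]
    if len(known) < len(vals.columns) and not quiet:
        import logging

        logging.getLogger(__name__).warning(
            "dropping %d taxa absent from training", len(vals.columns) - len(known)
        )
    row_tot = vals.to_numpy(dtype=float).sum(axis=1)
    Y = vals.reindex(columns=model.taxa, fill_value=0.0).to_numpy(dtype=float)
    cov_mass = Y.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        coverage = np.where(row_tot > 0, cov_mass / row_tot, 0.0)
    ok = cov_mass > 0
    pred = np.full(vals.shape[0], np.nan)

    if model.model_type.startswith("WA"):
        if model.model_type == "WAPLS":
            w = cov_mass
            scores = np.zeros((vals.shape[0], model.n_components))
            for a in range(model.n_components):
                raw = np.where(ok, (Y @ model.taxon_scores[:, a]) / np.where(ok, w, 1.0), np.nan)
                for f, c in enumerate(model.ortho_coefs[a]):
                    raw = raw - c * scores[:, f]
                scores[:, a] = (raw - model.comp_means[a]) / model.comp_sds[a]
            if model.n_components:
                pred = model.x_mean + scores @ model.reg_coefs
            else:
                pred = np.full(vals.shape[0], model.x_mean)
            pred = np.where(ok, pred, np.nan)
        else:
            W = Y if model.tol_weights is None else Y * model.tol_weights[None, :]
            wsum = W.sum(axis=1)
            ok = wsum > 0
            x0 = np.where(ok, (W @ model.optima) / np.where(ok, wsum, 1.0), np.nan)
            intercept, slope = model.deshrink
            if model.model_type in ("WA_inv", "WA_tol_inv"):
                pred = intercept + slope * x0
            else:
                pred = (x0 - intercept) / slope
    else:  # pragma: no cover - guarded by constructor
        raise DataError(f"unknown model type {model.model_type!r}")
    return PredictionResult(
        pd.Series(pred, index=vals.index, name="predicted"),
        pd.Series(coverage, index=vals.index, name="coverage"),
    )
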