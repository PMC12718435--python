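"""Constrained ordination and environmental-variable screening.

Implements the screening chain used before building a transfer function:
Pearson correlation grouping of redundant variables, DCA gradient length to
choose linear vs unimodal methods, redundancy analysis (RDA) and partial
RDA, Monte Carlo permutation tests, forward selection with independence
testing, per-variable variance partitioning, and the lambda1/lambda2
criterion that flags variables strong enough to calibrate against.

RDA here is the linear constrained ordination of Legendre & Legendre:
principal components of the fitted values of the multivariate regression
of the (centred, typically Hellinger-transformed) community matrix on the
constraints, after residualising both on any covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .data_model import AbundanceMatrix, DataError, EnvTable

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationGroups",
    "OrdinationResult",
    "SelectionReport",
    "correlation_groups",
    "dca_gradient_length",
    "rda_fit",
    "permutation_test",
    "forward_select",
    "independence_test",
    "variance_partition",
    "lambda_ratio",
    "lambda_ratio_from_percent",
]


# ---------------------------------------------------------------------------
# correlation grouping


@dataclass
class CorrelationGroups:
    """Partition of variables into mutually-correlated groups.

    Variables are linked when |r| > threshold_r and p < threshold_p; groups
    are the connected components of the link graph (singletons allowed).
    """

    groups: list[list[str]]
    pairwise_r: pd.DataFrame
    pairwise_p: pd.DataFrame
    threshold_r: float
    threshold_p: float
    excluded: list[str] = field(default_factory=list)


def correlation_groups(
    env: EnvTable, threshold_r: float = 0.8, threshold_p: float = 0.001
) -> CorrelationGroups:
    """Group redundant variables by pairwise Pearson correlation.

    p-values use the t distribution with n-2 degrees of freedom.  Constant
    columns cannot be correlated and are excluded with a warning.
    """
    vals = env.values
    if vals.shape[0] < 3:
        raise DataError("correlation grouping needs at least 3 sites")
    keep, excluded = [], []
    for v in vals.columns:
        (keep if vals[v].std(ddof=1) > 0 else excluded).append(v)
    if excluded:
        logger.warning("excluding constant variable(s) from correlation grouping: %s", excluded)
    sub = vals[keep]
    p_names = list(sub.columns)
    m = len(p_names)
    r_mat = np.eye(m)
    p_mat = np.zeros((m, m))
    adj = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            r, p = stats.pearsonr(sub.iloc[:, i], sub.iloc[:, j])
            r_mat[i, j] = r_mat[j, i] = r
            p_mat[i, j] = p_mat[j, i] = p
            if abs(r) > threshold_r and p < threshold_p:
                adj[i, j] = adj[j, i] = True
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [[p_names[i] for i in range(m) if labels[i] == g] for g in range(n_comp)]
    groups.sort(key=lambda g: (-len(g), g[0]))
    return CorrelationGroups(
        groups,
        pd.DataFrame(r_mat, index=p_names, columns=p_names),
        pd.DataFrame(p_mat, index=p_names, columns=p_names),
        threshold_r,
        threshold_p,
        excluded,
    )


# ---------------------------------------------------------------------------
# DCA gradient length


def dca_gradient_length(
    species: AbundanceMatrix, n_segments: int = 26, rescale: bool = True
) -> tuple[float, str]:
    """First-axis gradient length in species-turnover SD units.

    Correspondence analysis by SVD of the chi-square standardised matrix
    gives the first axis; segment detrending only affects later axes, so
    the length of axis 1 depends on the (optional) nonlinear rescaling
    alone.  Rescaling follows Hill's idea: the axis is expressed in units
    of the local within-sample dispersion of species scores, estimated in
    ``n_segments`` equal-width segments, so one SD corresponds to roughly
    one average species turnover.  Returns ``(length_sd, recommendation)``
    with recommendation ``"RDA"`` when the length is below 2 SD, else
    ``"CCA"``.
    """
    Y = species.values.to_numpy(dtype=float)
    if Y.shape[0] < 3 or Y.shape[1] < 2:
        raise DataError("DCA needs at least 3 sites and 2 taxa")
    if np.any(Y.sum(axis=1) <= 0) or np.any(Y.sum(axis=0) <= 0):
        raise DataError("DCA input has all-zero rows or columns")

    P = Y / Y.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    if sv[0] < 1e-12:
        # no turnover at all: every site has the same composition
        return 0.0, "RDA"
    if len(sv) < 2 or sv[1] < 1e-12 and sv[0] < 1e-12:
        raise DataError("community matrix is degenerate (rank < 2)")

    # species standard coordinates (weighted variance 1); shrunken site
    # scores are the within-site weighted averages of species scores
    u = Vt[0] / np.sqrt(c)
    x_site = (Y @ u) / Y.sum(axis=1)
    mu = x_site
    disp2 = (Y * (u[None, :] - mu[:, None]) ** 2).sum(axis=1) / Y.sum(axis=1)

    w = Y.sum(axis=1)
    pooled = np.sqrt(np.sum(w * disp2) / np.sum(w))
    if pooled < 1e-12:
        return 0.0, "RDA"
    if not rescale:
        length = float(np.ptp(x_site) / pooled)
        return length, "RDA" if length < 2 else "CCA"

    # per-segment local dispersion; empty/degenerate segments borrow the
    # pooled value so the stretched lengths always sum over the full range
    lo, hi = x_site.min(), x_site.max()
    edges = np.linspace(lo, hi, n_segments + 1)
    length = 0.0
    for s in range(n_segments):
        in_seg = (x_site >= edges[s]) & (x_site <= edges[s + 1] if s == n_segments - 1 else x_site < edges[s + 1])
        if in_seg.sum() > 0 and np.sum(w[in_seg] * disp2[in_seg]) > 0:
            local = np.sqrt(np.sum(w[in_seg] * disp2[in_seg]) / np.sum(w[in_seg]))
        else:
            local = pooled
        length += (edges[s + 1] - edges[s]) / local
    return float(length), "RDA" if length < 2 else "CCA"


# ---------------------------------------------------------------------------
# RDA


@dataclass
class OrdinationResult:
    """Eigenstructure of a (partial) redundancy analysis."""

    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    total_variance: float  # covariate-adjusted total
    grand_total_variance: float  # before covariate removal
    variance_fraction: np.ndarray  # constrained axes, % of covariate-adjusted total
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    constraints: list[str]
    covariates: list[str]

    @property
    def constrained_variance(self) -> float:
        return float(self.constrained_eigenvalues.sum())

    @property
    def residual_variance(self) -> float:
        return float(self.unconstrained_eigenvalues.sum())


def _matrix(env: EnvTable, names: list[str]) -> np.ndarray:
    missing = [v for v in names if v not in env.values.columns]
    if missing:
        raise DataError(f"unknown environmental variable(s): {missing}")
    return env.values[names].to_numpy(dtype=float)


def _residualize(M: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    """Residuals of the columns of M on [1, Z] (always removes the mean)."""
    Mc = M - M.mean(axis=0)
    if Z is None or Z.shape[1] == 0:
        return Mc
    Zc = Z - Z.mean(axis=0)
    coef, *_ = np.linalg.lstsq(Zc, Mc, rcond=None)
    return Mc - Zc @ coef


def rda_fit(
    species: AbundanceMatrix,
    env: EnvTable,
    constraints: list[str],
    covariates: list[str] | None = None,
) -> OrdinationResult:
    """Redundancy analysis of the community matrix on the constraints.

    With covariates, both the community matrix and the constraint columns
    are residualised on the covariates first (partial RDA).  Eigenvalues
    are variances (sums of squares / (n-1)); constrained axes are the
    principal axes of the fitted values, residual axes those of the
    regression residuals.
    """
    covariates = covariates or []
    if set(constraints) & set(covariates):
        raise DataError("constraints and covariates overlap")
    if species.sites != env.sites:
        raise DataError("species and environment site orderings differ")
    n = len(species.sites)
    Y = species.values.to_numpy(dtype=float)
    Yc = Y - Y.mean(axis=0)
    grand_total = float((Yc**2).sum() / (n - 1))

    Z = _matrix(env, covariates) if covariates else None
    X = _matrix(env, constraints)
    Yr = _residualize(Y, Z)
    Xr = _residualize(X, Z)
    # constraints fully absorbed by the covariates carry no conditional
    # information: keep them out of the projection instead of failing
    ref = np.maximum(np.linalg.norm(X - X.mean(axis=0), axis=0), 1e-30)
    aliased = np.linalg.norm(Xr, axis=0) <= 1e-10 * ref
    if aliased.any():
        if not covariates:
            raise DataError(f"collinear (rank-deficient) constraint set: {constraints}")
        logger.warning(
            "constraint(s) aliased by covariates: %s",
            [v for v, a in zip(constraints, aliased) if a],
        )
    Xk = Xr[:, ~aliased]
    if Xk.shape[1] and np.linalg.matrix_rank(Xk) < Xk.shape[1]:
        raise DataError(f"collinear (rank-deficient) constraint set: {constraints}")
    total = float((Yr**2).sum() / (n - 1))

    if Xk.shape[1]:
        coef, *_ = np.linalg.lstsq(Xk, Yr, rcond=None)
        fitted = Xk @ coef
    else:
        fitted = np.zeros_like(Yr)
    resid = Yr - fitted

    Uf, sf, Vft = np.linalg.svd(fitted, full_matrices=False)
    k = max(min(Xk.shape[1], n - 1, Y.shape[1]), 1)
    lam_c = (sf[:k] ** 2) / (n - 1)
    Ur, sr, Vrt = np.linalg.svd(resid, full_matrices=False)
    lam_u = (sr**2) / (n - 1)
    lam_u = lam_u[lam_u > max(1e-12 * max(total, 1.0), 0)]

    frac = 100.0 * lam_c / total if total > 0 else np.zeros_like(lam_c)
    axes_c = [f"RDA{i+1}" for i in range(k)]
    site_scores = pd.DataFrame(Uf[:, :k] * sf[:k], index=species.sites, columns=axes_c)
    species_scores = pd.DataFrame(Vft[:k].T, index=species.taxa, columns=axes_c)
    # biplot scores: correlations of constraint columns with site scores
    bip = np.zeros((len(constraints), k))
    for j in range(k):
        ss = site_scores.iloc[:, j].to_numpy()
        if ss.std() > 0:
            for i in range(len(constraints)):
                xi = Xr[:, i]
                bip[i, j] = np.corrcoef(xi, ss)[0, 1] if xi.std() > 0 else 0.0
    biplot = pd.DataFrame(bip, index=constraints, columns=axes_c)
    return OrdinationResult(
        lam_c, lam_u, total, grand_total, frac, site_scores, species_scores, biplot,
        list(constraints), list(covariates),
    )


# ---------------------------------------------------------------------------
# permutation machinery


def _pseudo_F(Yr: np.ndarray, Xr: np.ndarray, n: int, q: int, pcov: int) -> tuple[float, float]:
    """Pseudo-F of the constrained regression (inputs already residualised)."""
    coef, *_ = np.linalg.lstsq(Xr, Yr, rcond=None)
    fitted = Xr @ coef
    ss_fit = float((fitted**2).sum())
    ss_res = float(((Yr - fitted) ** 2).sum())
    df_res = n - q - pcov - 1
    if df_res <= 0 or ss_res <= 0:
        return np.inf, ss_fit
    return (ss_fit / q) / (ss_res / df_res), ss_fit


def permutation_test(
    species: AbundanceMatrix,
    env: EnvTable,
    constraints: list[str],
    covariates: list[str] | None = None,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Monte Carlo significance of an (partial) RDA constraint set.

    The null is built by unrestricted permutation of the site labels of
    the constraint columns, with covariates held fixed; the p-value is
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    covariates = covariates or []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(species.sites)
    q, pcov = len(constraints), len(covariates)
    Y = species.values.to_numpy(dtype=float)
    Z = _matrix(env, covariates) if covariates else None
    X = _matrix(env, constraints)
    Yr = _residualize(Y, Z)
    Xr = _residualize(X, Z)
    f_obs, _ = _pseudo_F(Yr, Xr, n, q, pcov)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Xp = _residualize(X[perm], Z)
        f_p, _ = _pseudo_F(Yr, Xp, n, q, pcov)
        if f_p >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(p)


# ---------------------------------------------------------------------------
# forward selection / independence / partitioning


@dataclass
class SelectionStep:
    variable: str
    added_variance_pct: float  # % of covariate-adjusted total
    pseudo_F: float
    p_value: float


@dataclass
class SelectionReport:
    selected: list[str]
    steps: list[SelectionStep]
    rejected: dict[str, str]  # variable -> reason
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.variable, s.added_variance_pct, s.pseudo_F, s.p_value) for s in self.steps],
            columns=["variable", "added_variance_pct", "pseudo_F", "p"],
        )


def _conditional_variance_pct(species, env, var, conditioning) -> float:
    res = rda_fit(species, env, [var], conditioning)
    return 100.0 * res.constrained_variance / res.grand_total_variance if res.grand_total_variance > 0 else 0.0


def forward_select(
    species: AbundanceMatrix,
    env: EnvTable,
    candidates: list[str],
    covariates: list[str] | None = None,
    alpha: float = 0.01,
    n_perm: int = 999,
    seed: int = 0,
) -> SelectionReport:
    """Forward selection of constraints by added variance with permutation gates.

    At each step the candidate with the largest additional explained
    variance among those significant (p <= alpha) given the already
    selected variables plus covariates is added; selection stops when no
    candidate qualifies.  Ties break lexicographically for determinism.
    """
    if not candidates:
        raise DataError("no candidate variables supplied")
    if 1.0 / (n_perm + 1) > alpha:
        logger.warning(
            "permutation p-value floor 1/%d exceeds alpha=%g; nothing can be selected",
            n_perm + 1,
            alpha,
        )
    covariates = covariates or []
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    steps: list[SelectionStep] = []
    rejected: dict[str, str] = {}
    remaining = sorted(candidates)
    while remaining:
        results = []
        for var in remaining:
            cond = selected + covariates
            try:
                f, p = permutation_test(species, env, [var], cond, n_perm, rng)
                res = rda_fit(species, env, [var], cond)
            except DataError:
                continue
            pct = 100.0 * res.constrained_variance / res.total_variance if res.total_variance > 0 else 0.0
            results.append((var, pct, f, p))
        qualifying = [r for r in results if r[3] <= alpha]
        if not qualifying:
            for var, pct, f, p in results:
                rejected.setdefault(var, f"non-significant (p={p:.3f})")
            break
        # largest added variance wins; exact ties resolve lexicographically
        top_pct = max(r[1] for r in qualifying)
        best = min((r for r in qualifying if r[1] == top_pct), key=lambda r: r[0])
        selected.append(best[0])
        steps.append(SelectionStep(best[0], best[1], best[2], best[3]))
        remaining = [v for v in remaining if v != best[0]]
    return SelectionReport(selected, steps, rejected, alpha)


def independence_test(
    species: AbundanceMatrix,
    env: EnvTable,
    varA: str,
    varB: str,
    alpha: float = 0.01,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Test whether two selected variables explain independent variance.

    Each variable is tested conditioned on the other; a variable that
    loses significance under conditioning is declared dependent on the
    other, and the one with the larger marginal variance is retained.
    """
    if varA == varB:
        raise DataError("independence_test needs two distinct variables")
    rng = np.random.default_rng(seed)
    out = {}
    for v, other in ((varA, varB), (varB, varA)):
        f, p = permutation_test(species, env, [v], [other], n_perm, rng)
        marg = _conditional_variance_pct(species, env, v, [])
        cond = _conditional_variance_pct(species, env, v, [other])
        out[v] = {"conditional_p": p, "marginal_pct": marg, "conditional_pct": cond}
    dep = out[varA]["conditional_p"] > alpha or out[varB]["conditional_p"] > alpha
    verdict = "dependent" if dep else "independent"
    retain = None
    if dep:
        retain = varA if (out[varA]["marginal_pct"], varB) > (out[varB]["marginal_pct"], varA) else varB
        # tie-break by name when marginal variance is identical
        if out[varA]["marginal_pct"] == out[varB]["marginal_pct"]:
            retain = min(varA, varB)
    return {"verdict": verdict, "retain": retain, "details": out}


def variance_partition(
    species: AbundanceMatrix,
    env: EnvTable,
    selected: list[str],
    covariates: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-variable conditional variance shares of the final (partial) RDA.

    For each selected variable, a partial RDA with that variable as the
    sole constraint and all other selected variables plus covariates as
    conditioning set gives its unique explained percentage of the total
    community variance; joint, covariate and total-explained rows complete
    the decomposition.  Percentages are of the grand (unadjusted) total.
    """
    if not selected:
        raise DataError("variance_partition needs at least one selected variable")
    covariates = covariates or []
    rng = np.random.default_rng(seed)
    rows = []
    for v in selected:
        cond = [s for s in selected if s != v] + covariates
        res = rda_fit(species, env, [v], cond)
        pct = 100.0 * res.constrained_variance / res.grand_total_variance
        f, p = permutation_test(species, env, [v], cond, n_perm, rng)
        lam1 = 100.0 * res.constrained_eigenvalues[0] / res.grand_total_variance
        pc1 = 100.0 * res.unconstrained_eigenvalues[0] / res.grand_total_variance
        rows.append((v, pct, lam1, pc1, lam1 / pc1 if pc1 > 0 else np.inf, p))
    table = pd.DataFrame(rows, columns=["variable", "variance_pct", "RDA1_pct", "PC1_pct", "lambda_ratio", "p"])
    # the joint fit needs a full-rank constraint basis; redundant variables
    # contribute nothing to it, so drop them (their unique share is 0 anyway)
    basis: list[str] = []
    for v in selected:
        M = _matrix(env, basis + [v])
        if np.linalg.matrix_rank(M - M.mean(axis=0)) == len(basis) + 1:
            basis.append(v)
    joint = rda_fit(species, env, basis, covariates)
    joint_pct = 100.0 * joint.constrained_variance / joint.grand_total_variance
    cov_pct = 0.0
    if covariates:
        cov_res = rda_fit(species, env, covariates, [])
        cov_pct = 100.0 * cov_res.constrained_variance / cov_res.grand_total_variance
    table.attrs["joint_constrained_pct"] = joint_pct
    table.attrs["covariate_pct"] = cov_pct
    table.attrs["total_explained_pct"] = joint_pct + cov_pct
    return table


def lambda_ratio_from_percent(rda1_pct: float, pc1_pct: float) -> float:
    """Ratio of the constrained first-axis share to the first residual axis."""
    if pc1_pct <= 0:
        raise DataError("first residual eigenvalue must be positive")
    return rda1_pct / pc1_pct


def lambda_ratio(
    species: AbundanceMatrix,
    env: EnvTable,
    variable: str,
    covariates: list[str] | None = None,
) -> tuple[float, bool]:
    """lambda1/lambda2 criterion for a single candidate variable.

    Fits the partial RDA with ``variable`` as sole constraint and returns
    the ratio of the constrained axis eigenvalue to the first residual
    (unconstrained) eigenvalue, plus the usable-for-calibration flag
    (ratio > 0.5).
    """
    res = rda_fit(species, env, [variable], covariates)
    if len(res.unconstrained_eigenvalues) == 0 or res.unconstrained_eigenvalues[0] <= 0:
        raise DataError("first residual eigenvalue is zero; ratio undefined")
    ratio = lambda_ratio_from_percent(
        float(res.constrained_eigenvalues[0]), float(res.unconstrained_eigenvalues[0])
    )
    return ratio, ratio > 0.5
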