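"""Feature-matrix statistics: availability filtering, autoscaling, PCA,
orthogonal-scores PLS / PLS-DA with VIP importance, leave-one-out
validation, and the univariate group tests.

The discriminant analysis is PLS1 regression on a 0/1 class indicator
(NIPALS, orthogonal scores): per component *a*

    w_a  = X' y / ||X' y||          (unit-norm weight)
    t_a  = X w_a                    (score)
    p_a  = X' t_a / (t_a' t_a)      (X-loading)
    q_a  = y' t_a / (t_a' t_a)      (Y-loading)
    X   <- X - t_a p_a'             (deflation)

Scores are mutually orthogonal by construction.  Variable importance in
projection for the first A components is

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a ),
    SS_a  = q_a^2 t_a' t_a

and satisfies sum_j VIP_j^2 = p (the number of features).  Predictive
performance uses leave-one-out cross-validation with re-centering and
re-scaling inside each fold: RMSEP_k = sqrt(PRESS_k / n) and
R2_k = 1 - PRESS_k / SS_tot (which can be negative for models worse than
the mean predictor).

Everything in this module is deterministic given its input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# feature-matrix preparation
# ---------------------------------------------------------------------------


def availability_filter(M: pd.DataFrame, threshold: float = 0.70) -> pd.DataFrame:
    """Keep features non-missing in at least ``threshold`` of participants.

    Dropped feature names are logged.  Raises if the threshold is not in
    (0, 1] or if no feature survives.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    frac = M.notna().mean(axis=0)
    keep = frac >= threshold
    dropped = list(M.columns[~keep])
    if dropped:
        logger.info(
            "availability filter dropped %d/%d features: %s",
            len(dropped), M.shape[1], ", ".join(dropped),
        )
    if not keep.any():
        raise ValueError("no features survive the availability filter")
    return M.loc[:, keep]


def drop_constant_features(M: pd.DataFrame) -> pd.DataFrame:
    """Drop zero-variance features (no information for scaled analyses;
    typically discretised spectral summaries that landed in one bin for
    every participant).  Dropped names are logged."""
    sd = M.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = list(M.columns[~keep])
    if dropped:
        logger.info("dropped %d constant feature(s): %s", len(dropped), ", ".join(dropped))
    if not keep.any():
        raise ValueError("no non-constant features remain")
    return M.loc[:, keep]


@dataclass
class ScaledMatrix:
    """Autoscaled matrix with provenance: centers, scales, imputation mask."""

    X: pd.DataFrame            # mean 0, sample SD 1; imputed cells are 0
    centers: pd.Series
    scales: pd.Series
    imputed: pd.DataFrame      # boolean per-cell imputation flags


def autoscale(M: pd.DataFrame) -> ScaledMatrix:
    """Column-wise center to mean 0 and scale to sample SD 1 (ddof=1).

    Remaining missing cells are mean-imputed, i.e. 0 after scaling, with
    the per-cell flags retained.  A constant column is an error (named).
    """
    centers = M.mean(axis=0)
    scales = M.std(axis=0, ddof=1)
    constant = scales[(scales == 0) | scales.isna()]
    if len(constant):
        raise ValueError(f"constant column(s): {', '.join(map(str, constant.index))}")
    imputed = M.isna()
    Z = (M - centers) / scales
    Z = Z.fillna(0.0)
    n_imp = int(imputed.values.sum())
    if n_imp:
        logger.info("mean-imputed %d missing cells", n_imp)
    return ScaledMatrix(X=Z, centers=centers, scales=scales, imputed=imputed)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    scores: pd.DataFrame          # participants x components
    loadings: pd.DataFrame        # features x components
    sdev: np.ndarray              # component standard deviations
    explained_var_pct: np.ndarray


def fit_pca(scaled: ScaledMatrix | pd.DataFrame) -> PCAModel:
    """Principal components of the autoscaled matrix via SVD.

    Explained-variance percentages sum to 100 over all components.
    """
    Z = scaled.X if isinstance(scaled, ScaledMatrix) else scaled
    X = Z.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2 / (n - 1)
    comps = [f"PC{i+1}" for i in range(len(s))]
    return PCAModel(
        scores=pd.DataFrame(U * s, index=Z.index, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=Z.columns, columns=comps),
        sdev=np.sqrt(var),
        explained_var_pct=100.0 * var / var.sum(),
    )


# ---------------------------------------------------------------------------
# PLS / PLS-DA
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    ncomp: int
    feature_names: list[str]
    W: np.ndarray                  # features x ncomp, unit-norm columns
    P: np.ndarray                  # X-loadings
    T: np.ndarray                  # scores, mutually orthogonal
    q: np.ndarray                  # Y-loadings, length ncomp
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: float
    explained_x_var_pct: np.ndarray  # per component, % of scaled-X SS
    explained_y_var_pct: np.ndarray  # per component, % of centered-y SS
    sample_ids: list = field(default_factory=list)

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.P,
            index=self.feature_names,
            columns=[f"comp{a+1}" for a in range(self.ncomp)],
        )


def _as_matrix(M) -> tuple[np.ndarray, list[str], list]:
    if isinstance(M, pd.DataFrame):
        return M.to_numpy(dtype=float), list(map(str, M.columns)), list(M.index)
    X = np.asarray(M, dtype=float)
    return X, [f"x{j+1}" for j in range(X.shape[1])], list(range(X.shape[0]))


def fit_plsda(
    M,
    y: Sequence[float] | Sequence[int],
    ncomp: int,
    scale: bool = True,
) -> PLSModel:
    """Fit orthogonal-scores NIPALS PLS1 of ``y`` on the feature matrix.

    ``y`` may be a 0/1 class indicator (PLS-DA) or a numeric response; it
    is centered internally.  Columns of ``M`` are centered and, with
    ``scale=True``, scaled to sample SD 1.  ``ncomp`` must lie in
    [1, min(n - 1, p)].
    """
    X0, names, ids = _as_matrix(M)
    yv = np.asarray(y, dtype=float)
    n, p = X0.shape
    if len(yv) != n:
        raise ValueError("y length does not match matrix rows")
    if np.ptp(yv) == 0:
        raise ValueError("y is constant")
    if not 1 <= ncomp <= min(n - 1, p):
        raise ValueError(f"ncomp must be in [1, {min(n - 1, p)}], got {ncomp}")

    x_center = X0.mean(axis=0)
    x_scale = X0.std(axis=0, ddof=1) if scale else np.ones(p)
    if np.any(x_scale == 0):
        bad = [names[j] for j in np.flatnonzero(x_scale == 0)]
        raise ValueError(f"constant column(s): {', '.join(bad)}")
    X = (X0 - x_center) / x_scale
    y_center = float(yv.mean())
    yc = yv - y_center

    ss_x_total = float(np.sum(X**2))
    ss_y_total = float(np.sum(yc**2))

    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    T = np.zeros((n, ncomp))
    q = np.zeros(ncomp)
    exp_x = np.zeros(ncomp)
    exp_y = np.zeros(ncomp)

    Xa = X.copy()
    for a in range(ncomp):
        w = Xa.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            raise ValueError(f"X exhausted after {a} components (X'y ~ 0)")
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        if tt < 1e-12:
            raise ValueError(f"degenerate score at component {a + 1}")
        pvec = Xa.T @ t / tt
        qa = float(yc @ t) / tt
        Xa = Xa - np.outer(t, pvec)
        W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa
        exp_x[a] = 100.0 * tt * float(pvec @ pvec) / ss_x_total
        exp_y[a] = 100.0 * qa**2 * tt / ss_y_total

    return PLSModel(
        ncomp=ncomp,
        feature_names=names,
        W=W,
        P=P,
        T=T,
        q=q,
        x_center=x_center,
        x_scale=x_scale,
        y_center=y_center,
        explained_x_var_pct=exp_x,
        explained_y_var_pct=exp_y,
        sample_ids=ids,
    )


def pls_coefficients(model: PLSModel, ncomp: int | None = None) -> np.ndarray:
    """Regression coefficients on the scaled X for the first ``ncomp``
    components: B = W (P'W)^{-1} q."""
    a = model.ncomp if ncomp is None else ncomp
    W, P, q = model.W[:, :a], model.P[:, :a], model.q[:a]
    return W @ np.linalg.solve(P.T @ W, q)


def pls_predict(model: PLSModel, M, ncomp: int | None = None) -> np.ndarray:
    """Predict the (class-indicator or numeric) response for new rows."""
    Xnew, _, _ = _as_matrix(M)
    Z = (Xnew - model.x_center) / model.x_scale
    return model.y_center + Z @ pls_coefficients(model, ncomp)


def vip(model: PLSModel, ncomp: int | None = None) -> pd.Series:
    """Variable importance in projection over the first ``ncomp``
    components; satisfies sum(VIP^2) = number of features."""
    a = model.ncomp if ncomp is None else ncomp
    if not 1 <= a <= model.ncomp:
        raise ValueError(f"ncomp must be in [1, {model.ncomp}]")
    p = len(model.feature_names)
    tt = np.einsum("ia,ia->a", model.T[:, :a], model.T[:, :a])
    ss = model.q[:a] ** 2 * tt                      # explained-y SS per comp
    wnorm2 = np.sum(model.W[:, :a] ** 2, axis=0)    # columns are unit norm
    contrib = (model.W[:, :a] ** 2 / wnorm2) @ ss
    scores = np.sqrt(p * contrib / ss.sum())
    return pd.Series(scores, index=model.feature_names, name="vip")


# ---------------------------------------------------------------------------
# importance report
# ---------------------------------------------------------------------------


@dataclass
class ImportanceReport:
    table: pd.DataFrame  # per feature: vip, loadings, flags, group stats


def important_features(
    model: PLSModel,
    ncomp: int | None = None,
    vip_threshold: float = 2.0,
    loading_threshold: float = 0.2,
    M: pd.DataFrame | None = None,
    labels: Sequence[bool] | None = None,
    equal_var: bool = False,
) -> ImportanceReport:
    """Flag features with VIP >= ``vip_threshold`` or any first-``ncomp``
    |loading| >= ``loading_threshold``; attach the two-group comparison
    (group means + unpaired t test) for flagged features when the raw
    matrix and case labels are supplied."""
    a = model.ncomp if ncomp is None else ncomp
    v = vip(model, a)
    load = model.loadings_frame().iloc[:, :a]
    tbl = pd.DataFrame({"vip": v})
    for c in load.columns:
        tbl[f"loading_{c}"] = load[c]
    tbl["vip_ge_threshold"] = tbl["vip"] >= vip_threshold
    tbl["abs_loading_ge_threshold"] = (load.abs() >= loading_threshold).any(axis=1)
    tbl["important"] = tbl["vip_ge_threshold"] | tbl["abs_loading_ge_threshold"]

    if M is not None and labels is not None:
        lab = np.asarray(labels, dtype=bool)
        for col in ("mean_case", "mean_control", "t", "df", "p"):
            tbl[col] = np.nan
        for feat in tbl.index[tbl["important"]]:
            x = M[feat].to_numpy(dtype=float)
            case, ctrl = x[lab], x[~lab]
            case, ctrl = case[np.isfinite(case)], ctrl[np.isfinite(ctrl)]
            tbl.loc[feat, "mean_case"] = case.mean() if len(case) else np.nan
            tbl.loc[feat, "mean_control"] = ctrl.mean() if len(ctrl) else np.nan
            res = ttest_unpaired(case, ctrl, equal_var=equal_var)
            if res is not None:
                tbl.loc[feat, ["t", "df", "p"]] = res["t"], res["df"], res["p"]
    return ImportanceReport(table=tbl.sort_values("vip", ascending=False))


# ---------------------------------------------------------------------------
# leave-one-out validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationResult:
    ncomp: int
    table: pd.DataFrame  # component, PRESS, RMSEP, R2 (cumulative components)

    def r2(self, k: int) -> float:
        return float(self.table.loc[self.table["component"] == k, "r2"].iloc[0])

    def rmsep(self, k: int) -> float:
        return float(self.table.loc[self.table["component"] == k, "rmsep"].iloc[0])


def loo_validate(M, y: Sequence[float], ncomp: int, scale: bool = True) -> ValidationResult:
    """Leave-one-out validation of the PLS model.

    Each fold refits on the remaining rows (re-centering and re-scaling
    inside the fold) and predicts the held-out row with 1..ncomp
    components.  Reports PRESS, RMSEP = sqrt(PRESS/n) and
    R2 = 1 - PRESS/SS_tot per component count.
    """
    X, names, _ = _as_matrix(M)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if n < 3:
        raise ValueError("leave-one-out needs n >= 3")
    if np.ptp(yv) == 0:
        raise ValueError("y is constant")
    preds = np.full((n, ncomp), np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = fit_plsda(X[mask], yv[mask], ncomp=ncomp, scale=scale)
        for k in range(1, ncomp + 1):
            preds[i, k - 1] = pls_predict(model, X[i : i + 1], ncomp=k)[0]
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    press = np.sum((yv[:, None] - preds) ** 2, axis=0)
    rmsep = np.sqrt(press / n)
    r2 = 1.0 - press / ss_tot
    return ValidationResult(
        ncomp=ncomp,
        table=pd.DataFrame(
            {
                "component": np.arange(1, ncomp + 1),
                "press": press,
                "rmsep": rmsep,
                "r2": r2,
            }
        ),
    )


# ---------------------------------------------------------------------------
# univariate tests
# ---------------------------------------------------------------------------


def ttest_unpaired(
    x: Sequence[float], y: Sequence[float], equal_var: bool = False
) -> Optional[dict[str, float]]:
    """Unpaired two-sample t test (Welch by default; pooled via
    ``equal_var=True``).  Returns ``None`` with a warning when either
    group has fewer than 2 non-missing values."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    xa, ya = xa[np.isfinite(xa)], ya[np.isfinite(ya)]
    if len(xa) < 2 or len(ya) < 2:
        warnings.warn("t test skipped: a group has fewer than 2 values")
        return None
    with warnings.catch_warnings():
        # near-identical groups trip scipy's catastrophic-cancellation
        # warning; the resulting t ~ 0 / p ~ 1 is the correct answer here
        warnings.filterwarnings("ignore", message="Precision loss", category=RuntimeWarning)
        res = spstats.ttest_ind(xa, ya, equal_var=equal_var)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


def chisq_test(
    table: Sequence[Sequence[int]], correction: bool = False
) -> Optional[dict[str, float]]:
    """Pearson chi-square test on a 2x2 count table (no continuity
    correction by default).  Returns ``None`` with a warning on a zero
    marginal."""
    tab = np.asarray(table, dtype=float)
    if np.any(tab < 0) or not np.allclose(tab, np.round(tab)):
        raise ValueError("table must hold non-negative integer counts")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        warnings.warn("chi-square skipped: zero marginal")
        return None
    res = spstats.chi2_contingency(tab, correction=correction)
    return {"chi2": float(res.statistic), "df": float(res.dof), "p": float(res.pvalue)}
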