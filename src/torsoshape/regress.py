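"""PLS regression of torso shape PCs on traditional body measures.

Each shape PC gets its own single-response partial least squares model
(PLS1, NIPALS deflation) over the 34 z-scored body measures.  The number of
components is chosen by 10-fold cross-validation on the mean squared
prediction error (MSPE) with the one-standard-error rule; a global component
count can be forced instead.  Per-predictor importance uses the variable
importance in projection (VIP) statistic,

    VIP_j = sqrt( p * sum_a SSY_a (w_aj / ||w_a||)^2 / sum_a SSY_a )

whose squared values average to 1 by construction; predictors with
VIP >= 0.8 are conventionally treated as contributing.  Unexplained shape
variation is probed by regressing each PC's PLS residuals on the binary sex
code (females = -1, males = +1): a significant slope marks the residual
variation as sexually dimorphic rather than measure-related.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VIP_THRESHOLD_DEFAULT = 0.8
ALPHA_DEFAULT = 0.001
CV_FOLDS_DEFAULT = 10
SWEEP_FIXED_HEIGHT_CM = {1: 180.0, -1: 160.0}   # male / female models


@dataclass(frozen=True)
class PLSRModel:
    """Fitted PLS1 model for one shape PC."""

    x_names: tuple[str, ...]
    y_name: str
    n_components: int
    weights: np.ndarray        # (A, p) unit-norm NIPALS weights w_a
    x_loadings: np.ndarray     # (A, p)
    y_loadings: np.ndarray     # (A,) q_a
    ssy: np.ndarray            # (A,) response variance captured per component
    coef: np.ndarray           # (p,) regression coefficients
    intercept: float
    x_mean: np.ndarray
    y_mean: float
    r2: float
    mspe_curve: np.ndarray | None = None
    mspe_se: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coef + self.y_mean

    @property
    def vip(self) -> np.ndarray:
        return vip(self)


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """Deflation-based PLS1; returns (W, P, q, ssy)."""
    n, p = Xc.shape
    W = np.empty((n_components, p))
    P = np.empty((n_components, p))
    q = np.empty(n_components)
    ssy = np.empty(n_components)
    Xa = Xc.copy()
    for a in range(n_components):
        w = Xa.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12 * max(1.0, np.linalg.norm(yc)):
            raise ValueError(
                f"component {a + 1} exceeds the predictive rank of X")
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        if tt < 1e-24:
            raise ValueError(
                f"component {a + 1} exceeds the predictive rank of X")
        pa = Xa.T @ t / tt
        qa = float(yc @ t) / tt
        Xa = Xa - np.outer(t, pa)
        W[a], P[a], q[a] = w, pa, qa
        ssy[a] = qa * qa * tt
    return W, P, q, ssy


def _coef_from_decomposition(W: np.ndarray, P: np.ndarray,
                             q: np.ndarray) -> np.ndarray:
    A = W.shape[0]
    R = np.linalg.solve(P @ W.T, np.eye(A))   # (P' W)^-1
    return W.T @ (R @ q)


def fit_plsr(X, y, n_components: int, x_names=None,
             y_name: str = "y") -> PLSRModel:
    """Fit a PLS1 model of ``y`` on ``X`` with ``n_components`` components.

    ``X`` is expected to be the z-scored measure matrix (any centred matrix
    works; centring is applied internally either way).
    """
    if isinstance(X, pd.DataFrame):
        x_names = tuple(X.columns) if x_names is None else tuple(x_names)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if x_names is None:
        x_names = tuple(f"x{j}" for j in range(p))
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n < 2 * n_components:
        raise ValueError("need n >= 2 * n_components observations")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc, yc = X - x_mean, y - y_mean
    W, P, q, ssy = _nipals_pls1(Xc, yc, n_components)
    coef = _coef_from_decomposition(W, P, q)
    resid = yc - Xc @ coef
    tss = float(yc @ yc)
    r2 = 0.0 if tss == 0 else 1.0 - float(resid @ resid) / tss
    return PLSRModel(x_names=x_names, y_name=y_name, n_components=n_components,
                     weights=W, x_loadings=P, y_loadings=q, ssy=ssy,
                     coef=coef, intercept=y_mean - x_mean @ coef,
                     x_mean=x_mean, y_mean=y_mean, r2=r2)


def vip(model: PLSRModel) -> np.ndarray:
    """Variable importance in projection for every predictor."""
    ssy = model.ssy
    total = float(ssy.sum())
    if total <= 0.0:
        raise ValueError("model explains zero response variance; VIP undefined")
    p = len(model.x_names)
    wn = model.weights / np.linalg.norm(model.weights, axis=1, keepdims=True)
    return np.sqrt(p * (ssy @ (wn ** 2)) / total)


def _fold_assignment(n: int, folds: int, rng: np.random.Generator,
                     stratify=None) -> np.ndarray:
    """Deterministic fold labels; round-robin within shuffled strata."""
    labels = np.empty(n, dtype=int)
    if stratify is None:
        strata = [np.arange(n)]
    else:
        codes = np.asarray(stratify)
        strata = [np.flatnonzero(codes == v) for v in np.unique(codes)]
    offset = 0
    for idx in strata:
        perm = rng.permutation(idx)
        labels[perm] = (np.arange(len(perm)) + offset) % folds
        offset += len(perm)
    return labels


def select_ncomponents(X, y, max_components: int,
                       folds: int = CV_FOLDS_DEFAULT, seed: int = 0,
                       stratify=None) -> tuple[int, np.ndarray, np.ndarray]:
    """Component count by 10-fold CV on MSPE with the 1-SE rule.

    Returns ``(n_star, mspe_curve, mspe_se)`` where the curve spans
    1..max_components.  ``n_star`` is the smallest count whose MSPE lies
    within one standard error of the curve minimum.  Fold assignment is
    deterministic in ``seed``; ``folds = n`` gives leave-one-out.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if folds > n:
        raise ValueError("more folds than observations")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    labels = _fold_assignment(n, folds, rng, stratify)
    # cap at what the smallest training split (and the final full-data
    # refit) can support
    min_train = int(min((labels != f).sum() for f in range(folds)))
    max_components = max(1, min(max_components, X.shape[1],
                                min_train - 2, n // 2))
    sq_err = np.full((folds, max_components), np.nan)
    for f in range(folds):
        tr, te = labels != f, labels == f
        if te.sum() == 0:
            continue
        x_mean = X[tr].mean(axis=0)
        y_mean = y[tr].mean()
        W, P, q, _ = _nipals_pls1(X[tr] - x_mean, y[tr] - y_mean,
                                  max_components)
        Xte = X[te] - x_mean
        for a in range(1, max_components + 1):
            coef = _coef_from_decomposition(W[:a], P[:a], q[:a])
            pred = Xte @ coef + y_mean
            sq_err[f, a - 1] = float(np.mean((y[te] - pred) ** 2))
    valid = ~np.isnan(sq_err[:, 0])
    fold_mse = sq_err[valid]
    mspe = fold_mse.mean(axis=0)
    se = fold_mse.std(axis=0, ddof=1) / np.sqrt(fold_mse.shape[0])
    best = int(np.argmin(mspe))
    threshold = mspe[best] + se[best]
    n_star = int(np.argmax(mspe <= threshold)) + 1
    return n_star, mspe, se


@dataclass(frozen=True)
class SexResidualResult:
    pc_name: str
    r2: float
    p: float
    sex_related: bool


def residuals_on_sex(residuals, sex, alpha: float = ALPHA_DEFAULT,
                     pc_name: str = "PC") -> SexResidualResult:
    """Regress per-participant PLS residuals on the +/-1 sex code."""
    from scipy import stats

    residuals = np.asarray(residuals, dtype=float).ravel()
    codes = np.asarray(sex, dtype=float).ravel()
    present = set(np.unique(codes))
    if not {-1.0, 1.0} <= present:
        raise ValueError("both sexes must be present")
    if residuals.std() == 0.0:
        return SexResidualResult(pc_name=pc_name, r2=0.0, p=1.0,
                                 sex_related=False)
    res = stats.linregress(codes, residuals)
    r2 = float(res.rvalue ** 2)
    p = float(res.pvalue)
    return SexResidualResult(pc_name=pc_name, r2=r2, p=p,
                             sex_related=bool(p < alpha))


def conditional_mean_slopes(Z: pd.DataFrame, anchor: str) -> pd.Series:
    """OLS slope of every z-scored column on the z-scored anchor column."""
    za = Z[anchor].to_numpy(dtype=float)
    var = float(za @ za)
    if var <= 0:
        raise ValueError("anchor column has zero variance")
    slopes = {c: float(Z[c].to_numpy(dtype=float) @ za) / var for c in Z.columns}
    return pd.Series(slopes)


def waist_girth_sweep(models: dict[str, PLSRModel], Z: pd.DataFrame,
                      raw_waist_cm: np.ndarray, fixed_height_cm: float,
                      waist_norm_mean: float, waist_norm_sd: float,
                      waist_values_cm=None, n_points: int = 25,
                      other: str = "conditional",
                      waist_column: str = "waist_girth") -> pd.DataFrame:
    """Predicted shape-PC trajectories across the sample's waist-girth range.

    ``Z`` is the z-scored (height-normalised) measure table the models were
    fitted on, for one sex; ``raw_waist_cm`` the same participants' raw
    waist girths, which bound the sweep.  ``waist_norm_mean``/``waist_norm_sd``
    are the cohort mean and sample SD of the height-normalised waist column
    (the scaler that produced ``Z``).  For each swept raw waist value the
    height is held at ``fixed_height_cm`` (180 cm male / 160 cm female by
    convention), the waist is set, and the remaining measures are placed at
    their conditional expectation given waist (per-column OLS on waist;
    ``other="mean"`` leaves them at the grand mean, i.e. z = 0).  Every PC
    model is then evaluated, giving one affine trajectory per PC.
    """
    raw_waist_cm = np.asarray(raw_waist_cm, dtype=float)
    lo, hi = float(raw_waist_cm.min()), float(raw_waist_cm.max())
    if waist_values_cm is None:
        waist_values_cm = np.linspace(lo, hi, n_points)
    waist_values_cm = np.asarray(waist_values_cm, dtype=float)
    if waist_values_cm.min() < lo - 1e-9 or waist_values_cm.max() > hi + 1e-9:
        raise ValueError("swept waist values outside the training support")
    if other not in ("conditional", "mean"):
        raise ValueError("other must be 'conditional' or 'mean'")
    z_waist = (waist_values_cm / fixed_height_cm - waist_norm_mean) \
        / waist_norm_sd

    slopes = conditional_mean_slopes(Z, waist_column)
    cols = list(Z.columns)
    rows = np.zeros((len(z_waist), len(cols)))
    for j, c in enumerate(cols):
        if c == waist_column:
            rows[:, j] = z_waist
        elif other == "conditional":
            rows[:, j] = slopes[c] * z_waist
    out = pd.DataFrame({"waist_girth_cm": waist_values_cm})
    for name, model in models.items():
        Xrow = pd.DataFrame(rows, columns=cols)[list(model.x_names)]
        out[name] = model.predict(Xrow.to_numpy())
    return out


def variance_decomposition(r2_by_pc: dict[str, float],
                           pc_ratios: dict[str, float]) -> pd.DataFrame:
    """Split total shape variance into measure-explained and unexplained
    parts, per shape PC and overall (percent of total shape variance)."""
    if set(r2_by_pc) != set(pc_ratios):
        raise ValueError("PC sets of R2 values and variance ratios differ")
    rows = []
    for pc in pc_ratios:
        share = float(pc_ratios[pc])
        r2 = float(np.clip(r2_by_pc[pc], 0.0, 1.0))
        rows.append({"pc": pc, "share_total_pct": 100.0 * share,
                     "explained_pct": 100.0 * r2 * share,
                     "unexplained_pct": 100.0 * (1.0 - r2) * share})
    df = pd.DataFrame(rows)
    total = {"pc": "total",
             "share_total_pct": df["share_total_pct"].sum(),
             "explained_pct": df["explained_pct"].sum(),
             "unexplained_pct": df["unexplained_pct"].sum()}
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
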