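"""Single-response partial least squares regression (NIPALS), leave-one-out
cross-validation with the first-local-minimum latent-variable rule, and the
R2 / RMSECV / RPD calibration metrics.

The model decomposes mean-centred predictors X and response y into
orthogonal latent variables chosen to maximise predictor-response
covariance: per component, weight w ∝ Xᵀy (unit norm), score t = Xw,
loadings p = Xᵀt/tᵀt and q = yᵀt/tᵀt, then X and y are deflated.  With a
single response the NIPALS inner loop converges in one step, so the
algorithm is fully deterministic.  Variables are centred only — reflectance
columns share units, so no autoscaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_TOL = 1e-12


@dataclass
class PLSRModel:
    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # p x A
    x_loadings: np.ndarray   # p x A
    y_loadings: np.ndarray   # A
    scores: np.ndarray       # n x A (calibration scores)
    coefficients: np.ndarray  # p, original units
    intercept: float
    ssy: np.ndarray          # response variation explained per component

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return predict(self, X_new)


@dataclass
class CVCurve:
    """RMSECV per candidate latent-variable count (index 0 -> 1 LV)."""

    rmsecv: np.ndarray
    chosen_lv: int
    rule: str  # "first_local_min" | "global_min_fallback"
    cv_predictions: np.ndarray | None = None  # n x l_max if retained


@dataclass
class ModelReport:
    """One calibration summary row: a target component modelled from one
    spectra source, mirroring a results-table row."""

    target: str
    spectra_source: str
    sample_size: int
    n_variables: int
    n_lv: int
    r2: float
    rmsecv: float
    rpd: float
    cv_predictions: np.ndarray = field(repr=False, default=None)
    preprocessing: str = "identity"
    selector: str = "none"


def fit_plsr(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSRModel:
    """Fit a PLS1 model with ``n_lv`` latent variables by NIPALS."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError(f"y length {y.size} != sample count {n}")
    if n < 2:
        raise ValueError("need at least two samples")
    if not 1 <= n_lv <= min(n - 1, p):
        raise ValueError(f"n_lv={n_lv} outside [1, min(n-1, p)={min(n - 1, p)}]")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    y_scale = float(np.sqrt(yc @ yc))
    if y_scale < _TOL:
        raise ValueError("zero-variance response")
    x_scale = max(float(np.abs(Xc).max()), 1.0)

    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    q = np.empty(n_lv)
    T = np.empty((n, n_lv))
    ssy = np.empty(n_lv)
    for a in range(n_lv):
        w = Xc.T @ yc
        wn = float(np.linalg.norm(w))
        if wn < _TOL * x_scale * y_scale:
            raise ValueError(
                f"n_lv={n_lv} exceeds the extractable components (deflated X "
                f"carries no covariance with y after {a})"
            )
        w /= wn
        t = Xc @ w
        tt = float(t @ t)
        if tt < _TOL:
            raise ValueError(f"degenerate score at component {a + 1}")
        p_a = Xc.T @ t / tt
        q_a = float(yc @ t) / tt
        Xc -= np.outer(t, p_a)
        yc = yc - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
        ssy[a] = q_a**2 * tt
    coefficients = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ coefficients)
    return PLSRModel(
        n_lv=n_lv,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coefficients=coefficients,
        intercept=intercept,
        ssy=ssy,
    )


def predict(model: PLSRModel, X_new: np.ndarray) -> np.ndarray:
    """ŷ = (X_new - x_mean) · b + y_mean."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.x_mean.size}"
        )
    return (X_new - model.x_mean) @ model.coefficients + model.y_mean


def _coefficients_per_lv(model: PLSRModel) -> np.ndarray:
    """Coefficient vectors for every truncation 1..n_lv of a fitted model
    (NIPALS components are extracted sequentially, so truncation equals a
    smaller fit).  Returns p x n_lv."""
    p, A = model.weights.shape
    out = np.empty((p, A))
    PtW = model.x_loadings.T @ model.weights
    for k in range(1, A + 1):
        out[:, k - 1] = model.weights[:, :k] @ np.linalg.solve(
            PtW[:k, :k], model.y_loadings[:k]
        )
    return out


def loocv_predictions(X: np.ndarray, y: np.ndarray, l_max: int) -> np.ndarray:
    """Held-out prediction of every sample at every LV count 1..l_max.

    Each sample is predicted by a model fit on the other n-1 samples;
    returns an n x l_max matrix.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least three samples")
    if l_max > min(n - 2, X.shape[1]):
        raise ValueError(
            f"l_max={l_max} too large for n={n}, p={X.shape[1]}"
        )
    preds = np.empty((n, l_max))
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = fit_plsr(X[mask], y[mask], l_max)
        B = _coefficients_per_lv(model)  # p x l_max
        preds[i] = (X[i] - model.x_mean) @ B + model.y_mean
        mask[i] = True
    return preds


def first_local_minimum(rmsecv: np.ndarray) -> tuple[int, str]:
    """The first-local-minimum LV rule on an RMSECV sequence.

    ``rmsecv[k-1]`` is the error at k latent variables.  The chosen count is
    the smallest k with rmsecv[k] < rmsecv[k-1] and rmsecv[k] <= rmsecv[k+1];
    k=1 qualifies if rmsecv[1] <= rmsecv[2].  Without any local minimum
    (e.g. a strictly decreasing curve) the global minimum is used and the
    fallback is recorded.
    """
    r = np.asarray(rmsecv, dtype=float)
    L = r.size
    if L == 0:
        raise ValueError("empty RMSECV sequence")
    if L == 1:
        return 1, "first_local_min"
    if r[0] <= r[1]:
        return 1, "first_local_min"
    for k in range(1, L - 1):  # interior candidates, 0-based
        if r[k] < r[k - 1] and r[k] <= r[k + 1]:
            return k + 1, "first_local_min"
    return int(np.argmin(r)) + 1, "global_min_fallback"


def loocv_curve(
    X: np.ndarray, y: np.ndarray, l_max: int, keep_predictions: bool = True
) -> CVCurve:
    """RMSECV over LV counts 1..l_max with the first-local-minimum rule."""
    preds = loocv_predictions(X, y, l_max)
    y = np.asarray(y, dtype=float).ravel()
    rmsecv = np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))
    chosen, rule = first_local_minimum(rmsecv)
    return CVCurve(
        rmsecv=rmsecv,
        chosen_lv=chosen,
        rule=rule,
        cv_predictions=preds if keep_predictions else None,
    )


def metrics(y: np.ndarray, y_cv: np.ndarray) -> tuple[float, float, float]:
    """(R2, RMSE, RPD) of cross-validated predictions.

    R2 = 1 - SSE/SST (may be negative for CV predictions); RMSE uses
    divisor n; RPD = sd(y; n-1 denominator) / RMSE and is undefined
    (raises) when RMSE is exactly zero.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_cv = np.asarray(y_cv, dtype=float).ravel()
    if y.shape != y_cv.shape:
        raise ValueError("y and y_cv must have equal length")
    n = y.size
    if n < 2:
        raise ValueError("need at least two samples")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero variance in y")
    sse = float(np.sum((y - y_cv) ** 2))
    r2 = 1.0 - sse / sst
    rmse = float(np.sqrt(sse / n))
    if rmse == 0:
        raise ZeroDivisionError("RMSE is zero: RPD undefined for a perfect fit")
    rpd = float(np.std(y, ddof=1)) / rmse
    return r2, rmse, rpd


def evaluate_model(
    X: np.ndarray,
    y: np.ndarray,
    l_max: int,
    target: str = "",
    spectra_source: str = "",
    preprocessing: str = "identity",
    selector: str = "none",
) -> ModelReport:
    """Full calibration protocol for one (target, predictor-matrix) pair:
    LOOCV curve -> first-local-minimum LV choice -> metrics at that LV."""
    X = np.asarray(X, dtype=float)
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    l_max = int(min(l_max, X.shape[0] - 2, X.shape[1], rank))
    curve = loocv_curve(X, y, l_max)
    y_cv = curve.cv_predictions[:, curve.chosen_lv - 1]
    r2, rmsecv, rpd = metrics(y, y_cv)
    return ModelReport(
        target=target,
        spectra_source=spectra_source,
        sample_size=X.shape[0],
        n_variables=X.shape[1],
        n_lv=curve.chosen_lv,
        r2=r2,
        rmsecv=rmsecv,
        rpd=rpd,
        cv_predictions=y_cv,
        preprocessing=preprocessing,
        selector=selector,
    )
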