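"""Wavelength (variable) selection: VIP scoring, the Successive Projections
Algorithm (SPA) and Competitive Adaptive Reweighted Sampling (CARS), all
returning a common :class:`SelectionResult`.

VIP ranks variables by their contribution to the response variation the PLS
components explain; SPA builds minimally collinear forward chains by
projecting candidate columns onto the orthogonal complement of the chosen
span; CARS shrinks the variable set down an exponentially decreasing
schedule while resampling variables in proportion to their PLS coefficient
magnitudes.  "No selection" is a legal outcome of the surrounding grid
search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plsr import fit_plsr, loocv_curve

_TOL = 1e-12


@dataclass
class SelectionResult:
    method: str                     # "VIP" | "SPA" | "CARS" | "none"
    selected_indices: np.ndarray    # unique, sorted
    scores: np.ndarray              # per-variable importance, length p
    rmsecv_of_subset: float
    seed: int | None = None
    n_lv: int | None = None

    def __post_init__(self) -> None:
        idx = np.asarray(self.selected_indices, dtype=int)
        if self.method != "none":
            if idx.size == 0:
                raise ValueError("selection returned no variables")
            if np.unique(idx).size != idx.size:
                raise ValueError("selected indices must be unique")
        self.selected_indices = np.sort(idx)


def _subset_rmsecv(
    X: np.ndarray, y: np.ndarray, idx: np.ndarray, l_max: int = 10
) -> float:
    """LOOCV RMSECV of a PLSR fit on the given column subset, at the LV
    count the first-local-minimum rule picks."""
    Xs = X[:, idx]
    l_max = int(min(l_max, Xs.shape[0] - 2, Xs.shape[1]))
    curve = loocv_curve(Xs, y, l_max, keep_predictions=False)
    return float(curve.rmsecv[curve.chosen_lv - 1])


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

def vip_scores(X: np.ndarray, y: np.ndarray, n_lv: int) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * Σ_a SSY_a (w_ja / ||w_a||)² / Σ_a SSY_a ) where SSY_a
    is the response variation explained by component a and w_a its weight
    vector.  The squared scores always average to 1 (Σ VIP² = p).
    """
    model = fit_plsr(X, y, n_lv)
    p = X.shape[1]
    W = model.weights
    wnorm2 = np.sum(W**2, axis=0)
    ssy = model.ssy
    total = float(ssy.sum())
    if total <= 0:
        raise ValueError("zero explained response variance")
    return np.sqrt(p * (W**2 / wnorm2) @ ssy / total)


def vip_select(
    X: np.ndarray,
    y: np.ndarray,
    n_lv: int,
    threshold: float = 1.0,
    l_max: int = 10,
) -> SelectionResult:
    """Keep variables with VIP above ``threshold`` (default 1.0)."""
    scores = vip_scores(X, y, n_lv)
    idx = np.flatnonzero(scores > threshold)
    if idx.size == 0:  # pathological threshold; fall back to the top scorer
        idx = np.array([int(np.argmax(scores))])
    return SelectionResult(
        method="VIP",
        selected_indices=idx,
        scores=scores,
        rmsecv_of_subset=_subset_rmsecv(X, y, idx, l_max),
        n_lv=n_lv,
    )


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

def _spa_chain(X: np.ndarray, start: int, max_vars: int) -> list[int]:
    """Forward projection chain: repeatedly pick the column with the largest
    norm of its projection onto the orthogonal complement of the span of the
    already-picked columns."""
    n, p = X.shape
    Xp = X.astype(float).copy()
    scale = float(np.linalg.norm(X, axis=0).max())
    chain = [start]
    for _ in range(max_vars - 1):
        v = Xp[:, chain[-1]]
        vv = float(v @ v)
        if vv < (_TOL * scale) ** 2:
            break
        Xp = Xp - np.outer(v, v @ Xp) / vv
        norms = np.linalg.norm(Xp, axis=0)
        norms[chain] = -1.0
        j = int(np.argmax(norms))
        if norms[j] < _TOL * scale:
            break  # remaining columns are in the selected span
        chain.append(j)
    return chain


def _ols_press_rmsecv(X: np.ndarray, y: np.ndarray) -> float:
    """Exact LOOCV RMSE of ordinary least squares with intercept, via the
    PRESS identity e_i / (1 - h_ii)."""
    n = X.shape[0]
    A = np.column_stack([np.ones(n), X])
    # pseudo-inverse handles the (excluded upstream) rank-deficient case
    pinv = np.linalg.pinv(A)
    H = A @ pinv
    resid = y - H @ y
    lever = np.clip(np.diag(H), None, 1 - 1e-12)
    press = resid / (1 - lever)
    return float(np.sqrt(np.mean(press**2)))


def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    max_vars: int,
    start: int | str = "scan",
) -> SelectionResult:
    """Successive projections algorithm.

    Candidate chain lengths 1..max_vars are compared by the LOOCV RMSE of a
    least-squares fit on the subset; ``start="scan"`` tries every start
    column and keeps the best chain (ties break toward fewer variables,
    then the lower start index).  Deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p == 0:
        raise ValueError("X has no columns")
    if not 1 <= max_vars <= min(n - 1, p):
        raise ValueError(f"max_vars={max_vars} outside [1, min(n-1, p)]")
    col_norms = np.linalg.norm(X - X.mean(axis=0), axis=0)
    if start == "scan":
        starts = [j for j in range(p) if col_norms[j] > _TOL]
        if not starts:
            raise ValueError("all columns are constant")
    else:
        starts = [int(start)]

    best: tuple[float, int, list[int]] | None = None  # (rmsecv, size, subset)
    best_chain: list[int] | None = None
    for s in starts:
        chain = _spa_chain(X, s, max_vars)
        for m in range(1, len(chain) + 1):
            subset = chain[:m]
            rms = _ols_press_rmsecv(X[:, subset], y)
            key = (rms, m, subset)
            if best is None or key[:2] < best[:2]:
                best = key
                best_chain = chain
    rms, m, subset = best
    scores = np.zeros(p)
    for rank, j in enumerate(best_chain, start=1):
        scores[j] = rank
    return SelectionResult(
        method="SPA",
        selected_indices=np.array(subset, dtype=int),
        scores=scores,
        rmsecv_of_subset=rms,
    )


# ---------------------------------------------------------------------------
# CARS
# ---------------------------------------------------------------------------

def cars_schedule(p: int, n_runs: int) -> np.ndarray:
    """Retained-variable counts per run: an exponentially decreasing
    schedule r_i = a e^{-k i} calibrated so run 1 keeps all p variables and
    run ``n_runs`` keeps exactly 2."""
    if p < 2:
        raise ValueError("schedule degenerate: need p >= 2")
    if n_runs < 2:
        raise ValueError("need at least two runs")
    k = np.log(p / 2) / (n_runs - 1)
    a = np.exp(k)
    runs = np.arange(1, n_runs + 1)
    counts = np.rint(p * a * np.exp(-k * runs)).astype(int)
    return np.clip(counts, 2, p)


def kfold_rmsecv(
    X: np.ndarray, y: np.ndarray, n_lv: int, n_folds: int, seed: int
) -> float:
    """K-fold CV RMSE of a PLSR fit, with a seed-determined fold shuffle."""
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    preds = np.empty(n)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        lv = int(min(n_lv, mask.sum() - 1, X.shape[1]))
        model = fit_plsr(X[mask], y[mask], lv)
        preds[fold] = model.predict(X[fold])
    return float(np.sqrt(np.mean((preds - y) ** 2)))


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    n_runs: int = 50,
    seed: int | None = None,
    subsample: float = 0.8,
    n_folds: int = 5,
    max_lv: int = 10,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    Per Monte-Carlo run: fit PLSR on a random 80% calibration subsample of
    the currently retained variables; shrink the retained set to the
    exponentially-decreasing-schedule count by weighted sampling without
    replacement with weights ∝ |PLS regression coefficient|; score the
    run's subset by k-fold RMSECV.  Returns the run subset with minimal
    RMSECV.  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 10:
        raise ValueError("CARS needs at least 10 samples")
    if n_runs < 10:
        raise ValueError("CARS needs at least 10 Monte-Carlo runs")
    counts = cars_schedule(p, n_runs)
    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(2**31))
    n_cal = max(4, int(round(subsample * n)))

    retained = np.arange(p)
    frequency = np.zeros(p)
    best_rms = np.inf
    best_subset = retained
    for i in range(n_runs):
        cal = rng.choice(n, size=n_cal, replace=False)
        lv = int(min(max_lv, n_cal - 2, retained.size))
        model = fit_plsr(X[np.ix_(cal, retained)], y[cal], lv)
        weights = np.abs(model.coefficients)
        target = min(counts[i], retained.size)
        if weights.sum() <= 0 or np.count_nonzero(weights) < target:
            keep = np.argsort(-weights)[:target]  # degenerate weights
        else:
            keep = rng.choice(
                retained.size, size=target, replace=False, p=weights / weights.sum()
            )
        retained = np.sort(retained[keep])
        frequency[retained] += 1
        lv_cv = int(min(max_lv, n - n // n_folds - 2, retained.size))
        rms = kfold_rmsecv(X[:, retained], y, lv_cv, n_folds, fold_seed)
        if rms < best_rms:
            best_rms = rms
            best_subset = retained.copy()
    return SelectionResult(
        method="CARS",
        selected_indices=best_subset,
        scores=frequency,
        rmsecv_of_subset=best_rms,
        seed=fold_seed,
    )


def no_selection(X: np.ndarray, y: np.ndarray, l_max: int = 10) -> SelectionResult:
    """The full spectrum, scored by the same LOOCV protocol — a legal
    outcome of the selector comparison."""
    idx = np.arange(X.shape[1])
    return SelectionResult(
        method="none",
        selected_indices=idx,
        scores=np.ones(X.shape[1]),
        rmsecv_of_subset=_subset_rmsecv(X, y, idx, l_max),
    )
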