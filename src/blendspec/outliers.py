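"""Robust outlier screening: PCA reduction to a low-dimensional score plane
followed by FAST-MCD (minimum covariance determinant) estimation, robust
Mahalanobis distances and a chi-square tolerance-ellipse cutoff.

MCD finds the h-subset (h = ⌊0.75 n⌋) whose covariance matrix has minimal
determinant — the most tightly clustered core of the data — and measures
every sample's distance to that core.  Samples outside the 97.5% tolerance
ellipse (chi-square quantile, 2 df) are flagged and excluded from the
quantitative stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .blocks import SpectraBlock

_DET_TOL = 1e-300


@dataclass
class PCAResult:
    """Mean-centred (unscaled) principal decomposition."""

    scores: np.ndarray          # n x k
    loadings: np.ndarray        # p x k, orthonormal
    explained_ratio: np.ndarray  # per-component fraction of total variance
    center: np.ndarray          # mean spectrum


@dataclass
class MCDResult:
    """Raw h-subset MCD estimates (no consistency scaling applied)."""

    location: np.ndarray
    scatter: np.ndarray       # covariance of the support subset (ddof=1)
    support: np.ndarray       # boolean, h True entries
    determinant: float
    h: int
    det_history: list[float]  # per C-step determinants of the winning start


@dataclass
class OutlierReport:
    sample_ids: list[str]
    scores: np.ndarray          # n x 2 PC scores
    mcd_location: np.ndarray
    mcd_scatter: np.ndarray     # consistency-scaled 2x2 covariance
    h: int
    robust_distance: np.ndarray
    cutoff: float
    flagged: np.ndarray         # boolean
    kept_ids: list[str]
    seed: int | None
    quantile: float

    def summary(self) -> dict:
        return {
            "n": len(self.sample_ids),
            "h": self.h,
            "cutoff": self.cutoff,
            "quantile": self.quantile,
            "n_flagged": int(self.flagged.sum()),
            "seed": self.seed,
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "pc1": self.scores[:, 0],
                "pc2": self.scores[:, 1],
                "distance": self.robust_distance,
                "flagged": self.flagged,
            }
        )


def pca_fit(block: SpectraBlock | np.ndarray, k: int) -> PCAResult:
    """Principal component analysis of mean-centred spectra (no variance
    scaling), via singular value decomposition."""
    X = block.values if isinstance(block, SpectraBlock) else np.asarray(block, float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least two samples")
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} outside [1, min(n-1, p)={min(n - 1, p)}]")
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise ValueError("zero-variance data")
    # deterministic sign: largest-magnitude loading entry positive
    for j in range(min(n, p)):
        lead = Vt[j, np.argmax(np.abs(Vt[j]))]
        if lead < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U[:, :k] * s[:k]
    return PCAResult(
        scores=scores,
        loadings=Vt[:k].T,
        explained_ratio=s[:k] ** 2 / total,
        center=center,
    )


def _subset_stats(X: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sub = X[idx]
    center = sub.mean(axis=0)
    diff = sub - center
    cov = diff.T @ diff / (len(idx) - 1)
    return center, cov


def _mahalanobis_sq(X: np.ndarray, center: np.ndarray, cov: np.ndarray) -> np.ndarray:
    diff = X - center
    sol = np.linalg.solve(cov, diff.T)
    return np.einsum("ij,ji->i", diff, sol)


def fast_mcd(
    scores: np.ndarray,
    h_fraction: float = 0.75,
    seed: int | None = None,
    n_starts: int = 500,
    n_best: int = 10,
    max_csteps: int = 100,
) -> MCDResult:
    """FAST-MCD: random elemental starts + concentration steps.

    Phase 1 draws ``n_starts`` elemental subsets of size d+1, runs two
    batched C-steps each; phase 2 iterates the ``n_best`` candidates with
    the smallest determinants to convergence.  Each C-step provably never
    increases the covariance determinant (asserted per iteration).  Returns
    the raw h-subset mean and covariance; no consistency scaling is applied
    here (see :func:`flag_outliers`).
    """
    X = np.asarray(scores, dtype=float)
    n, d = X.shape
    h = int(np.floor(h_fraction * n))
    if n < 4 or h < 3:
        raise ValueError(f"need n >= 4 and h >= 3, got n={n}, h={h}")
    if h > n:
        raise ValueError("h cannot exceed n")
    rng = np.random.default_rng(seed)

    scale = float(np.abs(X - X.mean(axis=0)).max()) or 1.0
    det_floor = (1e-12 * scale**2) ** d

    def c_step(idx: np.ndarray) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
        center, cov = _subset_stats(X, idx)
        det = float(np.linalg.det(cov))
        if not np.isfinite(det) or det <= det_floor:
            raise np.linalg.LinAlgError
        d2 = _mahalanobis_sq(X, center, cov)
        new_idx = np.sort(np.argpartition(d2, h - 1)[:h])
        return new_idx, det, center, cov

    # phase 1: elemental starts, two C-steps each
    candidates: list[tuple[float, np.ndarray]] = []
    for _ in range(n_starts):
        idx = rng.choice(n, size=d + 1, replace=False)
        try:
            center, cov = _subset_stats(X, idx)
            if float(np.linalg.det(cov)) <= det_floor:
                continue  # collinear elemental draw
            d2 = _mahalanobis_sq(X, center, cov)
            idx = np.sort(np.argpartition(d2, h - 1)[:h])
            for _ in range(2):
                idx, det, _, _ = c_step(idx)
            candidates.append((det, idx))
        except np.linalg.LinAlgError:
            continue
    if not candidates:
        raise ValueError("degenerate geometry: all candidate covariances singular")
    candidates.sort(key=lambda c: c[0])

    best: tuple[float, np.ndarray, np.ndarray, np.ndarray, list[float]] | None = None
    for det0, idx in candidates[:n_best]:
        history = [det0]
        prev_det = det0
        prev_idx = idx
        for _ in range(max_csteps):
            try:
                new_idx, det, center, cov = c_step(prev_idx)
            except np.linalg.LinAlgError:
                raise ValueError(
                    "degenerate geometry: singular candidate covariance"
                ) from None
            # C-step monotonicity is a theorem; violating it means a bug
            if det > prev_det * (1 + 1e-9):
                raise AssertionError("C-step increased the determinant")
            history.append(det)
            if np.array_equal(new_idx, prev_idx) or np.isclose(det, prev_det):
                prev_idx, prev_det = new_idx, det
                break
            prev_idx, prev_det = new_idx, det
        center, cov = _subset_stats(X, prev_idx)
        det = float(np.linalg.det(cov))
        if best is None or det < best[0]:
            best = (det, prev_idx, center, cov, history)

    det, idx, center, cov, history = best
    support = np.zeros(n, dtype=bool)
    support[idx] = True
    return MCDResult(
        location=center,
        scatter=cov,
        support=support,
        determinant=det,
        h=h,
        det_history=history,
    )


def robust_distances(
    scores: np.ndarray, center: np.ndarray, covariance: np.ndarray
) -> np.ndarray:
    """d_i = sqrt((s_i - center)^T Σ^{-1} (s_i - center))."""
    cov = np.asarray(covariance, dtype=float)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError("covariance is not positive definite") from None
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    return np.sqrt(_mahalanobis_sq(X, np.asarray(center, float), cov))


def consistency_factor(d2_raw: np.ndarray, dof: int) -> float:
    """Distance-median consistency scaling for the raw MCD scatter.

    The h-subset covariance systematically underestimates the scatter of
    the clean distribution; rescaling by median(d²)/χ²₀.₅(dof) makes the
    robust distances of clean Gaussian data follow their nominal
    chi-square law, so the tolerance-ellipse cutoff holds its level.
    """
    return float(np.median(d2_raw) / chi2.ppf(0.5, dof))


def chi_square_cutoff(quantile: float, dof: int = 2) -> float:
    """Tolerance-ellipse radius: sqrt of the chi-square quantile."""
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    return float(np.sqrt(chi2.ppf(quantile, dof)))


def flag_outliers(
    block: SpectraBlock,
    quantile: float = 0.975,
    seed: int | None = None,
    n_components: int = 2,
    h_fraction: float = 0.75,
    n_starts: int = 500,
) -> tuple[SpectraBlock, OutlierReport]:
    """Full screen: PCA(k=2) -> FAST-MCD -> robust distances -> cutoff.

    Samples with distance strictly above the chi-square tolerance radius
    are flagged; ties at the cutoff are kept.  Returns the kept sub-block
    and the full report.
    """
    if block.n_samples < 8:
        raise ValueError("outlier screening needs at least 8 samples")
    pca = pca_fit(block, n_components)
    mcd = fast_mcd(pca.scores, h_fraction=h_fraction, seed=seed, n_starts=n_starts)
    d_raw = robust_distances(pca.scores, mcd.location, mcd.scatter)
    c = consistency_factor(d_raw**2, n_components)
    scatter = mcd.scatter * c
    distances = d_raw / np.sqrt(c)
    cutoff = chi_square_cutoff(quantile, n_components)
    flagged = distances > cutoff
    kept = block.select_samples(~flagged)
    report = OutlierReport(
        sample_ids=list(block.sample_ids),
        scores=pca.scores,
        mcd_location=mcd.location,
        mcd_scatter=scatter,
        h=mcd.h,
        robust_distance=distances,
        cutoff=cutoff,
        flagged=flagged,
        kept_ids=list(kept.sample_ids),
        seed=seed,
        quantile=quantile,
    )
    return kept, report
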