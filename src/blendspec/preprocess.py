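"""Spectral preprocessing operators: moving average, Savitzky-Golay
smoothing/derivatives, SNV and MSC, plus ordered chaining of them.

All operators are row-local (one spectrum at a time) and return a new
block of the same shape.  Scatter corrections (SNV, MSC) remove the
per-spectrum affine distortions introduced by particle-size and optical
path variation; derivatives separate overlapping absorption features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .blocks import SpectraBlock

_SCATTER_STEPS = {"snv", "msc"}


@dataclass
class PreprocessPlan:
    """An ordered list of preprocessing steps.

    Each step is a ``(name, params)`` pair; legal names are ``moving_average``
    (``window``), ``savitzky_golay`` (``window``, ``polyorder``, ``deriv``),
    ``snv`` and ``msc`` (``reference`` = "mean" or an explicit spectrum).
    An empty plan is the identity ("no preprocessing"), a legal and at times
    winning choice.
    """

    steps: list[tuple[str, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        scatter = 0
        for name, params in self.steps:
            if name in ("moving_average", "savitzky_golay"):
                window = int(params.get("window", 0))
                if window != 1 and (window < 3 or window % 2 == 0):
                    raise ValueError(
                        f"{name}: window must be odd and >= 3 (or 1), got {window}"
                    )
                if name == "savitzky_golay":
                    polyorder = int(params.get("polyorder", 2))
                    deriv = int(params.get("deriv", 0))
                    if polyorder >= window:
                        raise ValueError("savitzky_golay: polyorder must be < window")
                    if deriv > polyorder:
                        raise ValueError("savitzky_golay: deriv must be <= polyorder")
            elif name in _SCATTER_STEPS:
                scatter += 1
            else:
                raise ValueError(f"unknown preprocessing step {name!r}")
        if scatter > 1:
            raise ValueError("at most one scatter-correction step (SNV or MSC)")

    @classmethod
    def from_specs(cls, specs: Iterable[dict]) -> "PreprocessPlan":
        """Build from config-style dicts, e.g. ``[{"name": "snv"}]``."""
        steps = []
        for spec in specs:
            spec = dict(spec)
            steps.append((spec.pop("name"), spec))
        return cls(steps)

    def describe(self) -> str:
        if not self.steps:
            return "identity"
        parts = []
        for name, params in self.steps:
            args = ",".join(f"{k}={v}" for k, v in params.items() if k != "reference")
            parts.append(f"{name}({args})" if args else name)
        return "+".join(parts)


def moving_average(block: SpectraBlock, window: int) -> SpectraBlock:
    """Uniform-kernel smoothing; the window shrinks symmetrically at edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd count, got {window}")
    if window > block.n_wavelengths:
        raise ValueError("window exceeds the number of wavelengths")
    if window == 1:
        return block.with_values(block.values.copy())
    kernel = np.ones(window)
    # same-mode convolution of values and of a ones-row: dividing the two
    # is exactly a symmetric shrinking window at the edges.
    counts = np.convolve(np.ones(block.n_wavelengths), kernel, mode="same")
    smoothed = np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="same"), 1, block.values
    )
    return block.with_values(smoothed / counts)


def savitzky_golay(
    block: SpectraBlock, window: int, polyorder: int, deriv: int = 0
) -> SpectraBlock:
    """Per-row local least-squares polynomial smoothing or differentiation.

    Derivatives are scaled by the wavelength step so the output is in
    reflectance per nm; they therefore require a uniform wavelength grid.
    Edges use polynomial extrapolation from the first/last full window.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if deriv > polyorder:
        raise ValueError("deriv must be <= polyorder")
    if window > block.n_wavelengths:
        raise ValueError("window exceeds the number of wavelengths")
    steps = np.diff(block.wavelengths)
    delta = float(np.median(steps))
    if deriv > 0 and not np.allclose(steps, delta, rtol=1e-6, atol=0):
        raise ValueError(
            "derivative scaling is undefined on a non-uniform wavelength grid"
        )
    out = savgol_filter(
        block.values,
        window_length=window,
        polyorder=polyorder,
        deriv=deriv,
        delta=delta,
        axis=1,
        mode="interp",
    )
    return block.with_values(out)


def snv(block: SpectraBlock) -> SpectraBlock:
    """Standard normal variate: centre each row to mean 0, scale to sd 1
    (n-1 denominator).  Constant rows are an error (zero spread)."""
    means = block.values.mean(axis=1, keepdims=True)
    sds = block.values.std(axis=1, ddof=1, keepdims=True)
    # tolerance absorbs the rounding of a numerically-constant row's mean
    tol = 1e-12 * np.maximum(1.0, np.abs(means.ravel()))
    flat = np.flatnonzero(sds.ravel() <= tol)
    if flat.size:
        raise ValueError(
            f"SNV undefined for constant spectrum of sample "
            f"{block.sample_ids[flat[0]]!r}"
        )
    return block.with_values((block.values - means) / sds)


def msc_fit(
    block: SpectraBlock, reference: np.ndarray | str = "mean"
) -> np.ndarray:
    """Resolve the MSC reference spectrum (default: column-wise mean of the
    calibration block).  Store and reuse it on prediction data — never
    recompute there."""
    if isinstance(reference, str):
        if reference != "mean":
            raise ValueError(f"unknown MSC reference policy {reference!r}")
        reference = block.values.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (block.n_wavelengths,):
        raise ValueError("MSC reference length must match the wavelength count")
    if np.ptp(reference) == 0:
        raise ValueError("MSC reference must not be constant")
    return reference


def msc(
    block: SpectraBlock, reference: np.ndarray | str = "mean"
) -> SpectraBlock:
    """Multiplicative scatter correction.

    Each spectrum x_i is regressed on the reference, x_i ~ a_i + b_i * ref,
    by ordinary least squares; the corrected spectrum is (x_i - a_i)/b_i.
    """
    ref = msc_fit(block, reference)
    refc = ref - ref.mean()
    denom = refc @ refc
    xc = block.values - block.values.mean(axis=1, keepdims=True)
    b = xc @ refc / denom
    degenerate = np.flatnonzero(np.abs(b) < 1e-12)
    if degenerate.size:
        raise ValueError(
            f"MSC slope ~ 0 for sample {block.sample_ids[degenerate[0]]!r}: "
            "degenerate spectrum"
        )
    a = block.values.mean(axis=1) - b * ref.mean()
    corrected = (block.values - a[:, None]) / b[:, None]
    return block.with_values(corrected)


_OPERATORS = {
    "moving_average": moving_average,
    "savitzky_golay": savitzky_golay,
    "snv": lambda block: snv(block),
    "msc": msc,
}


def apply_plan(block: SpectraBlock, plan: PreprocessPlan) -> SpectraBlock:
    """Apply the plan's operators strictly in listed order."""
    out = block
    for name, params in plan.steps:
        if name == "moving_average":
            out = moving_average(out, int(params["window"]))
        elif name == "savitzky_golay":
            out = savitzky_golay(
                out,
                int(params["window"]),
                int(params.get("polyorder", 2)),
                int(params.get("deriv", 0)),
            )
        elif name == "snv":
            out = snv(out)
        elif name == "msc":
            out = msc(out, params.get("reference", "mean"))
        else:  # pragma: no cover - PreprocessPlan validates names
            raise ValueError(f"unknown step {name!r}")
    return out


def fit_plan(block: SpectraBlock, plan: PreprocessPlan) -> PreprocessPlan:
    """Freeze data-dependent state (the MSC reference) on a calibration
    block, returning a plan safe to reuse on new samples without leakage."""
    frozen: list[tuple[str, dict]] = []
    current = block
    for name, params in plan.steps:
        if name == "msc":
            ref = msc_fit(current, params.get("reference", "mean"))
            params = {**params, "reference": ref}
        frozen.append((name, dict(params)))
        current = apply_plan(current, PreprocessPlan([(name, dict(params))]))
    return PreprocessPlan(frozen)
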