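"""Synthetic dual-range blend spectra: endmember generation, constrained
blend designs, linear mixing with instrument-style noise, and gross-outlier
injection.

The generator emulates the study structure of a four-component cut-tobacco
blending experiment scanned by two push-broom imagers: 30 blend recipes x 3
replicate scans = 90 samples; a dominant component constrained to 60-100%
and three minor components to 0-20% each, summing to exactly 100%; one
Vis-NIR block (400 wavelengths over 460-1020 nm) and one NIR block (220
wavelengths over 975-1713 nm).  Mixture spectra follow a linear mixing law
(proportion-weighted endmember sum) distorted by per-spectrum multiplicative
scatter, smooth baseline drift, replicate jitter and additive noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocks import NIR, VISNIR, SpectraBlock

COMPONENTS = (
    "tobacco_silk",
    "cut_stem",
    "fermented_cut_stem",
    "expanded_tobacco_silk",
)

#: Per-component allowed proportion intervals (fractions).
DEFAULT_RANGES = ((0.60, 1.00), (0.0, 0.20), (0.0, 0.20), (0.0, 0.20))

DEFAULT_VIS_GRID = np.linspace(460.0, 1020.0, 400)
DEFAULT_NIR_GRID = np.linspace(975.0, 1713.0, 220)


@dataclass
class NoiseModel:
    """Per-spectrum distortion amplitudes, all in reflectance units.

    additive_sd: iid channel noise; scatter_slope_sd / scatter_offset_sd:
    multiplicative and offset scatter per spectrum; baseline_amplitude:
    smooth quadratic drift; replicate_jitter_sd: between-scan offset shared
    across both instrument ranges.
    """

    additive_sd: float = 0.005
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.01
    baseline_amplitude: float = 0.01
    replicate_jitter_sd: float = 0.003

    def __post_init__(self) -> None:
        for name in (
            "additive_sd",
            "scatter_slope_sd",
            "scatter_offset_sd",
            "baseline_amplitude",
            "replicate_jitter_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def none(cls) -> "NoiseModel":
        """Noise-free: mixing becomes exactly linear."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class EndmemberSet:
    """Pure-component reflectance per instrument range."""

    vis: np.ndarray            # 4 x 400
    nir: np.ndarray            # 4 x 220
    vis_grid: np.ndarray
    nir_grid: np.ndarray
    component_names: tuple[str, ...] = COMPONENTS
    band_params: dict = field(default_factory=dict)

    def min_pairwise_separation(self) -> float:
        """Smallest mean absolute difference between any two components,
        over both ranges concatenated — the identifiability margin."""
        full = np.concatenate([self.vis, self.nir], axis=1)
        k = full.shape[0]
        sep = np.inf
        for i in range(k):
            for j in range(i + 1, k):
                sep = min(sep, float(np.mean(np.abs(full[i] - full[j]))))
        return sep


@dataclass
class BlendDesign:
    """Per-sample component proportions with replicate structure."""

    proportions: np.ndarray   # n x 4 fractions, rows sum to 1
    recipe_ids: list[int]
    replicates: list[int]     # scan index 1..n_replicates
    ranges: tuple = DEFAULT_RANGES

    def __post_init__(self) -> None:
        P = np.asarray(self.proportions, dtype=float)
        if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("design rows must sum to 1")
        for c, (lo, hi) in enumerate(self.ranges):
            if np.any(P[:, c] < lo - 1e-12) or np.any(P[:, c] > hi + 1e-12):
                raise ValueError(f"component {c} outside [{lo}, {hi}]")
        self.proportions = P

    @property
    def n_samples(self) -> int:
        return self.proportions.shape[0]

    def sample_ids(self) -> list[str]:
        return [
            f"R{r:02d}_S{s}" for r, s in zip(self.recipe_ids, self.replicates)
        ]

    def to_frame(self):
        import pandas as pd

        frame = pd.DataFrame(self.proportions, columns=list(COMPONENTS))
        frame.insert(0, "sample_id", self.sample_ids())
        frame.insert(1, "recipe", self.recipe_ids)
        frame.insert(2, "replicate", self.replicates)
        return frame


def _gauss(grid: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / width) ** 2)


# Component absorption-band layouts: (center nm, width nm, depth); positive
# depth subtracts (absorption), negative adds (reflectance peak).  The
# dominant component carries the deep 650-700 nm chlorophyll-like valley;
# all components share the 1450-1500 nm water/cellulose trough with
# differing depths; a 1650-1700 nm feature mimics the nicotine/polyphenol
# signature.
_VIS_BANDS = {
    "tobacco_silk": [(675, 28, 0.20), (480, 30, 0.05)],
    "cut_stem": [(675, 28, 0.06), (560, 35, 0.10)],
    "fermented_cut_stem": [(675, 28, 0.12), (520, 30, 0.08)],
    "expanded_tobacco_silk": [(675, 28, 0.04), (600, 40, -0.04)],
}
_NIR_BANDS = {
    "tobacco_silk": [(1475, 40, 0.25), (1200, 60, 0.06)],
    "cut_stem": [(1475, 40, 0.15), (1100, 50, 0.04)],
    "fermented_cut_stem": [(1475, 40, 0.30), (1350, 50, 0.08)],
    "expanded_tobacco_silk": [(1475, 40, 0.10), (1660, 35, -0.06)],
}
_VIS_LEVEL = {"expanded_tobacco_silk": 0.06}
_NIR_LEVEL = {"expanded_tobacco_silk": 0.05}


def make_endmembers(
    seed: int | None = 0,
    vis_grid: np.ndarray | None = None,
    nir_grid: np.ndarray | None = None,
    min_separation: float = 0.01,
    complementary: bool = False,
) -> EndmemberSet:
    """Generate the four pure-component spectra.

    Each spectrum is a smooth range baseline minus component-specific
    Gaussian absorption bands, with a small seeded depth jitter so seeds
    produce distinct but structurally identical sets.  With
    ``complementary=True`` the cut-stem NIR spectrum is made identical to
    the dominant component's and the expanded-silk Vis spectrum likewise,
    so each minor component is identifiable in exactly one range — the
    configuration used to study the gain from fusing the two ranges.
    """
    vis_grid = DEFAULT_VIS_GRID if vis_grid is None else np.asarray(vis_grid, float)
    nir_grid = DEFAULT_NIR_GRID if nir_grid is None else np.asarray(nir_grid, float)
    if vis_grid.size == 0 or nir_grid.size == 0:
        raise ValueError("wavelength grids must be non-empty")
    rng = np.random.default_rng(seed)

    vis_base = 0.15 + 0.40 / (1.0 + np.exp(-(vis_grid - 720.0) / 60.0))
    nir_base = (
        0.55
        - 1.5e-4 * (nir_grid - 975.0)
        + 0.03 * np.sin((nir_grid - 975.0) / 180.0)
    )

    vis = np.empty((4, vis_grid.size))
    nir = np.empty((4, nir_grid.size))
    band_params: dict = {}
    for c, name in enumerate(COMPONENTS):
        jitter = 1.0 + 0.05 * rng.standard_normal()
        v = vis_base + _VIS_LEVEL.get(name, 0.0)
        for center, width, depth in _VIS_BANDS[name]:
            v = v - depth * jitter * _gauss(vis_grid, center, width)
        w = nir_base + _NIR_LEVEL.get(name, 0.0)
        for center, width, depth in _NIR_BANDS[name]:
            w = w - depth * jitter * _gauss(nir_grid, center, width)
        vis[c] = np.clip(v, 0.0, 1.1)
        nir[c] = np.clip(w, 0.0, 1.1)
        band_params[name] = {
            "vis": _VIS_BANDS[name],
            "nir": _NIR_BANDS[name],
            "jitter": jitter,
        }
    if complementary:
        nir[1] = nir[0]   # cut stem indistinguishable from dominant in NIR
        vis[3] = vis[0]   # expanded silk indistinguishable in Vis-NIR
        band_params["complementary"] = True

    ems = EndmemberSet(
        vis=vis,
        nir=nir,
        vis_grid=vis_grid,
        nir_grid=nir_grid,
        band_params=band_params,
    )
    if not complementary and ems.min_pairwise_separation() < min_separation:
        raise ValueError(
            "endmembers not identifiable: pairwise separation "
            f"{ems.min_pairwise_separation():.4g} < {min_separation}"
        )
    return ems


def sample_blends(
    n_recipes: int = 30,
    n_replicates: int = 3,
    seed: int | None = 0,
    ranges: tuple = DEFAULT_RANGES,
) -> BlendDesign:
    """Constrained random blend design by rejection sampling.

    Minor components are drawn uniformly on their intervals; the dominant
    component takes the remainder 1 - Σ minors, and the draw is accepted
    iff that remainder lies in its own interval.  With the default ranges
    rejection occurs exactly when the minors sum beyond 0.40.  Each
    accepted recipe is repeated ``n_replicates`` times (replicate scans of
    the same physical blend share its exact proportions).
    """
    lo = np.array([r[0] for r in ranges])
    hi = np.array([r[1] for r in ranges])
    # feasible iff the minors' total can land inside [1 - hi0, 1 - lo0]
    if max(lo[1:].sum(), 1 - hi[0]) > min(hi[1:].sum(), 1 - lo[0]) + 1e-12:
        raise ValueError("infeasible component ranges: acceptance region empty")
    rng = np.random.default_rng(seed)
    recipes = []
    guard = 0
    while len(recipes) < n_recipes:
        guard += 1
        if guard > 100000 * n_recipes:
            raise ValueError("infeasible component ranges: rejection never accepts")
        minors = rng.uniform(lo[1:], hi[1:])
        major = 1.0 - minors.sum()
        if lo[0] <= major <= hi[0]:
            recipes.append(np.concatenate([[major], minors]))
    proportions = np.repeat(np.array(recipes), n_replicates, axis=0)
    recipe_ids = [r + 1 for r in range(n_recipes) for _ in range(n_replicates)]
    replicates = [s + 1 for _ in range(n_recipes) for s in range(n_replicates)]
    return BlendDesign(
        proportions=proportions,
        recipe_ids=recipe_ids,
        replicates=replicates,
        ranges=ranges,
    )


def _distort(
    M: np.ndarray,
    grid: np.ndarray,
    noise: NoiseModel,
    jitter: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply per-spectrum scatter, baseline drift and additive noise."""
    n, p = M.shape
    slope = rng.normal(1.0, noise.scatter_slope_sd, size=n)
    offset = rng.normal(0.0, noise.scatter_offset_sd, size=n)
    u = 2.0 * (grid - grid[0]) / (grid[-1] - grid[0]) - 1.0
    coeffs = rng.standard_normal((n, 3))
    drift = noise.baseline_amplitude * (
        coeffs[:, [0]] + coeffs[:, [1]] * u + coeffs[:, [2]] * u**2
    )
    out = slope[:, None] * M + offset[:, None] + drift + jitter[:, None]
    out = out + rng.normal(0.0, noise.additive_sd, size=(n, p))
    return out


def mix_spectra(
    endmembers: EndmemberSet,
    design: BlendDesign,
    noise: NoiseModel | None = None,
    seed: int | None = 0,
) -> tuple[SpectraBlock, SpectraBlock]:
    """Linear mixing plus instrument-style distortion, per range.

    spectrum_i = Σ_c proportion_ic * endmember_c, then per-spectrum scatter
    (slope ~ N(1, σ_slope), offset ~ N(0, σ_offset)), smooth baseline
    drift, a per-scan jitter shared between the two ranges, and additive
    channel noise.  Replicate scans get independent noise.  With the noise
    model zeroed the map is exactly linear.
    """
    if design.n_samples < 1:
        raise ValueError("design has no rows")
    noise = NoiseModel() if noise is None else noise
    P = design.proportions
    if P.shape[1] != endmembers.vis.shape[0]:
        raise ValueError("design component count != endmember count")
    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, noise.replicate_jitter_sd, size=design.n_samples)
    ids = design.sample_ids()
    vis = SpectraBlock(
        values=_distort(P @ endmembers.vis, endmembers.vis_grid, noise, jitter, rng),
        wavelengths=endmembers.vis_grid,
        sample_ids=ids,
        range_tag=VISNIR,
    )
    nir = SpectraBlock(
        values=_distort(P @ endmembers.nir, endmembers.nir_grid, noise, jitter, rng),
        wavelengths=endmembers.nir_grid,
        sample_ids=ids,
        range_tag=NIR,
    )
    return vis, nir


def inject_outliers(
    blocks: list[SpectraBlock],
    k: int,
    magnitude: float = 0.5,
    seed: int | None = 0,
) -> tuple[list[SpectraBlock], np.ndarray]:
    """Corrupt k randomly chosen samples with a gross uniform reflectance
    offset (the same samples across all given blocks), returning the
    corrupted blocks and ground-truth labels for detector validation."""
    if not blocks:
        raise ValueError("no blocks given")
    n = blocks[0].n_samples
    if k < 0 or k >= n / 4:
        raise ValueError(f"k={k} must satisfy 0 <= k < n/4 = {n / 4}")
    labels = np.zeros(n, dtype=bool)
    if k == 0:
        return [b.with_values(b.values.copy()) for b in blocks], labels
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    labels[idx] = True
    out = []
    for b in blocks:
        values = b.values.copy()
        values[idx] += magnitude
        out.append(b.with_values(values))
    return out, labels
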