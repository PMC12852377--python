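"""Three-stage study orchestration across spectra sources and blend targets.

Stage "raw": PLSR with LOOCV on the untouched Vis-NIR, NIR and fused
matrices for every target component (12 models).  Stage "screened": the
PCA+MCD outlier screen runs once per source on raw spectra — each source
may drop different samples — and all models are refit on each source's kept
subset.  Stage "processed": an explicit grid of (preprocessing plan x
variable selector) is evaluated by RMSECV per target and source, and the
winner is kept with its full grid trace.  The grid replaces any automated
preprocessing-search framework with an exhaustive, fully reproducible
enumeration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import FUSED, NIR, VISNIR, SpectraBlock
from .fusion import fuse_blocks, variable_labels
from .outliers import OutlierReport, flag_outliers
from .plsr import ModelReport, evaluate_model
from .preprocess import PreprocessPlan, apply_plan
from .selection import (
    SelectionResult,
    cars_select,
    no_selection,
    spa_select,
    vip_select,
)
from .synthetic import (
    COMPONENTS,
    BlendDesign,
    NoiseModel,
    make_endmembers,
    mix_spectra,
    sample_blends,
)

logger = logging.getLogger("blendspec")

SOURCES = (VISNIR, NIR, FUSED)


def default_plan_grid() -> dict[str, PreprocessPlan]:
    """The preprocessing plans the grid search compares."""
    return {
        "identity": PreprocessPlan([]),
        "ma5": PreprocessPlan([("moving_average", {"window": 5})]),
        "sg11": PreprocessPlan(
            [("savitzky_golay", {"window": 11, "polyorder": 2, "deriv": 0})]
        ),
        "ma5+d1": PreprocessPlan(
            [
                ("moving_average", {"window": 5}),
                ("savitzky_golay", {"window": 11, "polyorder": 2, "deriv": 1}),
            ]
        ),
        "sg11+msc": PreprocessPlan(
            [
                ("savitzky_golay", {"window": 11, "polyorder": 2, "deriv": 0}),
                ("msc", {"reference": "mean"}),
            ]
        ),
        "sg11+snv": PreprocessPlan(
            [
                ("savitzky_golay", {"window": 11, "polyorder": 2, "deriv": 0}),
                ("snv", {}),
            ]
        ),
    }


@dataclass
class StudyConfig:
    """Everything a study run needs; seeds are recorded in every output."""

    stages: tuple[str, ...] = ("raw", "screened", "processed")
    l_max: int = 20
    mcd_quantile: float = 0.975
    seed: int = 0
    plans: dict[str, PreprocessPlan] = field(default_factory=default_plan_grid)
    selectors: tuple[str, ...] = ("none", "VIP", "SPA", "CARS")
    spa_max_vars: int = 25
    cars_runs: int = 50
    vip_lv: int = 10
    simulate: bool = True
    n_recipes: int = 30
    n_replicates: int = 3
    noise: NoiseModel = field(default_factory=NoiseModel)
    vis_table: str | None = None
    nir_table: str | None = None
    design_table: str | None = None


@dataclass
class StudyReport:
    raw: list[ModelReport] = field(default_factory=list)
    screened: list[ModelReport] = field(default_factory=list)
    processed: list[ModelReport] = field(default_factory=list)
    outlier_reports: dict[str, OutlierReport] = field(default_factory=dict)
    selections: dict[tuple[str, str], SelectionResult] = field(default_factory=dict)
    grid_trace: list[dict] = field(default_factory=list)
    config: StudyConfig | None = None


# ---------------------------------------------------------------------------
# data assembly
# ---------------------------------------------------------------------------

def simulate_study(
    seed: int = 0,
    n_recipes: int = 30,
    n_replicates: int = 3,
    noise: NoiseModel | None = None,
    complementary: bool = False,
) -> tuple[SpectraBlock, SpectraBlock, BlendDesign]:
    """One simulated acquisition session: endmembers, design, mixed blocks."""
    rng = np.random.default_rng(seed)
    s_em, s_design, s_mix = (int(x) for x in rng.integers(2**31, size=3))
    ems = make_endmembers(seed=s_em, complementary=complementary)
    design = sample_blends(n_recipes, n_replicates, seed=s_design)
    vis, nir = mix_spectra(ems, design, noise=noise, seed=s_mix)
    return vis, nir, design


def load_study(config: StudyConfig) -> tuple[SpectraBlock, SpectraBlock, BlendDesign]:
    from .hsi_io import read_spectra_table

    if config.simulate:
        return simulate_study(
            config.seed, config.n_recipes, config.n_replicates, config.noise
        )
    vis = read_spectra_table(config.vis_table, range_tag=VISNIR)
    nir = read_spectra_table(config.nir_table, range_tag=NIR)
    frame = pd.read_csv(config.design_table)
    design = BlendDesign(
        proportions=frame[list(COMPONENTS)].to_numpy(),
        recipe_ids=list(frame["recipe"]),
        replicates=list(frame["replicate"]),
    )
    if vis.sample_ids != design.sample_ids() or nir.sample_ids != design.sample_ids():
        raise ValueError("sample ids misaligned across spectra tables and design")
    return vis, nir, design


def _targets(design: BlendDesign) -> dict[str, np.ndarray]:
    return {
        name: design.proportions[:, c] for c, name in enumerate(COMPONENTS)
    }


def _sources(vis: SpectraBlock, nir: SpectraBlock) -> dict[str, SpectraBlock]:
    return {VISNIR: vis, NIR: nir, FUSED: fuse_blocks([vis, nir])}


def _subset_design(design: BlendDesign, ids: list[str]) -> np.ndarray:
    index = {s: i for i, s in enumerate(design.sample_ids())}
    return np.array([index[s] for s in ids])


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_stage_raw(
    vis: SpectraBlock,
    nir: SpectraBlock,
    design: BlendDesign,
    l_max: int = 20,
) -> list[ModelReport]:
    """Models on untouched spectra: 4 targets x 3 sources."""
    if vis.sample_ids != design.sample_ids() or nir.sample_ids != design.sample_ids():
        raise ValueError("sample ids misaligned across sources and design")
    reports = []
    for source, block in _sources(vis, nir).items():
        for target, y in _targets(design).items():
            t0 = time.perf_counter()
            rep = evaluate_model(
                block.values, y, l_max, target=target, spectra_source=source
            )
            logger.info(
                "raw %s/%s: LV=%d R2=%.4f RMSECV=%.4f (%.2fs)",
                source, target, rep.n_lv, rep.r2, rep.rmsecv,
                time.perf_counter() - t0,
            )
            reports.append(rep)
    return reports


def run_stage_screened(
    vis: SpectraBlock,
    nir: SpectraBlock,
    design: BlendDesign,
    l_max: int = 20,
    quantile: float = 0.975,
    seed: int = 0,
) -> tuple[list[ModelReport], dict[str, OutlierReport], dict[str, SpectraBlock]]:
    """Screen each source independently on raw spectra, refit on kept rows."""
    reports: list[ModelReport] = []
    outliers: dict[str, OutlierReport] = {}
    kept_blocks: dict[str, SpectraBlock] = {}
    for source, block in _sources(vis, nir).items():
        kept, report = flag_outliers(block, quantile=quantile, seed=seed)
        outliers[source] = report
        kept_blocks[source] = kept
        rows = _subset_design(design, kept.sample_ids)
        for target, y in _targets(design).items():
            reports.append(
                evaluate_model(
                    kept.values,
                    y[rows],
                    l_max,
                    target=target,
                    spectra_source=source,
                )
            )
        logger.info(
            "screened %s: kept %d of %d", source, kept.n_samples, block.n_samples
        )
    return reports, outliers, kept_blocks


def _apply_selector(
    name: str,
    X: np.ndarray,
    y: np.ndarray,
    config: StudyConfig,
    seed: int,
) -> SelectionResult:
    if name == "none":
        return no_selection(X, y)
    if name == "VIP":
        n_lv = int(min(config.vip_lv, X.shape[0] - 2, X.shape[1]))
        return vip_select(X, y, n_lv)
    if name == "SPA":
        max_vars = int(min(config.spa_max_vars, X.shape[0] - 2, X.shape[1]))
        return spa_select(X, y, max_vars)
    if name == "CARS":
        return cars_select(X, y, n_runs=config.cars_runs, seed=seed)
    raise ValueError(f"unknown selector {name!r}")


def _restrict(
    block: SpectraBlock, ids: list[str], design: BlendDesign
) -> SpectraBlock:
    """Restrict a full-sample single-range block to the given sample ids."""
    index = {s: i for i, s in enumerate(block.sample_ids)}
    return block.select_samples(np.array([index[s] for s in ids]))


# ---------------------------------------------------------------------------
# whole study + reporting
# ---------------------------------------------------------------------------

def run_study(config: StudyConfig) -> StudyReport:
    vis, nir, design = load_study(config)
    report = StudyReport(config=config)
    kept: dict[str, SpectraBlock] = {}
    if "raw" in config.stages:
        report.raw = run_stage_raw(vis, nir, design, config.l_max)
    if "screened" in config.stages or "processed" in config.stages:
        report.screened, report.outlier_reports, kept = run_stage_screened(
            vis, nir, design, config.l_max, config.mcd_quantile, config.seed
        )
        if "screened" not in config.stages:
            report.screened = []
    if "processed" in config.stages:
        # single ranges keep their own screened rows; the fused source is
        # rebuilt from the full-sample per-range blocks restricted to the
        # fused screen's kept ids
        fused_ids = report.outlier_reports[FUSED].kept_ids
        vis_kept = _restrict(vis, report.outlier_reports[VISNIR].kept_ids, design)
        nir_kept = _restrict(nir, report.outlier_reports[NIR].kept_ids, design)
        # for the fused source the per-range blocks must carry the fused
        # screen's samples; pass the full blocks and the fused ids
        report.processed, report.selections, report.grid_trace = (
            run_stage_processed(vis, nir, vis_kept, nir_kept, fused_ids,
                                     design, config)
        )
    return report


def run_stage_processed(
    vis_full: SpectraBlock,
    nir_full: SpectraBlock,
    vis_kept: SpectraBlock,
    nir_kept: SpectraBlock,
    fused_kept_ids: list[str],
    design: BlendDesign,
    config: StudyConfig,
):
    """Exhaustive (plan x selector) grid per target and source.

    Single-range sources use their own screened subsets.  The fused source
    is rebuilt from the full-sample per-range blocks restricted to the
    samples its own screening kept, preprocessed per range, then fused.
    """
    reports: list[ModelReport] = []
    winners: dict[tuple[str, str], SelectionResult] = {}
    trace: list[dict] = []
    rng = np.random.default_rng(config.seed)
    if not config.plans or not config.selectors:
        raise ValueError("empty preprocessing/selector grid")
    for source in SOURCES:
        if source == VISNIR:
            base, ids = vis_kept, vis_kept.sample_ids
        elif source == NIR:
            base, ids = nir_kept, nir_kept.sample_ids
        else:
            base, ids = None, fused_kept_ids
        rows = _subset_design(design, ids)
        for target, y_full in _targets(design).items():
            y = y_full[rows]
            best = None
            for plan_name, plan in config.plans.items():
                if source == FUSED:
                    pre = fuse_blocks(
                        [
                            apply_plan(_restrict(vis_full, ids, design), plan),
                            apply_plan(_restrict(nir_full, ids, design), plan),
                        ]
                    )
                else:
                    pre = apply_plan(base, plan)
                for sel_name in config.selectors:
                    sel_seed = int(rng.integers(2**31))
                    sel = _apply_selector(sel_name, pre.values, y, config, sel_seed)
                    X_sel = pre.values[:, sel.selected_indices]
                    rep = evaluate_model(
                        X_sel,
                        y,
                        config.l_max,
                        target=target,
                        spectra_source=source,
                        preprocessing=plan_name,
                        selector=sel_name,
                    )
                    trace.append(
                        {
                            "target": target,
                            "source": source,
                            "plan": plan_name,
                            "selector": sel_name,
                            "n_variables": rep.n_variables,
                            "n_lv": rep.n_lv,
                            "r2": rep.r2,
                            "rmsecv": rep.rmsecv,
                            "rpd": rep.rpd,
                        }
                    )
                    key = (rep.rmsecv, rep.n_variables)
                    if best is None or key < (best[0], best[1]):
                        best = (rep.rmsecv, rep.n_variables, rep, sel)
            _, _, rep, sel = best
            reports.append(rep)
            winners[(target, source)] = sel
    return reports, winners, trace


def _stage_frame(reports: list[ModelReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "component": r.target,
                "source": r.spectra_source,
                "sample_size": r.sample_size,
                "n_variables": r.n_variables,
                "preprocessing": r.preprocessing,
                "selector": r.selector,
                "lvs": r.n_lv,
                "r2": r.r2,
                "rmsecv": r.rmsecv,
                "rpd": r.rpd,
            }
            for r in reports
        ]
    )


def write_report(report: StudyReport, outdir: str | Path) -> dict[str, Path]:
    """Persist stage tables, outlier tables, selected-variable tables and a
    run manifest; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for stage in ("raw", "screened", "processed"):
        reports = getattr(report, stage)
        if reports:
            path = outdir / f"models_{stage}.csv"
            _stage_frame(reports).to_csv(path, index=False)
            written[f"models_{stage}"] = path
    for source, rep in report.outlier_reports.items():
        path = outdir / f"outliers_{source}.csv"
        rep.to_frame().to_csv(path, index=False)
        written[f"outliers_{source}"] = path
    if report.grid_trace:
        path = outdir / "grid_trace.csv"
        pd.DataFrame(report.grid_trace).to_csv(path, index=False)
        written["grid_trace"] = path
    for (target, source), sel in report.selections.items():
        path = outdir / f"selected_{source}_{target}.csv"
        pd.DataFrame(
            {
                "variable_index": sel.selected_indices,
                "score": sel.scores[sel.selected_indices],
            }
        ).to_csv(path, index=False)
        written[f"selected_{source}_{target}"] = path
    manifest = {
        "seed": report.config.seed if report.config else None,
        "stages": list(report.config.stages) if report.config else [],
        "l_max": report.config.l_max if report.config else None,
        "mcd_quantile": report.config.mcd_quantile if report.config else None,
        "outlier_seeds": {
            source: rep.seed for source, rep in report.outlier_reports.items()
        },
        "selector_seeds": {
            f"{source}:{target}": sel.seed
            for (target, source), sel in report.selections.items()
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    written["manifest"] = path
    return written
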