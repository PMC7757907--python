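"""End-to-end invasion-risk pipeline: config, orchestration, manifests.

One :class:`RunConfig` drives the whole chain

    thin -> select-vars -> fit -> predict -> classify -> merge -> disperse

writing every intermediate product (text rasters, CSVs) plus a JSON run
manifest with the inputs, settings, seeds and per-stage record/cell counts,
so any output can be regenerated bit-identically from its manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dispersal import derive_params, dispersal_likelihood
from .enm import (
    FeatureSpec,
    apply_threshold,
    auc,
    extract_at_points,
    fit_maxent,
    percent_contribution,
    predict_logistic,
    sample_background,
    split_presences,
    threshold_10pct,
)
from .habitat import ClassScheme, classify, class_counts, normalize, overall_suitability
from .occurrences import OccurrenceSet, deduplicate, load_occurrences, thin_spatial
from .predictors import select_variables
from .raster import PredictorStack, RasterGrid, read_ascii_grid, write_ascii_grid

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat, validated settings for one pipeline run. Seeds are explicit."""

    occurrences_csv: str = ""
    predictors_dir: str = ""
    host_raster: str = ""
    scenario_dirs: dict = field(default_factory=dict)  # name -> predictors dir
    out_dir: str = "zonarisk_out"

    thin_min_km: float = 10.0
    correlation_cutoff: float = 0.7
    max_corr_cells: int | None = None

    feature_classes: tuple = ("linear", "quadratic", "hinge")
    hinge_knots: int = 20
    reg_multiplier: float = 2.0
    background_n: int = 10_000
    train_frac: float = 0.75
    tol: float = 1e-6
    max_iter: int = 500
    apply_threshold: bool = False

    class_breaks: tuple = (0.15, 0.30, 0.60)
    host_min: float | None = 0.0
    host_max: float | None = None

    d_max: float = 40.2
    k1: float = 0.5
    k2: float = 0.5
    paper_rounding: bool = True

    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.train_frac < 1):
            raise ValueError("train_frac must be in (0, 1)")
        if self.thin_min_km <= 0 or self.correlation_cutoff <= 0:
            raise ValueError("thin_min_km and correlation_cutoff must be positive")
        if self.background_n < 1 or self.reg_multiplier < 0:
            raise ValueError("background_n must be >= 1 and reg_multiplier >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feature_classes"] = list(self.feature_classes)
        d["class_breaks"] = list(self.class_breaks)
        return d


def validate_stack(predictor_paths, host_path: str | Path | None = None) -> PredictorStack:
    """Load a stack and assert co-registration across all layers (+ host).

    ``predictor_paths`` is a directory of ``.asc`` layers or a list of
    files. Mismatched transforms are fatal with per-layer diagnostics.
    """
    if isinstance(predictor_paths, (str, Path)) and Path(predictor_paths).is_dir():
        stack = PredictorStack.read_dir(predictor_paths)
    else:
        layers = {Path(p).stem: read_ascii_grid(p) for p in predictor_paths}
        stack = PredictorStack(layers)  # constructor asserts co-registration
    if host_path is not None:
        host = read_ascii_grid(host_path)
        if host.transform != stack.transform:
            raise ValueError(
                f"host raster grid {host.transform} does not match predictor "
                f"grid {stack.transform}"
            )
    n_valid = int(stack.valid.sum())
    total = stack.transform.nrows * stack.transform.ncols
    logger.info("stack: %d layers, %d/%d jointly valid cells", len(stack), n_valid, total)
    if n_valid == 0:
        raise ValueError("stack has no jointly valid cells")
    return stack


def run_synthetic_study(scenario=None, seed: int = 0, background_n: int = 10_000,
                        reg_multiplier: float = 2.0) -> dict:
    """Fit and evaluate the niche model on a synthetic landscape, in memory.

    Generates the scenario's predictors, truth surface and presences,
    thins at 10 km, prunes collinear layers at |r| > 0.7, fits the
    linear+quadratic+hinge model on a seeded 75/25 presence split against a
    uniform background sample, and reports held-out discrimination plus
    agreement with the known truth. All randomness derives from ``seed``
    (scenario seed, presence sample, background, split).
    """
    from scipy.stats import spearmanr

    from .synthetic import (
        SyntheticScenario,
        generate_predictor_stack,
        generate_true_suitability,
        sample_presences,
    )

    if scenario is None:
        scenario = SyntheticScenario(seed=seed)
    stack = generate_predictor_stack(scenario)
    truth = generate_true_suitability(
        stack, scenario.linear_coefficients, scenario.quadratic_coefficients,
        intercept=scenario.intercept,
    )
    occ = sample_presences(truth, scenario.presence_n, seed=scenario.seed + 1)
    occ = thin_spatial(deduplicate(occ), min_km=10.0)
    stack_sel, report = select_variables(stack, cutoff=0.7)
    bg = sample_background(stack_sel, n=background_n, seed=seed + 11)
    train, test = split_presences(occ, train_frac=0.75, seed=seed + 12)
    names = stack_sel.names
    train_X = extract_at_points(stack_sel, train)[names].to_numpy()
    test_X = extract_at_points(stack_sel, test)[names].to_numpy()
    bg_X = bg[names].to_numpy()
    model = fit_maxent(train_X, bg_X, FeatureSpec(), var_names=names,
                       reg_multiplier=reg_multiplier)
    surface = predict_logistic(model, stack_sel)
    v = stack_sel.valid
    rho = float(spearmanr(surface.values[v], truth.values[v]).statistic)
    return {
        "auc_test": auc(model.predict(test_X), model.predict(bg_X)),
        "auc_train": auc(model.predict(train_X), model.predict(bg_X)),
        "spearman_truth": rho,
        "n_thinned": len(occ),
        "n_train": len(train),
        "n_test": len(test),
        "retained": names,
        "dropped": report.dropped,
        "model": model,
        "surface": surface,
        "truth": truth,
        "stack": stack_sel,
        "occurrences": occ,
    }


@dataclass
class RiskMapBundle:
    """Everything one pipeline run produces, in memory."""

    occurrences: OccurrenceSet
    stack: PredictorStack
    model: object
    climatic_suitability: RasterGrid
    climatic_classes: RasterGrid
    overall: RasterGrid
    overall_classes: RasterGrid
    dispersal: RasterGrid
    evaluation: dict
    scenario_suitability: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> RiskMapBundle:
    """Execute every stage on disk inputs and write all products + manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": config.to_dict(), "stages": {}}

    def stage(name: str, **info) -> None:
        manifest["stages"][name] = info
        logger.info("stage %s: %s", name, info)

    try:
        # ----- occurrences -----
        occ = load_occurrences(config.occurrences_csv)
        occ = deduplicate(occ)
        occ = thin_spatial(occ, min_km=config.thin_min_km)
        occ.to_csv(out / "occurrences_thinned.csv")
        stage("thin", provenance=[asdict(s) | {"n_removed": s.n_removed} for s in occ.provenance])

        # ----- predictors -----
        stack = validate_stack(config.predictors_dir, config.host_raster or None)
        stack_sel, corr_report = select_variables(
            stack, cutoff=config.correlation_cutoff,
            max_cells=config.max_corr_cells, seed=config.seed,
        )
        corr_report.to_csv(out / "correlation_matrix.csv")
        stage("select_vars", retained=corr_report.retained, dropped=corr_report.dropped)

        # ----- model fit -----
        spec = FeatureSpec(classes=tuple(config.feature_classes), hinge_knots=config.hinge_knots)
        bg = sample_background(stack_sel, n=config.background_n, seed=config.seed + 1)
        train, test = split_presences(occ, train_frac=config.train_frac, seed=config.seed + 2)
        var_names = stack_sel.names
        train_X = extract_at_points(stack_sel, train)[var_names].to_numpy()
        test_X = extract_at_points(stack_sel, test)[var_names].to_numpy()
        bg_X = bg[var_names].to_numpy()
        model = fit_maxent(train_X, bg_X, spec, var_names=var_names,
                           reg_multiplier=config.reg_multiplier,
                           tol=config.tol, max_iter=config.max_iter)
        test_auc = auc(model.predict(test_X), model.predict(bg_X))
        train_auc = auc(model.predict(train_X), model.predict(bg_X))
        contrib = percent_contribution(model)
        thr = threshold_10pct(model, train_X)
        evaluation = {
            "auc_test": test_auc,
            "auc_train": train_auc,
            "n_train": len(train),
            "n_test": len(test),
            "threshold_10pct": thr,
            "percent_contribution": contrib.to_dict(),
            "converged": bool(model.converged),
        }
        (out / "evaluation.json").write_text(json.dumps(evaluation, indent=2) + "\n")
        stage("fit", auc_test=test_auc, auc_train=train_auc, n_features=len(model.lambdas),
              threshold_10pct=thr)

        # ----- predict + classify -----
        cs = predict_logistic(model, stack_sel)
        if config.apply_threshold:
            cs = apply_threshold(cs, thr)
        write_ascii_grid(cs, out / "climatic_suitability.asc")
        scheme = ClassScheme(breaks=tuple(config.class_breaks))
        cs_classes = classify(cs, scheme)
        write_ascii_grid(cs_classes, out / "climatic_suitability_classes.asc", fmt="%d")
        (out / "class_legend.json").write_text(json.dumps(scheme.legend(), indent=2) + "\n")
        stage("predict", valid_cells=int(cs.valid.sum()),
              class_counts=class_counts(cs_classes, scheme))

        scenario_cs: dict[str, RasterGrid] = {}
        for name, sdir in (config.scenario_dirs or {}).items():
            s_stack = validate_stack(sdir).subset(var_names)
            s_cs = predict_logistic(model, s_stack)
            write_ascii_grid(s_cs, out / f"climatic_suitability_{name}.asc")
            scenario_cs[name] = s_cs
        if scenario_cs:
            stage("predict_scenarios", scenarios=list(scenario_cs))

        # ----- merge (overall habitat suitability) -----
        host = read_ascii_grid(config.host_raster, units="ha")
        cs_n = normalize(cs)
        host_n = normalize(host, min_override=config.host_min, max_override=config.host_max)
        overall = overall_suitability(cs_n, host_n)
        write_ascii_grid(overall, out / "overall_suitability.asc")
        overall_classes = classify(overall, scheme)
        write_ascii_grid(overall_classes, out / "overall_suitability_classes.asc", fmt="%d")
        stage("merge", class_counts=class_counts(overall_classes, scheme))

        # ----- disperse -----
        params = derive_params(d_max=config.d_max, k1=config.k1, k2=config.k2,
                               paper_rounding=config.paper_rounding)
        params.to_json(out / "dispersal_params.json")
        lik = dispersal_likelihood(cs_n, host_n, occ, params)
        write_ascii_grid(lik, out / "dispersal_likelihood.asc")
        stage("disperse", sigma=params.sigma, c1=params.c1, c2=params.c2,
              max_likelihood=float(np.nanmax(lik.values)))
    except Exception as exc:
        # leave whatever was written; record where it stopped
        done = list(manifest["stages"])
        manifest["failed_after"] = done
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        raise RuntimeError(
            f"pipeline failed after stages {done}: {exc}"
        ) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return RiskMapBundle(
        occurrences=occ,
        stack=stack_sel,
        model=model,
        climatic_suitability=cs,
        climatic_classes=cs_classes,
        overall=overall,
        overall_classes=overall_classes,
        dispersal=lik,
        evaluation=evaluation,
        scenario_suitability=scenario_cs,
        manifest=manifest,
    )
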