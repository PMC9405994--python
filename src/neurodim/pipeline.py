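"""End-to-end orchestration: cohort -> CFA -> linear + network -> comparison.

One :class:`RunConfig` drives the whole run.  Every stage's numeric output
is written under the run directory, and a manifest (config echo, package
versions, per-file SHA-256) makes a run reproducible bit-for-bit from its
configuration alone: no timestamps or host state enter any artefact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, StageError
from .synthetic import (
    Cohort,
    CohortConfig,
    DOMAIN_COLUMNS,
    FACTOR_COLUMNS,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .cfa import (
    correlated_factors_spec,
    factor_scores,
    fit_cfa,
    single_factor_spec,
)
from .linear import fit_mvreg, predict
from .network import (
    NetworkConfig,
    ScalingSpec,
    evaluate,
    init_network,
    train,
)
from .compare import run_comparison_suite

log = logging.getLogger("neurodim")

STAGES = ("cohort", "cfa", "linear", "ann", "compare", "report")
STAGE_EXIT_CODES = {name: code for code, name in enumerate(STAGES, start=2)}


@dataclass
class RunConfig:
    """Configuration for one full pipeline run.

    Exactly one cohort source must be set: ``cohort`` (generate) or
    ``cohort_path`` (load an existing CSV).  The global ``seed`` is spawned
    deterministically into per-stage seeds (cohort draw, each network's
    weights/sampling), so two runs with the same config are bit-identical.
    """

    cohort: CohortConfig | None = field(default_factory=CohortConfig)
    cohort_path: str | None = None
    family_alpha: float = 0.05
    seed: int = 0
    ann_lower: NetworkConfig = field(
        default_factory=lambda: NetworkConfig(n_outputs=9)
    )
    ann_higher: NetworkConfig = field(
        default_factory=lambda: NetworkConfig(n_outputs=3)
    )

    def validate(self) -> None:
        if (self.cohort is None) == (self.cohort_path is None):
            raise ConfigError("exactly one of cohort / cohort_path must be set")

    def spawn_seeds(self) -> dict:
        children = np.random.SeedSequence(self.seed).generate_state(3)
        return {
            "cohort": int(children[0] % (2**31)),
            "ann_lower": int(children[1] % (2**31)),
            "ann_higher": int(children[2] % (2**31)),
        }

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort is not None:
            d["cohort"]["loading_pattern"] = {
                k: list(v) for k, v in self.cohort.loading_pattern.items()
            }
        return d

    @classmethod
    def from_jsonable(cls, raw: dict) -> "RunConfig":
        """Rebuild a config from a manifest's ``config`` entry."""
        kwargs = {"family_alpha": raw["family_alpha"], "seed": raw["seed"]}
        if raw.get("cohort_path"):
            kwargs["cohort_path"] = raw["cohort_path"]
            kwargs["cohort"] = None
        else:
            cohort_raw = dict(raw["cohort"])
            cohort_raw["loading_pattern"] = {
                k: (v[0], float(v[1]))
                for k, v in cohort_raw["loading_pattern"].items()
            }
            kwargs["cohort"] = CohortConfig(**cohort_raw)
        kwargs["ann_lower"] = NetworkConfig(**raw["ann_lower"])
        kwargs["ann_higher"] = NetworkConfig(**raw["ann_higher"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "cohort_path" in raw and raw["cohort_path"]:
            kwargs["cohort_path"] = raw["cohort_path"]
            kwargs["cohort"] = None
        elif "cohort" in raw:
            cohort_raw = dict(raw["cohort"])
            if "loading_pattern" in cohort_raw:
                cohort_raw["loading_pattern"] = {
                    k: (v[0], float(v[1]))
                    for k, v in cohort_raw["loading_pattern"].items()
                }
            kwargs["cohort"] = CohortConfig(**cohort_raw)
        for key in ("family_alpha", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        for key, n_out in (("ann_lower", 9), ("ann_higher", 3)):
            if key in raw:
                kwargs[key] = NetworkConfig(**{"n_outputs": n_out, **raw[key]})
        return cls(**kwargs)


@dataclass
class RunResult:
    """In-memory handles to everything a run produced."""

    out_dir: Path
    cohort: Cohort
    scores: pd.DataFrame
    cfa_fits: dict
    lm_fits: dict
    lm_predictions: pd.DataFrame
    ann_predictions: pd.DataFrame
    ann_traces: dict
    ann_states: dict
    report: object
    manifest: dict


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def run_pipeline(config: RunConfig, out_dir) -> RunResult:
    """Execute every stage, persisting outputs as each stage completes.

    A stage failure raises :class:`StageError` carrying the stage name;
    outputs of completed stages remain on disk for debugging.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.spawn_seeds()

    # ---- stage: cohort -------------------------------------------------
    try:
        if config.cohort_path is not None:
            cohort = read_cohort(config.cohort_path)
        else:
            cohort_cfg = dataclasses.replace(config.cohort, seed=seeds["cohort"])
            cohort = generate_cohort(cohort_cfg)
        write_cohort(cohort, out / "cohort.csv", out / "cohort_meta.json")
        log.info("cohort stage done (n=%d, seed=%s)", cohort.n_cases, seeds["cohort"])
    except Exception as exc:
        raise StageError("cohort", exc) from exc

    # ---- stage: cfa ----------------------------------------------------
    try:
        spec_corr = correlated_factors_spec()
        spec_single = single_factor_spec()
        fit_corr = fit_cfa(cohort.domains(), spec_corr)
        fit_single = fit_cfa(cohort.domains(), spec_single)
        scores_corr = factor_scores(fit_corr, spec_corr, cohort.domains())
        scores_single = factor_scores(fit_single, spec_single, cohort.domains())
        scores = pd.concat([scores_corr, scores_single], axis=1)
        scores.insert(0, "case_id", np.arange(len(scores)))
        scores.to_csv(out / "factor_scores.csv", index=False)
        _write_json(out / "cfa_correlated.json", fit_corr.to_jsonable())
        _write_json(out / "cfa_single.json", fit_single.to_jsonable())
        log.info(
            "cfa stage done (F_corr=%.4g, F_single=%.4g)",
            fit_corr.discrepancy, fit_single.discrepancy,
        )
    except Exception as exc:
        raise StageError("cfa", exc) from exc

    # ---- stage: linear -------------------------------------------------
    try:
        X = cohort.predictors()
        score_cols = scores[FACTOR_COLUMNS]
        lm_lower = fit_mvreg(X, cohort.domains())
        lm_higher = fit_mvreg(X, score_cols)
        lm_pred = pd.concat([predict(lm_lower, X), predict(lm_higher, X)], axis=1)
        _write_json(out / "lm_lower.json", lm_lower.to_jsonable())
        _write_json(out / "lm_higher.json", lm_higher.to_jsonable())
        lm_pred.to_csv(out / "lm_predictions.csv", index=False)
        log.info("linear stage done")
    except Exception as exc:
        raise StageError("linear", exc) from exc

    # ---- stage: ann ----------------------------------------------------
    try:
        # inputs are z-scored (targets min-max to [0,1] for the sigmoid
        # output units); correlations downstream are scale-invariant
        Xs = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        ann_preds = {}
        traces = {}
        states = {}
        for level, targets_df, base_cfg, seed_key in (
            ("lower", cohort.domains(), config.ann_lower, "ann_lower"),
            ("higher", score_cols, config.ann_higher, "ann_higher"),
        ):
            y_scaling = ScalingSpec.fit(targets_df)
            Ys = y_scaling.transform(targets_df)
            cfg = dataclasses.replace(base_cfg, seed=seeds[seed_key])
            state0 = init_network(cfg)
            state, trace = train(state0, Xs, Ys, cfg)
            result = evaluate(state, Xs, Ys, y_scaling)
            ann_preds[level] = pd.DataFrame(
                result.predictions, columns=targets_df.columns
            )
            traces[level] = trace
            states[level] = state
            trace.as_frame().to_csv(out / f"ann_{level}_trace.csv", index=False)
            log.info(
                "ann %s done: final SSE=%.2f RMSE=%.3f",
                level, trace.sse[-1], trace.final_rmse,
            )
        ann_pred = pd.concat([ann_preds["lower"], ann_preds["higher"]], axis=1)
        ann_pred.to_csv(out / "ann_predictions.csv", index=False)
    except Exception as exc:
        raise StageError("ann", exc) from exc

    # ---- stage: compare ------------------------------------------------
    try:
        actuals = pd.concat([cohort.domains(), score_cols], axis=1)
        report = run_comparison_suite(
            lm_pred, ann_pred, actuals,
            n=cohort.n_cases, family_alpha=config.family_alpha,
        )
        report.as_frame().to_csv(out / "comparison.csv", index=False)
        report.correlations_frame().to_csv(out / "correlations.csv", index=False)
        (out / "comparison.md").write_text(report.to_markdown())
        log.info("compare stage done")
    except Exception as exc:
        raise StageError("compare", exc) from exc

    # ---- stage: report / manifest --------------------------------------
    try:
        files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
        manifest = {
            "package_version": __version__,
            "config": config.to_jsonable(),
            "seeds": seeds,
            "files": {
                name: hashlib.sha256((out / name).read_bytes()).hexdigest()
                for name in files
            },
        }
        _write_json(out / "manifest.json", manifest)
    except Exception as exc:
        raise StageError("report", exc) from exc

    return RunResult(
        out_dir=out,
        cohort=cohort,
        scores=scores,
        cfa_fits={"correlated_factors": fit_corr, "single_factor": fit_single},
        lm_fits={"lower": lm_lower, "higher": lm_higher},
        lm_predictions=lm_pred,
        ann_predictions=ann_pred,
        ann_traces=traces,
        ann_states=states,
        report=report,
        manifest=manifest,
    )
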