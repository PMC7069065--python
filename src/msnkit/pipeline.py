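"""End-to-end orchestration: config, staged execution, manifest, determinism.

A run is described by a single config (YAML/JSON or a RunConfig instance):
the cohort source (synthetic parameters or a directory of feature tables),
the feature models, the density grid, the analyses to run, and one seed.  The
seed is split into independent per-stage seeds with numpy's SeedSequence
spawning, keyed by a fixed stage order, so each stage is reproducible in
isolation.  Outputs are plain CSV/TSV; a manifest records the config, the
per-stage row counts, and a sha256 checksum of every file written, and
re-running an identical config reproduces every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cognition import (
    bootstrap_weights,
    ef_summary,
    pls_cv_select,
    residualize_confounds,
)
from .io import FEATURE_SETS
from .network import DEFAULT_DENSITIES, nodal_strength, threshold_density, write_matrix
from .reliability import (
    build_group_network,
    graph_strength_table,
    run_intermodel,
    run_subject_vs_group,
    run_test_retest,
    subject_msn,
)
from .synthetic import (
    CohortConfig,
    SyntheticCohort,
    generate_cognition,
    generate_cohort,
    generate_retest,
    load_cohort,
    write_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

_STAGES = ("simulate", "retest", "cognition", "intermodel", "group", "predict")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2**31) from the run seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    seed: int = 0
    out_dir: str | Path = "results/run"
    cohort: CohortConfig | str | Path = field(default_factory=CohortConfig)
    models: tuple[str, ...] = ("msn10", "msn8", "msn7")
    densities: tuple[float, ...] = DEFAULT_DENSITIES
    analyses: tuple[str, ...] = ("intermodel", "retest", "group")
    retest_reliability: float | None = None  # defaults to the cohort config's value
    # predict-stage options
    predict_metric: str = "strength"
    predict_model: str = "msn10"
    predict_density: float = 0.4
    predict_outcome: str = "cogcomp"  # or "ef"
    predict_instances: int = 100
    predict_folds: int = 9
    predict_c_max: int = 10
    predict_stratified: bool = False
    predict_bins: int = 4
    predict_n_boot: int = 500

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(FEATURE_SETS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if not self.models or not self.analyses:
            raise ValueError("need at least one model and one analysis")
        bad = [d for d in self.densities if not (0 < d <= 1)]
        if bad:
            raise ValueError(f"densities outside (0, 1]: {bad}")
        allowed = {"intermodel", "retest", "group", "predict"}
        unknown = set(self.analyses) - allowed
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text())
        cohort = raw.pop("cohort", None)
        if isinstance(cohort, dict):
            cohort = CohortConfig(**cohort)
        elif cohort is None:
            cohort = CohortConfig()
        for key in ("models", "densities", "analyses"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(cohort=cohort, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the requested stages in dependency order; return the manifest.

    Stages: cohort acquisition (synthetic generation or directory load), retest
    generation where needed, then the requested analyses.  Any stage error
    aborts with the stage named.  Idempotent: identical configs give
    byte-identical outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    counts: dict[str, int] = {}

    # --- cohort -----------------------------------------------------------
    if isinstance(config.cohort, CohortConfig):
        cohort_cfg = dataclasses.replace(config.cohort, seed=stage_seed(config.seed, "simulate"))
        cohort = generate_cohort(cohort_cfg)
        rho = (
            config.retest_reliability
            if config.retest_reliability is not None
            else cohort_cfg.retest_reliability
        )
        if "retest" in config.analyses:
            generate_retest(cohort, rho, seed=stage_seed(config.seed, "retest"))
    else:
        cohort = load_cohort(config.cohort)
    counts["subjects"] = cohort.n_subjects

    manifest: dict[str, Any] = {
        "msnkit_version": __version__,
        "seed": config.seed,
        "config": {
            k: (str(v) if isinstance(v, (Path,)) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "cohort"
        },
        "stages": {},
    }

    models = [FEATURE_SETS[m] for m in config.models]
    densities = list(config.densities)

    # --- analyses ---------------------------------------------------------
    try:
        if "intermodel" in config.analyses:
            if len(models) < 2:
                raise ValueError("intermodel analysis needs at least two models")
            records, summary = run_intermodel(cohort, densities, tuple(models))
            outputs.append(_write_csv(records, out_dir / "intermodel_records.csv"))
            outputs.append(_write_csv(summary, out_dir / "intermodel_summary.csv"))
            strengths, effects = graph_strength_table(cohort, models, densities)
            outputs.append(_write_csv(strengths, out_dir / "graph_strength.csv"))
            outputs.append(_write_csv(effects, out_dir / "strength_effect_sizes.csv"))
            counts["intermodel_records"] = len(records)

        if "retest" in config.analyses:
            if any(s.retest_features is None for s in cohort.subjects):
                raise ValueError(
                    "retest analysis requested but the cohort has no retest session"
                )
            records, summary = run_test_retest(cohort, models, densities)
            outputs.append(_write_csv(records, out_dir / "retest_records.csv"))
            outputs.append(_write_csv(summary, out_dir / "retest_summary.csv"))
            counts["retest_records"] = len(records)

        if "group" in config.analyses:
            for model in models:
                records, summary = run_subject_vs_group(cohort, model, densities)
                outputs.append(
                    _write_csv(records, out_dir / f"group_records_{model.name}.csv")
                )
                outputs.append(
                    _write_csv(summary, out_dir / f"group_summary_{model.name}.csv")
                )
                counts[f"group_records_{model.name}"] = len(records)
            # group network at the largest density, for inspection
            d = max(densities)
            nets = [
                threshold_density(subject_msn(s, models[0]), d) for s in cohort.subjects
            ]
            grp = build_group_network(nets, models[0].name, d)
            outputs.append(
                write_matrix(
                    grp.weights,
                    out_dir / f"group_network_{models[0].name}_d{int(d * 100):02d}.tsv",
                    cohort.region_labels,
                )
            )

        if "predict" in config.analyses:
            counts.update(
                _run_predict(config, cohort, out_dir, outputs)
            )
    except ValueError as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    manifest["stages"] = counts
    manifest["outputs"] = {
        str(p.relative_to(out_dir)): _sha256(p) for p in sorted(outputs)
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_predict(
    config: RunConfig,
    cohort: SyntheticCohort,
    out_dir: Path,
    outputs: list[Path],
) -> dict[str, int]:
    """PLS prediction stage: predictor assembly, CV selection, bootstrap."""
    model = FEATURE_SETS[config.predict_model]
    d = config.predict_density
    mats = []
    for s in cohort.subjects:
        net = threshold_density(subject_msn(s, model), d)
        if config.predict_metric == "strength":
            mats.append(nodal_strength(net))
        elif config.predict_metric == "degree":
            mats.append(net.binary.sum(axis=1))
        elif config.predict_metric == "normalized_strength":
            deg = net.binary.sum(axis=1)
            mats.append(np.where(deg > 0, nodal_strength(net) / np.maximum(deg, 1), 0.0))
        else:
            raise ValueError(f"unknown predictor metric {config.predict_metric!r}")
    X_raw = np.stack(mats)  # subjects x nodes

    age = np.array([s.age for s in cohort.subjects])
    sex = np.array([s.sex for s in cohort.subjects])
    X = residualize_confounds(X_raw, age, sex)

    if config.predict_outcome == "cogcomp":
        y = np.array([s.cog_comp for s in cohort.subjects])
    elif config.predict_outcome == "ef":
        ef = np.stack([s.ef_scores for s in cohort.subjects])
        y = ef_summary(ef)
    else:
        raise ValueError(f"unknown outcome {config.predict_outcome!r}")
    if np.isnan(y).any():
        raise ValueError("missing cognitive outcome values")

    result = pls_cv_select(
        X,
        y,
        c_max=config.predict_c_max,
        n_instances=config.predict_instances,
        k=config.predict_folds,
        seed=stage_seed(config.seed, "predict"),
        stratified=config.predict_stratified,
        n_bins=config.predict_bins,
    )
    sel = pd.DataFrame(
        {
            "components": list(result.selection_counts),
            "count": list(result.selection_counts.values()),
        }
    )
    outputs.append(_write_csv(sel, out_dir / "pls_selection_counts.csv"))
    curve = pd.DataFrame(
        {"components": np.arange(result.c_max + 1), "mean_q2": result.q2_curve}
    )
    outputs.append(_write_csv(curve, out_dir / "pls_q2_curve.csv"))

    if result.chosen_c > 0:
        weights = bootstrap_weights(
            X,
            y,
            result.chosen_c,
            n_boot=config.predict_n_boot,
            seed=stage_seed(config.seed, "predict") + 1,
            region_labels=list(cohort.region_labels),
        )
        outputs.append(_write_csv(weights, out_dir / "pls_bootstrap_weights.csv"))
        logger.info("predict: retained %d components", result.chosen_c)
    else:
        logger.info("predict: zero components retained; no model built")
    return {"pls_chosen_c": result.chosen_c}
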