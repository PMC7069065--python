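"""Synthetic cohorts of parcellated cortical morphometry.

The generator emulates the statistical structure the downstream analyses
assume, so that the whole pipeline is testable without restricted MRI data:

* a shared cohort-level regional structure (a low-rank loading matrix common
  to all subjects) plus subject-specific deviations — subjects therefore
  resemble the group mean, the regime real MSN cohorts show;
* modality-structured measurement noise: features derived from the same MRI
  modality (7 T1w, 1 T2w, 2 DWI) share a noise component, so dropping a
  modality genuinely removes information and the 10- vs 8- vs 7-feature model
  hierarchy is testable;
* per-feature affine rescaling to raw units spanning orders of magnitude
  (gray-matter volume ~10^3 mm^3, mean diffusivity ~10^-3 mm^2/s), the
  heterogeneity that z-scoring must neutralize;
* optional retest sessions with a tunable test-retest reliability rho, and
  cognitive scores with tunable coupling beta to the network's true nodal
  strengths (beta = 0 gives cognition independent of the brain measures).

Everything is deterministic under the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    MSN10,
    FeatureSetSpec,
    FeatureTable,
    dk68_atlas,
    read_covariates,
    read_feature_table,
    write_feature_table,
)
from .network import build_msn, nodal_strength, zscore_features

__all__ = [
    "CohortConfig",
    "Subject",
    "SyntheticCohort",
    "DEFAULT_SCALES",
    "generate_cohort",
    "generate_retest",
    "generate_cognition",
    "write_cohort",
    "load_cohort",
]

#: Per-feature (offset, scale) pairs emulating raw FreeSurfer/DWI units.
#: Chosen so raw features span ~6 orders of magnitude: volumes ~10^3,
#: surface area ~10^2, thickness ~10^0, curvatures ~10^-1, MD ~10^-3.
DEFAULT_SCALES: dict[str, tuple[float, float]] = {
    "CT": (2.5, 0.3),
    "SA": (700.0, 150.0),
    "GM": (3000.0, 400.0),
    "MC": (0.13, 0.03),
    "GC": (0.25, 0.08),
    "FI": (2.0, 0.8),
    "CI": (0.35, 0.12),
    "T1T2": (1.4, 0.15),
    "FA": (0.25, 0.05),
    "MD": (8e-4, 1e-4),
}

#: Default noise SD per MRI modality, on the standardized latent scale.
DEFAULT_MODALITY_NOISE: dict[str, float] = {"T1w": 0.35, "T2w": 0.45, "DWI": 0.55}


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a synthetic cohort."""

    n_subjects: int = 50
    n_regions: int = 68
    feature_spec: FeatureSetSpec = MSN10
    n_latent: int = 6
    modality_noise: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODALITY_NOISE)
    )
    subject_sd: float = 0.5
    scale_vector: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCALES)
    )
    retest_reliability: float = 0.85
    behavior_effect: float = 0.0
    behavior_noise_sd: float = 1.0
    ef_loadings: tuple[float, float, float] = (0.8, 0.8, 0.8)
    age_range: tuple[float, float] = (22.0, 36.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if self.n_regions < 3:
            raise ValueError(f"n_regions must be >= 3, got {self.n_regions}")
        if self.n_latent < 1:
            raise ValueError(f"n_latent must be >= 1, got {self.n_latent}")
        if self.subject_sd < 0:
            raise ValueError(f"subject_sd must be >= 0, got {self.subject_sd}")
        if not (0 <= self.retest_reliability <= 1):
            raise ValueError(
                f"retest_reliability must be in [0, 1], got {self.retest_reliability}"
            )
        if self.behavior_effect < 0:
            raise ValueError(f"behavior_effect must be >= 0, got {self.behavior_effect}")
        for m, sd in self.modality_noise.items():
            if sd < 0:
                raise ValueError(f"modality_noise[{m!r}] must be >= 0, got {sd}")
        missing = [f for f in self.feature_spec.features if f not in self.scale_vector]
        if missing:
            raise ValueError(f"scale_vector missing entries for features: {missing}")


@dataclass
class Subject:
    subject_id: str
    age: float
    sex: str  # "F" or "M"
    features: FeatureTable
    retest_features: FeatureTable | None = None
    cog_comp: float = np.nan
    ef_scores: np.ndarray | None = None
    # standardized latent deviation (signal-free stochastic part), pre-rescale;
    # kept so retest sessions can share it
    latent_noise: np.ndarray | None = None


@dataclass
class SyntheticCohort:
    subjects: list[Subject]
    region_labels: tuple[str, ...]
    feature_labels: tuple[str, ...]
    config: CohortConfig
    signal: np.ndarray | None = None  # shared regions x features structure
    true_strengths: np.ndarray | None = None  # subjects x regions, set by generate_cognition
    driver_nodes: np.ndarray | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def feature_array(self, session: str = "test") -> np.ndarray:
        """Stack feature matrices into (n_subjects, n_regions, n_features)."""
        tables = []
        for s in self.subjects:
            t = s.features if session == "test" else s.retest_features
            if t is None:
                raise ValueError(f"subject {s.subject_id} has no {session!r} session")
            tables.append(t.values)
        return np.stack(tables)


def _region_labels(n_regions: int) -> tuple[str, ...]:
    if n_regions == 68:
        return dk68_atlas().region_labels
    return tuple(f"region_{i:03d}" for i in range(n_regions))


def _draw_latent_noise(
    rng: np.random.Generator, config: CohortConfig
) -> np.ndarray:
    """One subject's stochastic deviation on the standardized latent scale.

    Subject-specific iid deviations plus a per-modality regional component
    shared by all features of that modality.
    """
    spec = config.feature_spec
    R, F = config.n_regions, spec.n_features
    noise = config.subject_sd * rng.normal(size=(R, F))
    modalities = sorted(set(spec.modality_of[f] for f in spec.features))
    for m in modalities:
        u = rng.normal(size=R)
        sd = config.modality_noise.get(m, 0.0)
        for fi, f in enumerate(spec.features):
            if spec.modality_of[f] == m:
                noise[:, fi] += sd * u
    return noise


def _apply_scale(latent: np.ndarray, config: CohortConfig) -> np.ndarray:
    offsets = np.array([config.scale_vector[f][0] for f in config.feature_spec.features])
    scales = np.array([config.scale_vector[f][1] for f in config.feature_spec.features])
    return offsets + scales * latent


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort of parcellated morphometry tables plus covariates.

    Each subject's regions x features matrix is: shared low-rank regional
    signal (loading matrix times per-feature latent weights, standardized per
    feature) + subject deviation + modality-shared noise, affinely rescaled to
    raw units.  Bit-identical under the same config (seed included).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    spec = config.feature_spec
    R, F, q = config.n_regions, spec.n_features, config.n_latent

    loadings = rng.normal(size=(R, q))
    feat_weights = rng.normal(size=(q, F))
    signal = loadings @ feat_weights
    # standardize the shared structure per feature so noise SDs are on a known scale
    signal = (signal - signal.mean(axis=0)) / signal.std(axis=0, ddof=1)

    region_labels = _region_labels(R)
    ages = rng.uniform(config.age_range[0], config.age_range[1], size=config.n_subjects)
    sexes = rng.choice(np.array(["F", "M"]), size=config.n_subjects)

    subjects = []
    for i in range(config.n_subjects):
        latent_noise = _draw_latent_noise(rng, config)
        raw = _apply_scale(signal + latent_noise, config)
        sid = f"sub-{i + 1:04d}"
        subjects.append(
            Subject(
                subject_id=sid,
                age=float(ages[i]),
                sex=str(sexes[i]),
                features=FeatureTable(
                    subject_id=sid,
                    session="test",
                    values=raw,
                    region_labels=region_labels,
                    feature_labels=spec.features,
                ),
                latent_noise=latent_noise,
            )
        )

    cohort = SyntheticCohort(
        subjects=subjects,
        region_labels=region_labels,
        feature_labels=spec.features,
        config=config,
        signal=signal,
    )
    # default cognition at the configured coupling; regenerate with
    # generate_cognition() to change beta without touching the morphometry
    generate_cognition(
        cohort,
        beta=config.behavior_effect,
        noise_sd=config.behavior_noise_sd,
        seed=config.seed + 1_000_003,
    )
    return cohort


def generate_retest(cohort: SyntheticCohort, rho: float, seed: int) -> SyntheticCohort:
    """Fill retest sessions with cell-wise test-retest reliability rho.

    The retest stochastic part is rho * (session-1 deviation) +
    sqrt(1 - rho^2) * (a fresh deviation with the same modality structure), so
    the across-subject correlation of every (region, feature) cell between
    sessions is rho in the population.  rho = 1 reproduces session 1 exactly.
    """
    if not (0 <= rho <= 1):
        raise ValueError(f"retest reliability must be in [0, 1], got {rho}")
    rng = np.random.default_rng(seed)
    config = cohort.config
    for s in cohort.subjects:
        if s.latent_noise is None or cohort.signal is None:
            raise ValueError(
                f"subject {s.subject_id}: retest generation requires the generative "
                "internals; cohorts loaded from disk cannot be extended"
            )
        fresh = _draw_latent_noise(rng, config)
        retest_noise = rho * s.latent_noise + np.sqrt(1 - rho**2) * fresh
        raw = _apply_scale(cohort.signal + retest_noise, config)
        s.retest_features = FeatureTable(
            subject_id=s.subject_id,
            session="retest",
            values=raw,
            region_labels=cohort.region_labels,
            feature_labels=cohort.feature_labels,
        )
    return cohort


def generate_cognition(
    cohort: SyntheticCohort,
    beta: float,
    noise_sd: float = 1.0,
    seed: int = 0,
    n_driver_nodes: int | None = None,
) -> SyntheticCohort:
    """Attach cognitive scores with coupling beta to true nodal strength.

    The composite score is beta times the standardized projection of each
    subject's (unthresholded) MSN nodal-strength profile onto a fixed random
    regional contrast, plus Gaussian noise.  ``n_driver_nodes`` restricts the
    contrast to a sparse set of regions (for signal-recovery studies); by
    default the contrast is dense.  beta = 0 yields cognition independent of
    every network measure.  The three executive-function subtests load on one
    latent factor plus independent noise.
    """
    if beta < 0:
        raise ValueError(f"behavior effect must be >= 0, got {beta}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    R = len(cohort.region_labels)

    strengths = np.stack(
        [nodal_strength(build_msn(zscore_features(s.features))) for s in cohort.subjects]
    )
    cohort.true_strengths = strengths

    contrast = np.zeros(R)
    if n_driver_nodes is not None:
        nodes = rng.choice(R, size=n_driver_nodes, replace=False)
        contrast[nodes] = rng.normal(size=n_driver_nodes)
        # keep drivers well away from zero so "driving node" is well defined
        contrast[nodes] += np.sign(contrast[nodes])
        cohort.driver_nodes = np.sort(nodes)
    else:
        contrast = rng.normal(size=R)
        cohort.driver_nodes = None

    proj = strengths @ contrast
    sd = proj.std(ddof=1)
    zproj = (proj - proj.mean()) / sd if sd > 0 else np.zeros_like(proj)
    cog = beta * zproj + rng.normal(0, noise_sd, size=cohort.n_subjects)

    lam = np.asarray(cohort.config.ef_loadings, dtype=float)
    g = rng.normal(size=cohort.n_subjects)
    ef = lam * g[:, None] + np.sqrt(1 - lam**2) * rng.normal(size=(cohort.n_subjects, 3))

    for i, s in enumerate(cohort.subjects):
        s.cog_comp = float(cog[i])
        s.ef_scores = ef[i]
    return cohort


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write per-subject per-session TSV tables + covariates CSV + config JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.subjects:
        write_feature_table(s.features, out_dir / f"{s.subject_id}_test.tsv")
        sessions = [("test", s)]
        if s.retest_features is not None:
            write_feature_table(s.retest_features, out_dir / f"{s.subject_id}_retest.tsv")
            sessions.append(("retest", s))
        for session, subj in sessions:
            ef = subj.ef_scores if subj.ef_scores is not None else [np.nan] * 3
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "session": session,
                    "age": subj.age,
                    "sex": subj.sex,
                    "cog_comp": subj.cog_comp,
                    "ef1": ef[0],
                    "ef2": ef[1],
                    "ef3": ef[2],
                }
            )
    pd.DataFrame(rows).to_csv(out_dir / "covariates.csv", index=False)
    cfg = {
        "n_subjects": cohort.config.n_subjects,
        "n_regions": cohort.config.n_regions,
        "feature_spec": cohort.config.feature_spec.name,
        "n_latent": cohort.config.n_latent,
        "modality_noise": dict(cohort.config.modality_noise),
        "subject_sd": cohort.config.subject_sd,
        "retest_reliability": cohort.config.retest_reliability,
        "behavior_effect": cohort.config.behavior_effect,
        "behavior_noise_sd": cohort.config.behavior_noise_sd,
        "age_range": list(cohort.config.age_range),
        "seed": cohort.config.seed,
    }
    (out_dir / "config.json").write_text(json.dumps(cfg, indent=2))
    return out_dir


def load_cohort(
    in_dir: str | Path, spec: FeatureSetSpec = MSN10
) -> SyntheticCohort:
    """Load a cohort written by :func:`write_cohort` (generative internals absent)."""
    in_dir = Path(in_dir)
    cov = read_covariates(in_dir / "covariates.csv")
    cfg_path = in_dir / "config.json"
    config = CohortConfig()
    if cfg_path.exists():
        raw = json.loads(cfg_path.read_text())
        config = replace(
            config,
            n_subjects=raw.get("n_subjects", config.n_subjects),
            n_regions=raw.get("n_regions", config.n_regions),
            seed=raw.get("seed", config.seed),
        )
    test_rows = cov[cov["session"] == "test"]
    subjects = []
    region_labels: tuple[str, ...] | None = None
    for _, row in test_rows.iterrows():
        sid = str(row["subject_id"])
        atlas = None
        if config.n_regions != 68:
            from .io import RegionAtlas

            atlas = RegionAtlas(_region_labels(config.n_regions))
        table = read_feature_table(
            in_dir / f"{sid}_test.tsv", atlas=atlas, spec=spec, subject_id=sid
        )
        retest_path = in_dir / f"{sid}_retest.tsv"
        retest = (
            read_feature_table(
                retest_path, atlas=atlas, spec=spec, subject_id=sid, session="retest"
            )
            if retest_path.exists()
            else None
        )
        region_labels = table.region_labels
        ef = np.array([row.get("ef1", np.nan), row.get("ef2", np.nan), row.get("ef3", np.nan)])
        subjects.append(
            Subject(
                subject_id=sid,
                age=float(row["age"]),
                sex=str(row["sex"]),
                features=table,
                retest_features=retest,
                cog_comp=float(row.get("cog_comp", np.nan)),
                ef_scores=ef,
            )
        )
    if not subjects:
        raise ValueError(f"no subjects found in {in_dir}")
    return SyntheticCohort(
        subjects=subjects,
        region_labels=region_labels or (),
        feature_labels=spec.features,
        config=config,
    )
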