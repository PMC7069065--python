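"""Reliability studies over a cohort of MSNs.

Three analyses, each across a density grid:

* intermodel — every subject's full 10-feature MSN is the reference and is
  compared hierarchically against the 8-feature and the 7-feature MSN
  (10-vs-8 and 10-vs-7 only; the reduced models are never compared to each
  other);
* test-retest — each subject's session-1 MSN of a given model is compared to
  the retest-session MSN of the same model;
* subject-vs-group — each subject's thresholded MSN is compared to the group
  network, the element-wise mean of all subjects' thresholded matrices (the
  subject is not excluded from the mean).

Summaries follow the M +/- SD reporting convention per contrast x density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FeatureSetSpec, MSN10, MSN8, MSN7, subset_features
from .network import (
    DEFAULT_DENSITIES,
    MSNMatrix,
    ThresholdedMSN,
    build_msn,
    graph_strength,
    threshold_density,
    zscore_features,
)
from .similarity import SimilarityRecord, compare_networks, paired_effect_size
from .synthetic import SyntheticCohort

logger = logging.getLogger(__name__)

__all__ = [
    "GroupNetwork",
    "subject_msn",
    "records_to_frame",
    "summarize_records",
    "run_intermodel",
    "run_test_retest",
    "build_group_network",
    "run_subject_vs_group",
    "graph_strength_table",
]


@dataclass
class GroupNetwork:
    """Group-average network: mean of subjects' thresholded weighted matrices."""

    model: str
    density: float
    weights: np.ndarray


def subject_msn(subject, model: FeatureSetSpec, session: str = "test") -> MSNMatrix:
    """Build one subject's MSN for a given feature model and session."""
    table = subject.features if session == "test" else subject.retest_features
    if table is None:
        raise ValueError(f"subject {subject.subject_id} has no {session!r} session")
    sub = subset_features(table, model)
    return build_msn(
        zscore_features(sub),
        subject_id=subject.subject_id,
        model=model.name,
        region_labels=table.region_labels,
    )


def records_to_frame(records: Sequence[SimilarityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "pair": [f"{r.pair[0]}_vs_{r.pair[1]}" for r in records],
            "density": [r.density for r in records],
            "r_all": [r.r_all for r in records],
            "r_nonzero": [r.r_nonzero for r in records],
            "mantel_r": [r.mantel_r for r in records],
            "prop_replicated": [r.prop_replicated for r in records],
        }
    )


def summarize_records(frame: pd.DataFrame, analysis: str) -> pd.DataFrame:
    """Long-format M +/- SD summary per contrast x density x statistic."""
    stats = ["r_all", "r_nonzero", "mantel_r", "prop_replicated"]
    rows = []
    for (pair, density), grp in frame.groupby(["pair", "density"], sort=True):
        for stat in stats:
            vals = grp[stat].to_numpy()
            rows.append(
                {
                    "analysis": analysis,
                    "contrast": pair,
                    "density": density,
                    "statistic": stat,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "n": len(vals),
                }
            )
    return pd.DataFrame(rows)


def _thresholded(
    cohort: SyntheticCohort,
    models: Sequence[FeatureSetSpec],
    densities: Sequence[float],
    session: str = "test",
) -> dict[str, dict[str, dict[float, ThresholdedMSN]]]:
    """model -> subject_id -> density -> ThresholdedMSN, skipping bad subjects."""
    out: dict[str, dict[str, dict[float, ThresholdedMSN]]] = {m.name: {} for m in models}
    for s in cohort.subjects:
        for m in models:
            try:
                msn = subject_msn(s, m, session=session)
            except ValueError as exc:
                logger.warning("skipping %s (%s, %s): %s", s.subject_id, m.name, session, exc)
                continue
            out[m.name][s.subject_id] = {d: threshold_density(msn, d) for d in densities}
    return out


def run_intermodel(
    cohort: SyntheticCohort,
    densities: Sequence[float] = DEFAULT_DENSITIES,
    models: tuple[FeatureSetSpec, FeatureSetSpec, FeatureSetSpec] = (MSN10, MSN8, MSN7),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hierarchical intermodel comparison: full model vs each reduced model.

    Returns (per-subject records, M +/- SD summary).  Subjects missing any
    model are skipped with a warning; n in the summary reflects that.
    """
    reference, *reduced = models
    nets = _thresholded(cohort, models, densities)
    records: list[SimilarityRecord] = []
    for s in cohort.subjects:
        if any(s.subject_id not in nets[m.name] for m in models):
            logger.warning("subject %s missing a model; skipped", s.subject_id)
            continue
        for red in reduced:
            for d in densities:
                records.append(
                    compare_networks(
                        nets[reference.name][s.subject_id][d],
                        nets[red.name][s.subject_id][d],
                        subject_id=s.subject_id,
                        pair=(reference.name, red.name),
                    )
                )
    frame = records_to_frame(records)
    return frame, summarize_records(frame, "intermodel")


def run_test_retest(
    cohort: SyntheticCohort,
    models: Sequence[FeatureSetSpec] = (MSN10, MSN8, MSN7),
    densities: Sequence[float] = DEFAULT_DENSITIES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Session-1 vs retest comparison of the same model, per subject."""
    records: list[SimilarityRecord] = []
    for s in cohort.subjects:
        if s.retest_features is None:
            logger.warning("subject %s has no retest session; skipped", s.subject_id)
            continue
        for m in models:
            test = subject_msn(s, m, session="test")
            retest = subject_msn(s, m, session="retest")
            for d in densities:
                records.append(
                    compare_networks(
                        threshold_density(test, d),
                        threshold_density(retest, d),
                        subject_id=s.subject_id,
                        pair=(f"{m.name}-test", f"{m.name}-retest"),
                    )
                )
    frame = records_to_frame(records)
    return frame, summarize_records(frame, "retest")


def build_group_network(
    nets: Sequence[ThresholdedMSN] | Sequence[np.ndarray],
    model: str = "",
    density: float = np.nan,
) -> GroupNetwork:
    """Element-wise mean of the cohort's (thresholded) weighted matrices.

    Note the mean of density-d networks is generally not itself at density d.
    """
    mats = [n.weighted if isinstance(n, ThresholdedMSN) else np.asarray(n) for n in nets]
    if not mats:
        raise ValueError("no networks to average")
    return GroupNetwork(model=model, density=density, weights=np.mean(mats, axis=0))


def run_subject_vs_group(
    cohort: SyntheticCohort,
    model: FeatureSetSpec = MSN10,
    densities: Sequence[float] = DEFAULT_DENSITIES,
    average: str = "thresholded",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare each subject's thresholded MSN with the group-average network.

    ``average="thresholded"`` (default) averages the subjects' thresholded
    weighted matrices at each density; ``average="raw"`` averages the raw MSNs
    and thresholds the mean.  For the binary replication statistic the group
    matrix is re-thresholded to density d so both networks have equal edge
    counts; the subject network is the reference.
    """
    if average not in ("thresholded", "raw"):
        raise ValueError(f"average must be 'thresholded' or 'raw', got {average!r}")
    msns = {s.subject_id: subject_msn(s, model) for s in cohort.subjects}
    records: list[SimilarityRecord] = []
    for d in densities:
        thresholded = {sid: threshold_density(m, d) for sid, m in msns.items()}
        if average == "thresholded":
            group = build_group_network(list(thresholded.values()), model.name, d)
        else:
            group = build_group_network(
                [m.weights for m in msns.values()], model.name, d
            )
        group_thr = threshold_density(
            MSNMatrix("group", model.name, group.weights), d
        )
        for sid, net in thresholded.items():
            records.append(
                compare_networks(
                    net, group_thr, subject_id=sid, pair=(model.name, f"{model.name}-group")
                )
            )
    frame = records_to_frame(records)
    return frame, summarize_records(frame, "group")


def graph_strength_table(
    cohort: SyntheticCohort,
    models: Sequence[FeatureSetSpec] = (MSN10, MSN8, MSN7),
    densities: Sequence[float] = DEFAULT_DENSITIES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject graph strength by model x density, plus paired effect sizes.

    Effect sizes contrast the full model against each reduced model (paired t
    over subjects, r = sqrt(t^2/(t^2+df))); p values are not reported.
    """
    nets = _thresholded(cohort, models, densities)
    rows = []
    for m in models:
        for sid, by_d in nets[m.name].items():
            for d, net in by_d.items():
                rows.append(
                    {
                        "subject_id": sid,
                        "model": m.name,
                        "density": d,
                        "graph_strength": graph_strength(net),
                    }
                )
    strengths = pd.DataFrame(rows)
    reference, *reduced = models
    effect_rows = []
    for red in reduced:
        for d in densities:
            a = strengths.query("model == @reference.name and density == @d").set_index(
                "subject_id"
            )["graph_strength"]
            b = strengths.query("model == @red.name and density == @d").set_index(
                "subject_id"
            )["graph_strength"]
            common = a.index.intersection(b.index)
            rec = paired_effect_size(
                a.loc[common].to_numpy(),
                b.loc[common].to_numpy(),
                contrast=f"{reference.name}_vs_{red.name}",
                density=d,
            )
            effect_rows.append(
                {
                    "contrast": rec.contrast,
                    "density": rec.density,
                    "t": rec.t,
                    "df": rec.df,
                    "r_effect": rec.r_effect,
                }
            )
    return strengths, pd.DataFrame(effect_rows)
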