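"""End-to-end pipeline: simulate a cohort, embed, align, model, analyze.

``run_pipeline`` chains every stage on a fully synthetic cohort and writes
all artifacts plus a machine-readable summary JSON.  Each stage is also
usable on its own through the module functions, so any slice of the chain
can run on external data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import AlignedScales, gpa_align_1d, normalize_scales
from .behavior import behavior_ols, classify_movement, gaze_area, mean_abs_velocity
from .design import StimulusSet, TrialList, build_trial_list, default_stimulus_set, write_trial_list_csv
from .embedding import CVReport, PerceptualScale, cv_dimension_select, soe_embed, triplet_accuracy
from .io import RunConfig, config_hash, write_aligned_scales_csv, write_responses_csv, write_scale_json
from .models import LosoReport, fit_exponential_by_add, loso_evaluate
from .observer import (
    ObserverProfile,
    ScaleParams,
    TripletResponse,
    default_cohort_profiles,
    materialize_scale,
    simulate_gaze,
    simulate_head_trace,
    simulate_responses,
)

logger = logging.getLogger("palscale")

__all__ = ["SubjectResult", "PipelineResult", "run_pipeline", "simulate_cohort", "scale_table"]


@dataclass(frozen=True)
class SubjectResult:
    """Everything derived for one synthetic subject."""

    subject_id: str
    profile: ObserverProfile
    responses: list[TripletResponse]
    cv_report: CVReport
    scale: PerceptualScale
    catch_accuracy: float
    mean_velocity: tuple[float, float, float]
    movement_class: str
    gaze_area_pct: float


@dataclass(frozen=True)
class PipelineResult:
    stimuli: StimulusSet
    trial_lists: list[TrialList]
    subjects: list[SubjectResult]
    aligned: AlignedScales
    loso: LosoReport
    ols_table: pd.DataFrame
    summary: dict


def _catch_accuracy(responses: Sequence[TripletResponse], catch_index: int) -> float:
    """Fraction of catch trials where the exaggerated lens was NOT chosen."""
    catch = [r for r in responses if r.trial.is_catch]
    if not catch:
        return float("nan")
    return float(np.mean([r.winner != catch_index for r in catch]))


def simulate_cohort(
    config: RunConfig,
) -> tuple[StimulusSet, list[TrialList], list[ObserverProfile], list[list[TripletResponse]]]:
    """Build per-subject designs and all subjects' simulated responses.

    Each subject receives their own seeded trial list: trial order and the
    anchor assigned to each 3-subset are randomized per subject, so the
    constraint sets differ across the cohort (which also decorrelates the
    embedding error the average-observer scale inherits).
    """
    stimuli = default_stimulus_set()
    trial_lists = [
        build_trial_list(
            stimuli, catch_fraction=config.catch_fraction, seed=config.seed + 1000 * i
        )
        for i in range(config.n_subjects)
    ]
    profiles = default_cohort_profiles(
        config.n_subjects, sigma=config.sigma, lapse=config.lapse, seed=config.seed + 1
    )
    responses = [
        simulate_responses(tl, materialize_scale(ScaleParams(), tl.extended_lenses), p)
        for tl, p in zip(trial_lists, profiles)
    ]
    return stimuli, trial_lists, profiles, responses


def scale_table(
    aligned: AlignedScales, stimuli: StimulusSet, subject_ids: Sequence[str]
) -> pd.DataFrame:
    """Long-format table (subject, sph, add, value, is_reference)."""
    rows = []
    for sid, values in zip(subject_ids, aligned.values):
        for lens, v in zip(stimuli, values):
            rows.append(
                {
                    "subject": sid,
                    "sph": lens.sph,
                    "add": lens.add,
                    "value": float(v),
                    "is_reference": lens.is_reference,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full chain and write artifacts under ``out_dir``.

    Stages: simulate responses -> per-subject CV dimension selection and
    embedding -> GPA alignment -> 0/1 normalization -> exponential fits and
    LOSO model comparison -> head/gaze behavior analysis -> OLS of scale on
    lens power and behavior.  Fully reproducible from the config seed.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"{config_hash(config)}_seed{config.seed}"

    stage = "simulate"
    try:
        stimuli, trial_lists, profiles, all_responses = simulate_cohort(config)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    n_stimuli = len(stimuli)
    catch_index = n_stimuli
    subjects: list[SubjectResult] = []
    for i, (trial_list, profile, responses) in enumerate(
        zip(trial_lists, profiles, all_responses)
    ):
        sid = f"S{i + 1:02d}"
        write_trial_list_csv(trial_list, out / f"trials_{sid}_{tag}.csv")
        stage = f"embed[{sid}]"
        try:
            core = [r for r in responses if not r.trial.is_catch]
            cv = cv_dimension_select(
                core,
                n_stimuli,
                dims=config.dims,
                folds=config.folds,
                seed=config.seed + i,
                margin=config.margin,
                restarts=config.cv_restarts,
            )
            fit = soe_embed(
                core,
                n_stimuli,
                dim=cv.selected_dim,
                margin=config.margin,
                restarts=config.restarts,
                seed=config.seed + i,
            )
            stage = f"behavior[{sid}]"
            trace = simulate_head_trace(
                profile, duration=config.head_duration, rate=config.head_rate
            )
            velocity = mean_abs_velocity(trace)
            gaze = simulate_gaze(profile, n=config.gaze_samples)
            area = gaze_area(
                gaze, bandwidth=config.gaze_bandwidth, mass=config.gaze_mass
            )
            subjects.append(
                SubjectResult(
                    subject_id=sid,
                    profile=profile,
                    responses=responses,
                    cv_report=cv,
                    scale=fit,
                    catch_accuracy=_catch_accuracy(responses, catch_index),
                    mean_velocity=velocity,
                    movement_class=classify_movement(
                        velocity, config.movement_threshold
                    ),
                    gaze_area_pct=area,
                )
            )
            write_responses_csv(responses, trial_list, sid, out / f"responses_{sid}_{tag}.csv")
            write_scale_json(fit, stimuli, out / f"scale_{sid}_{tag}.json")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "align"
    try:
        # alignment needs 1-D values; a subject whose CV picked d > 1 is
        # re-embedded in 1-D for the cross-subject scale
        raw = []
        for s in subjects:
            if s.scale.dim == 1:
                raw.append(s.scale.values_1d)
            else:
                core = [r for r in s.responses if not r.trial.is_catch]
                refit = soe_embed(
                    core, n_stimuli, dim=1, margin=config.margin,
                    restarts=config.restarts, seed=config.seed,
                )
                raw.append(refit.values_1d)
        aligned = gpa_align_1d(np.vstack(raw))
        aligned = normalize_scales(
            aligned,
            zero_stimulus=stimuli.reference_index,
            unit_stimulus=stimuli.index_of(5.0, 3.0),
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    subject_ids = [s.subject_id for s in subjects]
    table = scale_table(aligned, stimuli, subject_ids)

    stage = "fit-models"
    try:
        exp_fits = fit_exponential_by_add(table[~table["is_reference"]])
        loso = (
            loso_evaluate(table, families=config.families, seed=config.seed)
            if len(subjects) >= 2
            else LosoReport(table=pd.DataFrame(columns=["subject", "family", "r2"]))
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "behavior-ols"
    try:
        behavior_frame = table.merge(
            pd.DataFrame(
                {
                    "subject": subject_ids,
                    "movement_class": [s.movement_class for s in subjects],
                    "gaze_area": [s.gaze_area_pct for s in subjects],
                }
            ),
            on="subject",
        )
        ols = behavior_ols(behavior_frame)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "n_trials": len(trial_lists[0]),
        "n_catch": trial_lists[0].n_catch,
        "subjects": {
            s.subject_id: {
                "selected_dim": s.cv_report.selected_dim,
                "accuracy": s.scale.accuracy,
                "catch_accuracy": s.catch_accuracy,
                "movement_class": s.movement_class,
                "gaze_area_pct": s.gaze_area_pct,
                "mean_velocity": list(s.mean_velocity),
            }
            for s in subjects
        },
        "exponential_fits": {
            str(add): {"a": f.a, "b": f.b, "c": f.c, "rss": f.rss}
            for add, f in exp_fits.items()
        },
        "loso_median_r2": {
            fam: loso.median_r2(fam) for fam in config.families if len(subjects) >= 2
        },
        "ols": ols.to_dict(orient="records"),
    }

    write_aligned_scales_csv(aligned.values, stimuli, subject_ids, out / f"scales_aligned_{tag}.csv")
    loso.table.to_csv(out / f"loso_{tag}.csv", index=False, float_format="%.9f")
    ols.to_csv(out / f"ols_{tag}.csv", index=False, float_format="%.9f")
    (out / f"summary_{tag}.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    logger.info("pipeline complete: %d subjects, artifacts in %s", len(subjects), out)

    return PipelineResult(
        stimuli=stimuli,
        trial_lists=trial_lists,
        subjects=subjects,
        aligned=aligned,
        loso=loso,
        ols_table=ols,
        summary=summary,
    )
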