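"""Readers/writers for the pipeline's CSV/JSON artifacts and the run config.

No domain-standard container exists for triplet psychophysics, so the
schemas are plain CSV with a header row (seeds recorded as ``#`` comment
lines) and JSON for nested results.  Writers use fixed float formatting so
that write(load(x)) round-trips byte-identically for canonical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import StimulusSet, TrialList, TripletTrial
from .embedding import PerceptualScale
from .observer import GazeSamples, HeadTrace, TripletResponse
from .stimuli import LensSpec

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "write_responses_csv",
    "load_responses",
    "write_head_trace_csv",
    "load_head_trace",
    "write_gaze_csv",
    "load_gaze",
    "write_scale_json",
    "write_aligned_scales_csv",
]

logger = logging.getLogger("palscale")

RESPONSE_COLUMNS = ["subject_id", "trial_index", "pair_id", "answer", "is_catch", "n_repeats"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run; every seed is explicit."""

    n_subjects: int = 13
    seed: int = 0
    catch_fraction: float = 0.2
    sigma: float = 0.05
    lapse: float = 0.0
    dims: tuple[int, ...] = (1, 2, 3)
    margin: float = 1.0
    restarts: int = 10
    cv_restarts: int = 3
    folds: int = 10
    n_bootstrap: int = 0
    movement_threshold: float = 10.0
    gaze_bandwidth: float = 2.0
    gaze_mass: float = 0.95
    gaze_samples: int = 2000
    head_duration: float = 30.0
    head_rate: float = 90.0
    families: tuple[str, ...] = ("linear", "exponential", "tree-ensemble")
    out_dir: str = "palscale_run"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("config needs at least one subject")
        if not (0 <= self.catch_fraction < 1):
            raise ValueError("catch_fraction must lie in [0, 1)")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config, rejecting unknown keys."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("dims", "families"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return RunConfig(**data)


def config_hash(config: RunConfig) -> str:
    """Short stable hash identifying a configuration."""
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# --- triplet responses -----------------------------------------------------


def write_responses_csv(
    responses: Sequence[TripletResponse],
    trial_list: TrialList,
    subject_id: str,
    path: str | Path,
) -> None:
    trial_to_index = {id(t): i for i, t in enumerate(trial_list.trials)}
    lines = [f"# seed={trial_list.seed}", ",".join(RESPONSE_COLUMNS)]
    for r in responses:
        idx = trial_to_index[id(r.trial)]
        lines.append(
            f"{subject_id},{idx},{r.trial.pair_id},{r.answer},"
            f"{int(r.trial.is_catch)},{r.n_repeats}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_responses(
    path: str | Path, trial_list: TrialList
) -> list[TripletResponse]:
    """Load a response CSV; malformed rows are reported with line numbers."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    header_line = None
    rows: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if header_line is None:
            header_line = line
            header = [c.strip() for c in line.split(",")]
            missing = set(RESPONSE_COLUMNS) - set(header)
            if missing:
                raise ValueError(
                    f"{path}: missing response columns {sorted(missing)}"
                )
            col = {name: header.index(name) for name in RESPONSE_COLUMNS}
            continue
        rows.append((lineno, line))
    if header_line is None:
        raise ValueError(f"{path}: no header row found")
    if not rows:
        warnings.warn(f"{path}: response file contains a header but no rows", stacklevel=2)
        return []

    responses = []
    for lineno, line in rows:
        parts = [p.strip() for p in line.split(",")]
        try:
            trial_index = int(parts[col["trial_index"]])
            answer = int(parts[col["answer"]])
            n_repeats = int(parts[col["n_repeats"]])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
        if answer not in (1, 2):
            raise ValueError(f"{path}:{lineno}: answer must be 1 or 2, got {answer}")
        if not (0 <= trial_index < len(trial_list.trials)):
            raise ValueError(f"{path}:{lineno}: trial index {trial_index} out of range")
        responses.append(
            TripletResponse(trial_list.trials[trial_index], answer, n_repeats)
        )
    return responses


# --- tracking streams ------------------------------------------------------


def write_head_trace_csv(trace: HeadTrace, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "t": trace.t,
            "qw": trace.quaternions[:, 0],
            "qx": trace.quaternions[:, 1],
            "qy": trace.quaternions[:, 2],
            "qz": trace.quaternions[:, 3],
        }
    )
    frame.to_csv(path, index=False, float_format="%.9f")


def load_head_trace(path: str | Path) -> HeadTrace:
    frame = pd.read_csv(path)
    missing = {"t", "qw", "qx", "qy", "qz"} - set(frame.columns)
    if missing:
        raise ValueError(f"head-trace CSV missing columns: {sorted(missing)}")
    quats = frame[["qw", "qx", "qy", "qz"]].to_numpy()
    # re-normalize away the round-trip quantization from fixed-precision CSV
    quats = quats / np.linalg.norm(quats, axis=1, keepdims=True)
    return HeadTrace(t=frame["t"].to_numpy(), quaternions=quats)


def write_gaze_csv(gaze: GazeSamples, path: str | Path) -> None:
    frame = pd.DataFrame(
        np.column_stack([gaze.t, gaze.left, gaze.right]),
        columns=["t", "lx", "ly", "lz", "rx", "ry", "rz"],
    )
    frame.to_csv(path, index=False, float_format="%.9f")


def load_gaze(path: str | Path) -> GazeSamples:
    frame = pd.read_csv(path)
    missing = {"t", "lx", "ly", "lz", "rx", "ry", "rz"} - set(frame.columns)
    if missing:
        raise ValueError(f"gaze CSV missing columns: {sorted(missing)}")
    return GazeSamples(
        t=frame["t"].to_numpy(),
        left=frame[["lx", "ly", "lz"]].to_numpy(),
        right=frame[["rx", "ry", "rz"]].to_numpy(),
    )


# --- scales ----------------------------------------------------------------


def write_scale_json(
    scale: PerceptualScale,
    stimuli: StimulusSet,
    path: str | Path,
    extra: dict[str, Any] | None = None,
) -> None:
    from . import __version__

    payload = {
        "stimuli": [
            {"sph": l.sph, "add": l.add, "is_reference": l.is_reference}
            for l in stimuli
        ],
        "coordinates": scale.coordinates.tolist(),
        "dim": scale.dim,
        "loss": scale.loss,
        "accuracy": scale.accuracy,
        "seed": scale.seed,
        "software_version": __version__,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_aligned_scales_csv(
    values: np.ndarray,
    stimuli: StimulusSet,
    subject_ids: Sequence[str],
    path: str | Path,
) -> None:
    rows = []
    for sid, row in zip(subject_ids, values):
        for lens, v in zip(stimuli, row):
            rows.append({"subject_id": sid, "sph": lens.sph, "add": lens.add, "value": v})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9f")
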