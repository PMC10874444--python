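"""Stimulus sets and triplet trial lists.

The triplet paradigm presents three lenses per trial — choice 1, anchor,
choice 2 — and asks which choice appears more similar to the anchor.  A full
design presents every unordered 3-subset of the stimulus set twice, with the
roles of choice 1 and choice 2 swapped in the second presentation, plus a
fraction of trivial "catch" trials containing an exaggeratedly distorted
lens whose correct answer is unambiguous.

For the canonical 11-condition stimulus grid (Sph in {-5, -2.5, 0, 2.5, 5}
crossed with Add in {1, 3}, plus the undistorted reference) and a catch
fraction of 0.2 this yields 2*C(11,3) = 330 core trials and 83 catch trials,
413 in total per subject.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stimuli import DEFAULT_CATCH_LENS, REFERENCE_LENS, LensSpec

__all__ = [
    "StimulusSet",
    "TripletTrial",
    "TrialList",
    "build_stimulus_set",
    "build_trial_list",
    "default_stimulus_set",
    "write_trial_list_csv",
    "read_trial_list_csv",
]

SPH_GRID = (-5.0, -2.5, 0.0, 2.5, 5.0)
ADD_GRID = (1.0, 3.0)


@dataclass(frozen=True)
class StimulusSet:
    """Ordered, duplicate-free list of lens conditions.

    When the undistorted reference is present it occupies index 0.
    """

    lenses: tuple[LensSpec, ...]

    def __post_init__(self) -> None:
        keys = [(l.sph, l.add) for l in self.lenses]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (sph, add) pairs in stimulus set")
        refs = [l for l in self.lenses if l.is_reference]
        if len(refs) > 1:
            raise ValueError("at most one reference condition allowed")
        if refs and not self.lenses[0].is_reference:
            raise ValueError("the reference condition must be at index 0")

    def __len__(self) -> int:
        return len(self.lenses)

    def __getitem__(self, i: int) -> LensSpec:
        return self.lenses[i]

    def __iter__(self):
        return iter(self.lenses)

    def index_of(self, sph: float, add: float) -> int:
        for i, l in enumerate(self.lenses):
            if l.sph == sph and l.add == add:
                return i
        raise KeyError(f"no stimulus with sph={sph}, add={add}")

    @property
    def reference_index(self) -> int | None:
        return 0 if self.lenses and self.lenses[0].is_reference else None


@dataclass(frozen=True)
class TripletTrial:
    """One presentation: indices of choice1, anchor, choice2 into the
    extended stimulus list (the catch lens sits at index ``n_stimuli``)."""

    choice1: int
    anchor: int
    choice2: int
    is_catch: bool
    pair_id: int

    def __post_init__(self) -> None:
        if len({self.choice1, self.anchor, self.choice2}) != 3:
            raise ValueError("triplet indices must be pairwise distinct")


@dataclass(frozen=True)
class TrialList:
    """Randomized sequence of triplet trials for one subject.

    ``stimuli`` holds the core conditions; catch trials reference the
    ``catch_lens`` through the extended index ``len(stimuli)``.
    """

    trials: tuple[TripletTrial, ...]
    stimuli: StimulusSet
    catch_lens: LensSpec
    seed: int
    n_core: int
    n_catch: int

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def extended_lenses(self) -> tuple[LensSpec, ...]:
        return tuple(self.stimuli) + (self.catch_lens,)

    def core_trials(self) -> list[TripletTrial]:
        return [t for t in self.trials if not t.is_catch]

    def catch_trials(self) -> list[TripletTrial]:
        return [t for t in self.trials if t.is_catch]


def build_stimulus_set(
    sph_values: Iterable[float] = SPH_GRID,
    add_values: Iterable[float] = ADD_GRID,
    include_reference: bool = True,
) -> StimulusSet:
    """Cross ``sph_values`` with ``add_values``; optionally prepend the reference.

    The canonical defaults give the 11-condition set: 5 far powers times
    2 addition powers plus the undistorted reference.
    """
    sph_values = list(sph_values)
    add_values = list(add_values)
    pairs = [(s, a) for s in sph_values for a in add_values]
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate (sph, add) pairs requested")
    lenses: list[LensSpec] = [REFERENCE_LENS] if include_reference else []
    for s, a in pairs:
        lens = LensSpec(float(s), float(a))
        if include_reference and (s, a) == (0.0, 0.0):
            continue
        lenses.append(lens)
    return StimulusSet(tuple(lenses))


def default_stimulus_set() -> StimulusSet:
    """The 11-condition stimulus set used throughout."""
    return build_stimulus_set()


def _catch_companions(stimuli: StimulusSet) -> list[int]:
    """Indices of mildly/undistorted conditions eligible for catch trials."""
    out = [i for i, l in enumerate(stimuli) if l.is_reference or abs(l.sph) <= 2.5]
    if len(out) < 2:
        raise ValueError("stimulus set has too few mild conditions for catch trials")
    return out


def build_trial_list(
    stimuli: StimulusSet,
    catch_fraction: float = 0.2,
    catch_lens: LensSpec = DEFAULT_CATCH_LENS,
    seed: int = 0,
) -> TrialList:
    """Build a full randomized trial list for one subject.

    Core trials: every unordered 3-subset of ``stimuli`` appears exactly
    twice; the anchor for a subset is drawn uniformly at random (seeded) and
    shared by both presentations, which swap choice 1 and choice 2 and share
    a ``pair_id``.  Catch trials place the exaggerated ``catch_lens`` as one
    of the choices (never the anchor) against mildly or undistorted
    companions, so the correct answer is objective.  The catch count is
    ``ceil(n_core * f / (1 - f))``, making catches a fraction ``f`` of the
    total up to rounding.  The final order is a seeded permutation.
    """
    n = len(stimuli)
    if n < 3:
        raise ValueError(f"need at least 3 stimuli, got {n}")
    if not (0 <= catch_fraction < 1):
        raise ValueError(f"catch fraction must be in [0, 1), got {catch_fraction}")

    rng = np.random.default_rng(seed)
    trials: list[TripletTrial] = []
    for pair_id, combo in enumerate(itertools.combinations(range(n), 3)):
        anchor = int(rng.choice(combo))
        a, b = [i for i in combo if i != anchor]
        trials.append(TripletTrial(a, anchor, b, is_catch=False, pair_id=pair_id))
        trials.append(TripletTrial(b, anchor, a, is_catch=False, pair_id=pair_id))
    n_core = len(trials)

    n_catch = math.ceil(n_core * catch_fraction / (1.0 - catch_fraction)) if catch_fraction else 0
    catch_index = n  # extended index of the catch lens
    companions = _catch_companions(stimuli) if n_catch else []
    next_pair = n_core // 2
    for k in range(n_catch):
        anchor, other = rng.choice(companions, size=2, replace=False)
        if rng.random() < 0.5:
            trial = TripletTrial(catch_index, int(anchor), int(other), True, next_pair + k)
        else:
            trial = TripletTrial(int(other), int(anchor), catch_index, True, next_pair + k)
        trials.append(trial)

    order = rng.permutation(len(trials))
    return TrialList(
        trials=tuple(trials[i] for i in order),
        stimuli=stimuli,
        catch_lens=catch_lens,
        seed=int(seed),
        n_core=n_core,
        n_catch=n_catch,
    )


_TRIAL_COLUMNS = [
    "trial_index",
    "pair_id",
    "choice1_sph",
    "choice1_add",
    "anchor_sph",
    "anchor_add",
    "choice2_sph",
    "choice2_add",
    "is_catch",
]


def write_trial_list_csv(trial_list: TrialList, path: str | Path) -> None:
    """Write a trial list as CSV (lens parameters per slot, seed as a # comment)."""
    lenses = trial_list.extended_lenses
    rows = []
    for idx, t in enumerate(trial_list.trials):
        c1, an, c2 = lenses[t.choice1], lenses[t.anchor], lenses[t.choice2]
        rows.append(
            [idx, t.pair_id, c1.sph, c1.add, an.sph, an.add, c2.sph, c2.add, int(t.is_catch)]
        )
    frame = pd.DataFrame(rows, columns=_TRIAL_COLUMNS)
    buf = StringIO()
    buf.write(f"# seed={trial_list.seed}\n")
    frame.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_trial_list_csv(
    path: str | Path,
    stimuli: StimulusSet,
    catch_lens: LensSpec = DEFAULT_CATCH_LENS,
) -> TrialList:
    """Read a trial-list CSV written by :func:`write_trial_list_csv`."""
    text = Path(path).read_text().splitlines()
    seed = 0
    for line in text:
        if line.startswith("# seed="):
            seed = int(line.split("=", 1)[1])
    frame = pd.read_csv(path, comment="#")
    missing = set(_TRIAL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trial-list CSV missing columns: {sorted(missing)}")

    catch_index = len(stimuli)

    def resolve(sph: float, add: float) -> int:
        if (sph, add) == (catch_lens.sph, catch_lens.add):
            return catch_index
        return stimuli.index_of(sph, add)

    trials = []
    n_core = n_catch = 0
    for _, row in frame.iterrows():
        t = TripletTrial(
            resolve(row.choice1_sph, row.choice1_add),
            resolve(row.anchor_sph, row.anchor_add),
            resolve(row.choice2_sph, row.choice2_add),
            bool(row.is_catch),
            int(row.pair_id),
        )
        trials.append(t)
        if t.is_catch:
            n_catch += 1
        else:
            n_core += 1
    return TrialList(tuple(trials), stimuli, catch_lens, seed, n_core, n_catch)
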