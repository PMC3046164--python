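"""Experimental schedule construction and end-to-end session runs.

A session per condition comprises three phases: calibration trials (a fixed
numerosity shown with a feedback numeral), practice trials (random
numerosities, no feedback), and the experiment proper (every numerosity
repeated a fixed number of times, in a seeded random order).  The runner
renders each trial's stimulus via the stimulus module and, when a simulated
observer is supplied, logs its responses into an estimate table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import observer as obs
from .geometry import DisplayGeometry
from .stimulus import (Layout, make_background, motion_path,
                       render_first_order, render_second_order, sample_layout,
                       save_frames)

log = logging.getLogger(__name__)

PHASES = ("calibration", "practice", "proper")


@dataclass(frozen=True)
class SessionConfig:
    numerosity_min: int = 10
    numerosity_max: int = 30
    reps: int = 6
    calibration_trials: int = 3
    calibration_numerosity: int = 20
    practice_trials: int = 40
    conditions: tuple[str, ...] = ("first_order", "second_order")
    practice_per_condition: bool = True
    interleave_conditions: bool = False
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.numerosity_max < self.numerosity_min:
            raise ValueError("empty numerosity range")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    @property
    def numerosities(self) -> list[int]:
        return list(range(self.numerosity_min, self.numerosity_max + 1))


@dataclass(frozen=True)
class Trial:
    index: int
    phase: str
    condition: str
    numerosity: int
    layout_seed: int
    texture_seed: int
    feedback: bool


@dataclass(frozen=True)
class TrialSchedule:
    trials: tuple[Trial, ...]
    config: SessionConfig

    def proper_counts(self) -> pd.Series:
        df = self.to_frame()
        proper = df[df["phase"] == "proper"]
        return proper.groupby(["condition", "numerosity"]).size()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(t) for t in self.trials])

    def to_json(self) -> str:
        return json.dumps({
            "config": dataclasses.asdict(self.config),
            "trials": [dataclasses.asdict(t) for t in self.trials],
        }, indent=2, default=list)


def _derive_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2 ** 31 - 1))


def build_schedule(cfg: SessionConfig | None = None,
                   seed: int | None = None) -> TrialSchedule:
    """Build the full trial schedule, deterministic given the seed.

    Per condition block: ``calibration_trials`` trials at the calibration
    numerosity with feedback on, then ``practice_trials`` trials with
    numerosities sampled uniformly (with replacement) from the range with
    feedback off, then a seeded uniform permutation of the reps x range
    proper trials.  Each trial carries its own derived layout and texture
    seeds so layout draws are independent across trials.
    """
    cfg = cfg or SessionConfig()
    rng = np.random.default_rng(cfg.master_seed if seed is None else seed)
    nums = cfg.numerosities
    trials: list[Trial] = []

    def add(phase: str, condition: str, numerosity: int, feedback: bool):
        trials.append(Trial(
            index=len(trials), phase=phase, condition=condition,
            numerosity=int(numerosity), layout_seed=_derive_seed(rng),
            texture_seed=_derive_seed(rng), feedback=feedback))

    def add_calibration(cond: str) -> None:
        for _ in range(cfg.calibration_trials):
            add("calibration", cond, cfg.calibration_numerosity, True)

    def add_practice(cond: str | None) -> None:
        for _ in range(cfg.practice_trials):
            c = cond if cond is not None else str(rng.choice(cfg.conditions))
            add("practice", c, int(rng.choice(nums)), False)

    if cfg.interleave_conditions:
        # all calibration (+ practice) first, then one shuffled proper block
        for cond in cfg.conditions:
            add_calibration(cond)
            if cfg.practice_per_condition:
                add_practice(cond)
        if not cfg.practice_per_condition:
            add_practice(None)
        proper = [(cond, int(n)) for cond in cfg.conditions
                  for n in np.repeat(nums, cfg.reps)]
        for i in rng.permutation(len(proper)):
            add("proper", proper[i][0], proper[i][1], False)
    else:
        if not cfg.practice_per_condition:
            for cond in cfg.conditions:
                add_calibration(cond)
            add_practice(None)
        for cond in cfg.conditions:
            if cfg.practice_per_condition:
                add_calibration(cond)
                add_practice(cond)
            for n in rng.permutation(np.repeat(nums, cfg.reps)):
                add("proper", cond, int(n), False)
    return TrialSchedule(trials=tuple(trials), config=cfg)


def run_session(cfg: SessionConfig | None = None,
                observer_params: obs.ObserverParams | None = None,
                out_dir: str | Path | None = None,
                geometry: DisplayGeometry | None = None,
                subject: int = 1,
                fast: bool = True,
                save_images: bool = False) -> pd.DataFrame:
    """Run one simulated session end to end.

    For every scheduled trial a layout is sampled (and, unless ``fast``,
    the frame sequence is rendered).  If ``observer_params`` is given,
    responses are simulated; otherwise the estimate column is left empty.
    With ``out_dir`` the schedule (JSON), per-trial layouts (JSON), the
    estimate table (CSV) and optionally the frames (PNG) are written.

    Returns the estimate table with an extra ``phase`` column.
    """
    cfg = cfg or SessionConfig()
    geometry = geometry or DisplayGeometry()
    schedule = build_schedule(cfg)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "schedule.json").write_text(schedule.to_json())
    resp_rng = np.random.default_rng(
        np.random.SeedSequence([cfg.master_seed, subject, 7]))
    path = motion_path(geometry)
    rows = []
    layouts: dict[int, Layout] = {}
    trial_in_cond: dict[str, int] = {}
    for trial in schedule.trials:
        layout = sample_layout(trial.numerosity, geometry, trial.layout_seed)
        layouts[trial.index] = layout
        if not fast:
            background = make_background(geometry, trial.texture_seed)
            if trial.condition == "first_order":
                seq = render_first_order(layout, path, background, geometry)
            else:
                seq = render_second_order(layout, path, background, geometry)
            if out is not None and save_images:
                save_frames(seq, out / f"trial_{trial.index:04d}",
                            geometry=geometry)
        estimate = np.nan
        if observer_params is not None:
            estimate = obs.draw_estimate(trial.numerosity, trial.condition,
                                         observer_params, resp_rng)
        trial_in_cond[trial.condition] = trial_in_cond.get(trial.condition,
                                                           0) + 1
        rows.append((subject, trial.condition, trial.numerosity,
                     layout.mean_height_deg, estimate,
                     trial_in_cond[trial.condition], trial.phase))
        if trial.index % 50 == 0:
            log.info("trial %d/%d (%s, n=%d)", trial.index,
                     len(schedule.trials), trial.condition, trial.numerosity)
    table = pd.DataFrame(rows, columns=obs.TABLE_COLUMNS + ["phase"])
    if out is not None:
        (out / "layouts.json").write_text(json.dumps(
            {str(i): json.loads(l.to_json()) for i, l in layouts.items()}))
        table.to_csv(out / "estimates.csv", index=False)
    return table
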