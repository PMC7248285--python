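"""Synthetic observers and cohorts.

Simulates trial-level anger/fear categorisation data by inverting the choice
models: an observer with known parameters responds "anger" on each trial with
probability ``Phi(w_eff u + b_eff)``.  Default cohorts mirror the study
design this package analyses — 21 control-like observers generated under the
perceptual-sensitivity model (Threat+ slope above Threat−) and 15
patient-like observers under the decision-bias model (criterion shifted
towards "anger" under direct gaze and towards "fear" under averted gaze) —
each completing the full 600-trial balanced schedule.  Ground-truth
parameters are retained for every simulated subject so that model and
parameter recovery can be measured end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import design as design_mod
from .behavior import score_trials
from .models import (
    MODEL_IDS,
    PARAM_NAMES,
    SLOPE_NAMES,
    ObserverParameters,
    _p_anger_vec,
    prepare_trials,
)

__all__ = [
    "DesignConfig",
    "GroupConfig",
    "CohortDataset",
    "sample_observer",
    "simulate_trials",
    "generate_cohort",
    "load_config",
]


@dataclass(frozen=True)
class DesignConfig:
    """Design of each simulated subject's session."""

    n_identities: int = 20
    n_levels: int = 7
    n_blocks: int = 5


@dataclass(frozen=True)
class GroupConfig:
    """Generative description of one simulated group.

    ``means``/``sds`` give the between-subject distribution of each parameter
    of ``generative_model``; observers are drawn from a normal truncated at 0
    for slopes.  An sd of 0 plants the mean exactly.
    """

    label: str
    n_subjects: int
    generative_model: str
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.generative_model not in MODEL_IDS:
            raise ValueError(f"unknown model {self.generative_model!r}")
        names = set(PARAM_NAMES[self.generative_model])
        if set(self.means) != names or set(self.sds) != names:
            raise ValueError(
                f"means/sds must cover exactly {sorted(names)} for "
                f"{self.generative_model}"
            )
        if any(s < 0 for s in self.sds.values()):
            raise ValueError("sds must be >= 0")


#: Default control-like group: sensitivity model with a Threat+ advantage.
DEFAULT_CONTROL = GroupConfig(
    label="control",
    n_subjects=21,
    generative_model="M1",
    means={"w_plus": 1.2, "w_minus": 0.9, "b": 0.0},
    sds={"w_plus": 0.2, "w_minus": 0.2, "b": 0.2},
)

#: Default patient-like group: gaze-conditioned bias, anger-ward under
#: direct gaze and fear-ward under averted gaze.
DEFAULT_PATIENT = GroupConfig(
    label="patient",
    n_subjects=15,
    generative_model="M2",
    means={"w": 1.0, "b_direct": 0.3, "b_averted": -0.3},
    sds={"w": 0.2, "b_direct": 0.2, "b_averted": 0.2},
)


def sample_observer(config: GroupConfig, rng: np.random.Generator) -> ObserverParameters:
    """Draw one observer's parameters from the group distribution.

    Slopes are drawn from a normal truncated at zero; criteria from an
    untruncated normal.  A zero sd returns the mean exactly.
    """
    values: dict[str, float] = {}
    for name in PARAM_NAMES[config.generative_model]:
        mean = float(config.means[name])
        sd = float(config.sds[name])
        if sd == 0.0:
            values[name] = mean
        elif name in SLOPE_NAMES:
            a = (0.0 - mean) / sd
            values[name] = float(
                stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng)
            )
        else:
            values[name] = float(rng.normal(mean, sd))
    return ObserverParameters(model_id=config.generative_model, **values)


def simulate_trials(
    params: ObserverParameters,
    schedule: design_mod.TrialSchedule | pd.DataFrame,
    rng: np.random.Generator,
    n_levels: int | None = None,
) -> pd.DataFrame:
    """Simulate one observer's responses to a trial schedule.

    Each response is Bernoulli in the model's anger probability; correctness
    is scored against the stimulus emotion (NaN for neutral trials).
    """
    trials = (
        schedule.trials if isinstance(schedule, design_mod.TrialSchedule) else schedule
    )
    out = trials.copy()
    arrs = prepare_trials(out, n_levels=n_levels)
    p = _p_anger_vec(params.to_vector(), params.model_id, arrs)
    anger = rng.random(len(p)) < p
    out["response"] = np.where(anger, "anger", "fear")
    return score_trials(out)


@dataclass(frozen=True)
class CohortDataset:
    """Simulated multi-group dataset with its ground-truth ledger."""

    trials: pd.DataFrame
    truth: pd.DataFrame
    design: DesignConfig
    master_seed: int

    def group_trials(self, label: str) -> pd.DataFrame:
        return self.trials[self.trials["group"] == label].reset_index(drop=True)

    def to_csv(self, trials_path, truth_path=None) -> None:
        self.trials.to_csv(trials_path, index=False)
        if truth_path is not None:
            self.truth.to_csv(truth_path, index=False)


def _subject_rng(master_seed: int, group_index: int, subject_index: int) -> np.random.Generator:
    # Stable per-subject substreams: entropy keyed on (seed, group, subject)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(group_index, subject_index))
    )


def generate_cohort(
    groups: list[GroupConfig] | None = None,
    design: DesignConfig | None = None,
    master_seed: int = 0,
) -> CohortDataset:
    """Simulate a full cohort over the balanced design.

    Defaults reproduce the study-like configuration: 21 controls under the
    sensitivity model and 15 patients under the bias model, 600 trials each.
    Every subject gets an independently shuffled schedule and an independent
    random substream derived from the master seed, so the dataset is exactly
    reproducible.
    """
    groups = groups if groups is not None else [DEFAULT_CONTROL, DEFAULT_PATIENT]
    design = design or DesignConfig()
    stimuli = design_mod.enumerate_stimuli(design.n_identities, design.n_levels)

    trial_frames = []
    truth_rows = []
    subject_counter = 0
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise ValueError(f"group labels must be unique, got {labels}")
    for g_idx, group in enumerate(groups):
        for s_idx in range(group.n_subjects):
            rng = _subject_rng(master_seed, g_idx, s_idx)
            subject_id = f"{group.label}-{s_idx + 1:02d}"
            params = sample_observer(group, rng)
            schedule_seed = int(rng.integers(0, 2**31 - 1))
            schedule = design_mod.build_schedule(
                stimuli,
                design.n_blocks,
                seed=schedule_seed,
                subject_index=subject_counter,
            )
            sim = simulate_trials(params, schedule, rng, n_levels=design.n_levels)
            sim.insert(0, "group", group.label)
            sim.insert(0, "subject", subject_id)
            trial_frames.append(sim)
            row = {
                "subject": subject_id,
                "group": group.label,
                "model": group.generative_model,
            }
            row.update(params.as_dict())
            truth_rows.append(row)
            subject_counter += 1

    return CohortDataset(
        trials=pd.concat(trial_frames, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
        design=design,
        master_seed=master_seed,
    )


def load_config(path) -> tuple[list[GroupConfig], DesignConfig, int]:
    """Load a cohort configuration from a YAML (or JSON) file.

    Layout::

        seed: 0
        design: {identities: 20, levels: 7, blocks: 5}
        groups:
          - label: control
            n_subjects: 21
            model: M1
            means: {w_plus: 1.2, w_minus: 0.9, b: 0.0}
            sds: {w_plus: 0.2, w_minus: 0.2, b: 0.2}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    d = cfg.get("design", {})
    design = DesignConfig(
        n_identities=int(d.get("identities", 20)),
        n_levels=int(d.get("levels", 7)),
        n_blocks=int(d.get("blocks", 5)),
    )
    groups = [
        GroupConfig(
            label=g["label"],
            n_subjects=int(g["n_subjects"]),
            generative_model=g["model"],
            means={k: float(v) for k, v in g["means"].items()},
            sds={k: float(v) for k, v in g["sds"].items()},
        )
        for g in cfg.get("groups", [])
    ]
    return groups, design, int(cfg.get("seed", 0))
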