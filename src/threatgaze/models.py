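"""Probit choice models of gaze-contextualised emotion categorisation.

Each trial presents a face whose emotion evidence is coded on a signed axis
``u``: positive for anger morphs, negative for fear morphs, 0 for neutral,
with magnitude ``morph_level / n_levels``.  An observer responds "anger" with
probability

    P(anger) = Phi(w_eff * u + b_eff)

where ``Phi`` is the standard normal CDF.  The three models differ in what
gaze direction modulates:

* ``M1`` (perceptual sensitivity): the slope depends on threat congruence —
  ``w_plus`` for Threat+ stimuli (anger/direct or fear/averted), ``w_minus``
  for Threat−, their mean for neutral; a single criterion ``b``.
* ``M2`` (decision bias): a single slope ``w``; the criterion depends on gaze
  — ``b_direct`` under direct gaze, ``b_averted`` under averted gaze, so even
  neutral faces are answered asymmetrically.
* ``M3`` (combined): both mechanisms at once (4 free parameters).

M1 and M2 have 3 free parameters each, so their maximised log-likelihoods are
directly comparable as model evidence without a complexity penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr

from .design import StimulusCondition

__all__ = [
    "MODEL_IDS",
    "PARAM_NAMES",
    "P_FLOOR",
    "ObserverParameters",
    "ModelFit",
    "FitSettings",
    "signed_evidence",
    "threat_congruence",
    "prepare_trials",
    "p_choose_anger",
    "negative_log_likelihood",
    "fit_ml",
]

MODEL_IDS = ("M1", "M2", "M3")

PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "M1": ("w_plus", "w_minus", "b"),
    "M2": ("w", "b_direct", "b_averted"),
    "M3": ("w_plus", "w_minus", "b_direct", "b_averted"),
}

SLOPE_NAMES = frozenset({"w", "w_plus", "w_minus"})

#: Probability floor applied to every trial likelihood (no lapse parameter;
#: this keeps M1 and M2 at three parameters each while keeping the
#: log-likelihood finite).
P_FLOOR = 1e-6

THREAT_PLUS = "threat_plus"
THREAT_MINUS = "threat_minus"
UNDEFINED = "undefined"


def signed_evidence(emotion: str, morph_level: int, n_levels: int = 7) -> float:
    """Signed emotion evidence in [-1, 1].

    Anger morphs map to ``+morph_level / n_levels``, fear morphs to the
    negative, neutral to exactly 0.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if emotion == "neutral":
        if morph_level != 0:
            raise ValueError("neutral stimuli must have morph_level 0")
        return 0.0
    if not 1 <= morph_level <= n_levels:
        raise ValueError(
            f"morph_level {morph_level} out of range 1..{n_levels} for {emotion}"
        )
    mag = morph_level / n_levels
    if emotion == "anger":
        return mag
    if emotion == "fear":
        return -mag
    raise ValueError(f"unknown emotion {emotion!r}")


def threat_congruence(gaze: str, emotion: str) -> str:
    """Threat congruence of a gaze-emotion combination.

    Threat+ combinations signal self-relevant threat: anger with direct gaze
    (the anger is aimed at the observer) or fear with averted gaze (the feared
    danger is nearby).  Anger/averted and fear/direct are Threat−.  Neutral
    faces are undefined.
    """
    if gaze not in ("direct", "averted"):
        raise ValueError(f"unknown gaze {gaze!r}")
    if emotion == "neutral":
        return UNDEFINED
    if emotion not in ("anger", "fear"):
        raise ValueError(f"unknown emotion {emotion!r}")
    if (gaze == "direct") == (emotion == "anger"):
        return THREAT_PLUS
    return THREAT_MINUS


@dataclass(frozen=True)
class ObserverParameters:
    """Parameter set for one observer under one model.

    Only the fields of the chosen model may be set: M1 uses
    ``(w_plus, w_minus, b)``, M2 ``(w, b_direct, b_averted)``, M3
    ``(w_plus, w_minus, b_direct, b_averted)``.  Slopes must be >= 0;
    positive criteria bias responses towards "anger".
    """

    model_id: str
    w_plus: float | None = None
    w_minus: float | None = None
    b: float | None = None
    w: float | None = None
    b_direct: float | None = None
    b_averted: float | None = None

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model_id {self.model_id!r}")
        required = PARAM_NAMES[self.model_id]
        for name in required:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"{self.model_id} requires parameter {name}")
            if name in SLOPE_NAMES and value < 0:
                raise ValueError(f"slope {name} must be >= 0, got {value}")
        for name in set(PARAM_NAMES["M3"]) | {"w", "b"}:
            if name not in required and getattr(self, name) is not None:
                raise ValueError(
                    f"{name} is not a parameter of {self.model_id}"
                )

    def to_vector(self) -> np.ndarray:
        return np.array(
            [getattr(self, n) for n in PARAM_NAMES[self.model_id]], dtype=float
        )

    @classmethod
    def from_vector(cls, model_id: str, vector: Iterable[float]) -> "ObserverParameters":
        names = PARAM_NAMES[model_id]
        values = [float(v) for v in vector]
        if len(values) != len(names):
            raise ValueError(
                f"{model_id} expects {len(names)} parameters, got {len(values)}"
            )
        return cls(model_id=model_id, **dict(zip(names, values)))

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES[self.model_id]}


# ---------------------------------------------------------------------------
# Vectorised trial representation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialArrays:
    """Numeric view of a trial table used by the likelihood."""

    u: np.ndarray            # signed evidence per trial
    threat_plus: np.ndarray  # boolean
    threat_minus: np.ndarray
    neutral: np.ndarray
    direct: np.ndarray
    response_anger: np.ndarray | None  # None for stimulus-only tables

    def __len__(self) -> int:
        return len(self.u)


def prepare_trials(trials: pd.DataFrame, n_levels: int | None = None) -> TrialArrays:
    """Convert a trial table to the numeric arrays the likelihood consumes.

    Expects columns ``emotion``, ``morph_level``, ``gaze`` and, when responses
    are present, ``response`` with values in {"anger", "fear"}.  ``n_levels``
    defaults to the largest morph level in the table.
    """
    if len(trials) == 0:
        raise ValueError("trial table is empty")
    emotion = trials["emotion"].to_numpy()
    level = trials["morph_level"].to_numpy(dtype=int)
    gaze = trials["gaze"].to_numpy()

    if n_levels is None:
        n_levels = int(level.max()) if level.max() > 0 else 1

    neutral = emotion == "neutral"
    anger = emotion == "anger"
    fear = emotion == "fear"
    if not np.all(neutral | anger | fear):
        bad = sorted(set(emotion) - {"neutral", "anger", "fear"})
        raise ValueError(f"unknown emotions in table: {bad}")
    if np.any(neutral & (level != 0)) or np.any(~neutral & (level == 0)):
        raise ValueError("morph_level must be 0 exactly for neutral trials")
    if np.any(level > n_levels):
        raise ValueError("morph_level exceeds n_levels")

    u = np.where(anger, level, -level) / float(n_levels)
    u[neutral] = 0.0
    direct = gaze == "direct"
    tplus = (~neutral) & (direct == anger)
    tminus = (~neutral) & ~tplus

    response_anger = None
    if "response" in trials.columns:
        resp = trials["response"].to_numpy()
        if not np.all(np.isin(resp, ("anger", "fear"))):
            bad = sorted(set(resp) - {"anger", "fear"})
            raise ValueError(f"unknown responses in table: {bad}")
        response_anger = resp == "anger"

    return TrialArrays(
        u=u,
        threat_plus=tplus,
        threat_minus=tminus,
        neutral=neutral,
        direct=direct,
        response_anger=response_anger,
    )


def _effective_terms(
    theta: np.ndarray, model_id: str, arrs: TrialArrays
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial effective slope and criterion for a parameter vector."""
    if model_id == "M1":
        w_plus, w_minus, b = theta
        w_eff = np.where(
            arrs.threat_plus,
            w_plus,
            np.where(arrs.threat_minus, w_minus, 0.5 * (w_plus + w_minus)),
        )
        b_eff = np.full(len(arrs), b)
    elif model_id == "M2":
        w, b_direct, b_averted = theta
        w_eff = np.full(len(arrs), w)
        b_eff = np.where(arrs.direct, b_direct, b_averted)
    elif model_id == "M3":
        w_plus, w_minus, b_direct, b_averted = theta
        w_eff = np.where(
            arrs.threat_plus,
            w_plus,
            np.where(arrs.threat_minus, w_minus, 0.5 * (w_plus + w_minus)),
        )
        b_eff = np.where(arrs.direct, b_direct, b_averted)
    else:
        raise ValueError(f"unknown model_id {model_id!r}")
    return w_eff, b_eff


def _p_anger_vec(theta: np.ndarray, model_id: str, arrs: TrialArrays) -> np.ndarray:
    w_eff, b_eff = _effective_terms(theta, model_id, arrs)
    p = ndtr(w_eff * arrs.u + b_eff)
    return np.clip(p, P_FLOOR, 1.0 - P_FLOOR)


def p_choose_anger(
    params: ObserverParameters,
    stimulus: StimulusCondition,
    n_levels: int = 7,
) -> float:
    """Probability of an "anger" response to one stimulus, floored away from 0/1."""
    df = pd.DataFrame(
        {
            "emotion": [stimulus.emotion],
            "morph_level": [stimulus.morph_level],
            "gaze": [stimulus.gaze],
        }
    )
    arrs = prepare_trials(df, n_levels=n_levels)
    return float(_p_anger_vec(params.to_vector(), params.model_id, arrs)[0])


def _nll_and_grad(
    theta: np.ndarray, model_id: str, arrs: TrialArrays
) -> tuple[float, np.ndarray]:
    w_eff, b_eff = _effective_terms(theta, model_id, arrs)
    eta = w_eff * arrs.u + b_eff
    p = np.clip(ndtr(eta), P_FLOOR, 1.0 - P_FLOOR)
    y = arrs.response_anger
    nll = -float(np.sum(np.where(y, np.log(p), np.log1p(-p))))

    # dNLL/d eta, with the floored probability in the denominator
    phi = np.exp(-0.5 * eta * eta) / math.sqrt(2.0 * math.pi)
    g_eta = phi * (p - y) / (p * (1.0 - p))

    u = arrs.u
    if model_id == "M1":
        d_wp = u * (arrs.threat_plus + 0.5 * arrs.neutral)
        d_wm = u * (arrs.threat_minus + 0.5 * arrs.neutral)
        grad = np.array([np.sum(g_eta * d_wp), np.sum(g_eta * d_wm), np.sum(g_eta)])
    elif model_id == "M2":
        grad = np.array(
            [
                np.sum(g_eta * u),
                np.sum(g_eta * arrs.direct),
                np.sum(g_eta * ~arrs.direct),
            ]
        )
    else:  # M3
        d_wp = u * (arrs.threat_plus + 0.5 * arrs.neutral)
        d_wm = u * (arrs.threat_minus + 0.5 * arrs.neutral)
        grad = np.array(
            [
                np.sum(g_eta * d_wp),
                np.sum(g_eta * d_wm),
                np.sum(g_eta * arrs.direct),
                np.sum(g_eta * ~arrs.direct),
            ]
        )
    return nll, grad


def negative_log_likelihood(
    params: ObserverParameters,
    trials: pd.DataFrame | TrialArrays,
    n_levels: int | None = None,
) -> float:
    """Negative log-likelihood (nats) of the observed responses.

    Sums ``-ln P(response_t)`` over all trials, neutral trials included; the
    probability floor keeps the result finite.
    """
    arrs = trials if isinstance(trials, TrialArrays) else prepare_trials(
        trials, n_levels=n_levels
    )
    if arrs.response_anger is None:
        raise ValueError("trial table has no 'response' column")
    p = _p_anger_vec(params.to_vector(), params.model_id, arrs)
    y = arrs.response_anger
    return -float(np.sum(np.where(y, np.log(p), np.log1p(-p))))


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitSettings:
    """Bounds and deterministic start grid for the multi-start fit.

    The slope/criterion start values form a Cartesian grid covering shallow to
    steep psychometric regimes; identical data and settings always reproduce
    the same fit.
    """

    w_max: float = 20.0
    b_max: float = 5.0
    slope_starts: tuple[float, ...] = (0.1, 1.0, 3.0)
    bias_starts: tuple[float, ...] = (-1.0, 0.0, 1.0)
    gtol: float = 1e-8
    max_iter: int = 500


@dataclass(frozen=True)
class ModelFit:
    """Maximum-likelihood fit of one model to one subject's trials."""

    subject_id: str | int
    model_id: str
    parameters: ObserverParameters
    log_likelihood: float
    n_trials: int
    converged: bool
    n_restarts_used: int
    at_bound: bool = False

    @property
    def n_parameters(self) -> int:
        return len(PARAM_NAMES[self.model_id])

    def bic_evidence(self) -> float:
        """BIC-penalised evidence, LL - (k/2) ln n (nats)."""
        return self.log_likelihood - 0.5 * self.n_parameters * math.log(self.n_trials)


def _start_grid(model_id: str, settings: FitSettings) -> list[np.ndarray]:
    names = PARAM_NAMES[model_id]
    axes = [
        settings.slope_starts if n in SLOPE_NAMES else settings.bias_starts
        for n in names
    ]
    grid = np.stack(
        [g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=-1
    )
    return [grid[i] for i in range(len(grid))]


def _bounds(model_id: str, settings: FitSettings) -> list[tuple[float, float]]:
    return [
        (0.0, settings.w_max) if n in SLOPE_NAMES else (-settings.b_max, settings.b_max)
        for n in PARAM_NAMES[model_id]
    ]


def fit_ml(
    trials: pd.DataFrame | TrialArrays,
    model_id: str,
    subject_id: str | int = "subject",
    settings: FitSettings | None = None,
    n_levels: int | None = None,
) -> ModelFit:
    """Fit one model to one subject's trials by bounded multi-start ML.

    Runs L-BFGS-B from every point of the deterministic start grid and keeps
    the best optimum (ties broken by grid order).  Degenerate data (e.g. all
    responses identical) do not raise: the optimum then sits on a parameter
    bound and the fit is flagged ``at_bound``.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    settings = settings or FitSettings()
    arrs = trials if isinstance(trials, TrialArrays) else prepare_trials(
        trials, n_levels=n_levels
    )
    if arrs.response_anger is None:
        raise ValueError("trial table has no 'response' column")

    bounds = _bounds(model_id, settings)
    best: optimize.OptimizeResult | None = None
    any_success = False
    starts = _start_grid(model_id, settings)
    for x0 in starts:
        res = optimize.minimize(
            _nll_and_grad,
            x0,
            args=(model_id, arrs),
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            options={"gtol": settings.gtol, "maxiter": settings.max_iter},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun - 1e-12:
            best = res

    theta = np.asarray(best.x, dtype=float)
    at_bound = any(
        np.isclose(t, lo) or np.isclose(t, hi)
        for t, (lo, hi) in zip(theta, bounds)
        # a slope resting at 0 is a legitimate interior optimum for flat data,
        # but still counts as a bound for diagnostic purposes
    )
    params = ObserverParameters.from_vector(model_id, theta)
    return ModelFit(
        subject_id=subject_id,
        model_id=model_id,
        parameters=params,
        log_likelihood=-float(best.fun),
        n_trials=len(arrs),
        converged=any_success,
        n_restarts_used=len(starts),
        at_bound=at_bound,
    )


def fit_cohort(
    trials: pd.DataFrame,
    model_ids: Iterable[str] = ("M1", "M2"),
    settings: FitSettings | None = None,
    n_levels: int | None = None,
) -> list[ModelFit]:
    """Fit each requested model to every subject in a multi-subject table."""
    fits: list[ModelFit] = []
    for subject_id, sub in trials.groupby("subject", sort=True):
        arrs = prepare_trials(sub, n_levels=n_levels)
        for model_id in model_ids:
            fits.append(
                fit_ml(arrs, model_id, subject_id=subject_id, settings=settings)
            )
    return fits


def fits_to_frame(fits: Iterable[ModelFit]) -> pd.DataFrame:
    """Tabulate fits (one row per subject x model) for CSV export."""
    rows = []
    for f in fits:
        row: dict = {
            "subject": f.subject_id,
            "model": f.model_id,
            "logL": f.log_likelihood,
            "n_trials": f.n_trials,
            "converged": f.converged,
            "at_bound": f.at_bound,
        }
        row.update(f.parameters.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
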