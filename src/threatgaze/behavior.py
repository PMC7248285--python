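"""Accuracy aggregation, exclusion filtering, and the focal contrasts.

Works on trial tables (one row per trial: subject, emotion, morph_level,
gaze, response).  Accuracy is defined on emotion (non-neutral) trials only;
neutral faces have no correct answer.  The scientifically central comparison
is Threat+ versus Threat− accuracy — anger/direct and fear/averted against
anger/averted and fear/direct — which is exactly the 2 (gaze) x 2 (emotion)
within-subject interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import THREAT_MINUS, THREAT_PLUS, UNDEFINED, threat_congruence

__all__ = [
    "TestResult",
    "score_correct",
    "score_trials",
    "accuracy_table",
    "exclusion_filter",
    "threat_contrast",
    "paired_t",
    "interaction_2x2",
    "neutral_gaze_bias",
]


def score_correct(emotion: str, response: str) -> str:
    """Score one trial: 'correct', 'incorrect', or 'undefined' (neutral)."""
    if emotion == "neutral":
        return "undefined"
    if emotion not in ("anger", "fear"):
        raise ValueError(f"unknown emotion {emotion!r}")
    if response not in ("anger", "fear"):
        raise ValueError(f"unknown response {response!r}")
    return "correct" if response == emotion else "incorrect"


def score_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Add a ``correct`` column (1/0, NaN for neutral trials)."""
    out = trials.copy()
    neutral = out["emotion"] == "neutral"
    out["correct"] = np.where(
        neutral, np.nan, (out["emotion"] == out["response"]).astype(float)
    )
    return out


def accuracy_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Proportion correct per subject x emotion x gaze x morph level.

    Neutral trials are excluded.  Returns a tidy frame with columns
    ``subject, emotion, gaze, morph_level, accuracy, n_trials``.
    """
    scored = score_trials(trials)
    emo = scored[scored["emotion"] != "neutral"]
    if len(emo) == 0:
        raise ValueError("no emotion (non-neutral) trials in table")
    grouped = (
        emo.groupby(["subject", "emotion", "gaze", "morph_level"], sort=True)
        ["correct"]
        .agg(accuracy="mean", n_trials="count")
        .reset_index()
    )
    return grouped


def exclusion_filter(
    trials: pd.DataFrame, threshold: float = 0.60
) -> tuple[list, pd.DataFrame]:
    """Apply the overall-accuracy inclusion criterion.

    A subject is retained iff their proportion correct over emotion
    (non-neutral) trials is at least ``threshold`` — the boundary case is
    retained.  Returns the retained subject ids and a per-subject report
    with columns ``subject, n_emotion_trials, accuracy, excluded``.
    """
    scored = score_trials(trials)
    report_rows = []
    retained = []
    for subject, sub in scored.groupby("subject", sort=True):
        emo = sub[sub["emotion"] != "neutral"]
        if len(emo) == 0:
            raise ValueError(f"subject {subject!r} has no emotion trials")
        acc = float(emo["correct"].mean())
        excluded = acc < threshold
        report_rows.append(
            {
                "subject": subject,
                "n_emotion_trials": len(emo),
                "accuracy": acc,
                "excluded": excluded,
            }
        )
        if not excluded:
            retained.append(subject)
    return retained, pd.DataFrame(report_rows)


def _congruence_column(table: pd.DataFrame) -> pd.Series:
    return pd.Series(
        [threat_congruence(g, e) for g, e in zip(table["gaze"], table["emotion"])],
        index=table.index,
    )


def threat_contrast(table: pd.DataFrame) -> pd.Series:
    """Per-subject Threat+ minus Threat− accuracy from an accuracy table.

    Cells (emotion x gaze x morph level) are averaged with equal weight; all
    four gaze-emotion combinations must be present for every subject.
    """
    tab = table.copy()
    tab["congruence"] = _congruence_column(tab)
    tab = tab[tab["congruence"] != UNDEFINED]
    out = {}
    for subject, sub in tab.groupby("subject", sort=True):
        combos = set(zip(sub["emotion"], sub["gaze"]))
        expected = {
            ("anger", "direct"), ("anger", "averted"),
            ("fear", "direct"), ("fear", "averted"),
        }
        missing = expected - combos
        if missing:
            raise ValueError(
                f"subject {subject!r} is missing gaze x emotion cells: "
                f"{sorted(missing)}"
            )
        plus = sub.loc[sub["congruence"] == THREAT_PLUS, "accuracy"].mean()
        minus = sub.loc[sub["congruence"] == THREAT_MINUS, "accuracy"].mean()
        out[subject] = float(plus - minus)
    return pd.Series(out, name="threat_contrast")


@dataclass(frozen=True)
class TestResult:
    """A t-test with paired/within-subject Cohen's d.

    ``cohen_d`` is the mean difference divided by the standard deviation of
    the differences (the within-subject convention).  For the 2x2 interaction
    the equivalent F statistic is ``t**2`` on (1, df) degrees of freedom.
    """

    statistic: float
    df: int
    p_value: float
    tail: str
    cohen_d: float

    @property
    def f_statistic(self) -> float:
        return self.statistic**2


def _t_from_diffs(diffs: np.ndarray, tail: str) -> TestResult:
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    n = len(diffs)
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        raise ZeroDivisionError(
            "zero variance of paired differences; t statistic undefined"
        )
    t = mean / (sd / math.sqrt(n))
    df = n - 1
    if tail == "two":
        p = 2.0 * float(stats.t.sf(abs(t), df))
    else:
        # one-tailed in the direction mean(diff) > 0
        p = float(stats.t.sf(t, df))
    return TestResult(
        statistic=t, df=df, p_value=p, tail=tail, cohen_d=mean / sd
    )


def paired_t(x, y, tail: str = "two") -> TestResult:
    """Paired Student t-test on per-subject values (x - y).

    ``tail="one"`` tests the directional hypothesis mean(x - y) > 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    return _t_from_diffs(x - y, tail)


def interaction_2x2(table: pd.DataFrame, tail: str = "two") -> TestResult:
    """Within-subject gaze x emotion interaction on accuracies.

    Pools each subject's accuracy over morph levels into the four gaze x
    emotion cell means and tests the difference of differences
    ``(anger_direct - anger_averted) - (fear_direct - fear_averted)`` against
    zero with a one-sample t.  For a 2x2 within-subject design this is
    exactly the repeated-measures interaction: F = t^2 on (1, n-1) df.
    """
    cells = (
        table[table["emotion"] != "neutral"]
        .groupby(["subject", "emotion", "gaze"], sort=True)["accuracy"]
        .mean()
        .unstack(["emotion", "gaze"])
    )
    needed = [
        ("anger", "direct"), ("anger", "averted"),
        ("fear", "direct"), ("fear", "averted"),
    ]
    missing = [c for c in needed if c not in cells.columns]
    if missing:
        raise ValueError(f"missing gaze x emotion cells: {missing}")
    dod = (
        cells[("anger", "direct")] - cells[("anger", "averted")]
        - (cells[("fear", "direct")] - cells[("fear", "averted")])
    ).to_numpy(dtype=float)
    return _t_from_diffs(dod, tail)


def neutral_gaze_bias(trials: pd.DataFrame) -> dict:
    """Anger-response rates to neutral faces by gaze direction.

    A gaze-conditioned decision bias announces itself on neutral faces: more
    "anger" responses under direct than averted gaze.  Pools neutral trials
    across subjects and compares the two rates with Fisher's exact test.
    Returns rates, counts, the rate difference, and the two-sided p value.
    """
    neutral = trials[trials["emotion"] == "neutral"]
    if len(neutral) == 0:
        raise ValueError("no neutral trials in table")
    res: dict = {}
    counts = {}
    for gaze in ("direct", "averted"):
        sub = neutral[neutral["gaze"] == gaze]
        if len(sub) == 0:
            raise ValueError(f"no neutral {gaze}-gaze trials")
        k = int((sub["response"] == "anger").sum())
        n = len(sub)
        counts[gaze] = (k, n)
        res[f"anger_rate_{gaze}"] = k / n
        res[f"n_{gaze}"] = n
    (kd, nd), (ka, na) = counts["direct"], counts["averted"]
    table = [[kd, nd - kd], [ka, na - ka]]
    res["rate_difference"] = kd / nd - ka / na
    res["p_value"] = float(stats.fisher_exact(table)[1])
    return res
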