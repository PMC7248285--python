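import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import threatgaze as tg
from threatgaze.design import StimulusCondition, build_schedule, enumerate_stimuli
from threatgaze.models import (
    P_FLOOR,
    FitSettings,
    ObserverParameters,
    negative_log_likelihood,
    p_choose_anger,
    prepare_trials,
    signed_evidence,
    threat_congruence,
)
from threatgaze.simulate import simulate_trials


def random_trials(rng, n, n_levels=7):
    """A random response table spanning all stimulus classes."""
    emotions = rng.choice(["anger", "fear", "neutral"], size=n, p=[0.45, 0.45, 0.1])
    levels = np.where(
        emotions == "neutral", 0, rng.integers(1, n_levels + 1, size=n)
    )
    return pd.DataFrame(
        {
            "emotion": emotions,
            "morph_level": levels,
            "gaze": rng.choice(["direct", "averted"], size=n),
            "response": rng.choice(["anger", "fear"], size=n),
        }
    )


def nll_by_hand(params, trials, n_levels=7):
    """Independent per-trial likelihood summation (scalar loop, scipy CDF)."""
    total = 0.0
    for row in trials.itertuples():
        u = signed_evidence(row.emotion, row.morph_level, n_levels)
        if params.model_id == "M1":
            cong = threat_congruence(row.gaze, row.emotion)
            w = {"threat_plus": params.w_plus, "threat_minus": params.w_minus,
                 "undefined": 0.5 * (params.w_plus + params.w_minus)}[cong]
            b = params.b
        elif params.model_id == "M2":
            w = params.w
            b = params.b_direct if row.gaze == "direct" else params.b_averted
        else:
            cong = threat_congruence(row.gaze, row.emotion)
            w = {"threat_plus": params.w_plus, "threat_minus": params.w_minus,
                 "undefined": 0.5 * (params.w_plus + params.w_minus)}[cong]
            b = params.b_direct if row.gaze == "direct" else params.b_averted
        p = min(max(norm.cdf(w * u + b), P_FLOOR), 1 - P_FLOOR)
        total -= math.log(p if row.response == "anger" else 1 - p)
    return total


class TestSignedEvidence:
    @pytest.mark.parametrize(
        "emotion, level, expected",
        [("neutral", 0, 0.0), ("anger", 7, 1.0), ("fear", 4, -4 / 7)],
    )
    def test_coding(self, emotion, level, expected):
        assert signed_evidence(emotion, level, 7) == pytest.approx(expected)

    def test_neutral_with_nonzero_level_rejected(self):
        with pytest.raises(ValueError):
            signed_evidence("neutral", 2, 7)

    def test_out_of_range_level_rejected(self):
        with pytest.raises(ValueError):
            signed_evidence("anger", 8, 7)


class TestThreatCongruence:
    @pytest.mark.parametrize(
        "gaze, emotion, expected",
        [
            ("direct", "anger", "threat_plus"),
            ("averted", "fear", "threat_plus"),
            ("direct", "fear", "threat_minus"),
            ("averted", "anger", "threat_minus"),
            ("averted", "neutral", "undefined"),
        ],
    )
    def test_mapping(self, gaze, emotion, expected):
        assert threat_congruence(gaze, emotion) == expected


class TestObserverParameters:
    def test_m1_requires_its_parameters(self):
        with pytest.raises(ValueError):
            ObserverParameters("M1", w_plus=1.0, w_minus=1.0)  # missing b

    def test_foreign_parameter_rejected(self):
        with pytest.raises(ValueError):
            ObserverParameters("M1", w_plus=1, w_minus=1, b=0, b_direct=0.5)

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            ObserverParameters("M2", w=-0.5, b_direct=0, b_averted=0)

    def test_vector_round_trip(self):
        p = ObserverParameters("M3", w_plus=1.2, w_minus=0.8, b_direct=0.3,
                               b_averted=-0.3)
        assert ObserverParameters.from_vector("M3", p.to_vector()) == p


class TestChoiceProbability:
    def test_neutral_direct_gaze_bias(self):
        p = ObserverParameters("M2", w=1.0, b_direct=0.5, b_averted=0.0)
        s = StimulusCondition(1, "female", "neutral", 0, "direct")
        assert p_choose_anger(p, s) == pytest.approx(norm.cdf(0.5), abs=1e-9)

    def test_full_anger_morph_unit_slope(self):
        p = ObserverParameters("M1", w_plus=1.0, w_minus=1.0, b=0.0)
        s = StimulusCondition(1, "female", "anger", 7, "direct")
        assert p_choose_anger(p, s) == pytest.approx(norm.cdf(1.0), abs=1e-9)

    @settings(max_examples=25, derandomize=True)
    @given(level=st.integers(1, 7), w=st.floats(0.1, 5.0))
    def test_probit_symmetry(self, level, w):
        """With equal slopes and no bias, P(anger|u) + P(anger|-u) = 1."""
        p = ObserverParameters("M1", w_plus=w, w_minus=w, b=0.0)
        anger = StimulusCondition(1, "female", "anger", level, "direct")
        fear = StimulusCondition(1, "female", "fear", level, "direct")
        assert p_choose_anger(p, anger) + p_choose_anger(p, fear) == pytest.approx(1.0)

    def test_monotone_in_evidence_and_bias(self):
        base = ObserverParameters("M2", w=1.5, b_direct=0.0, b_averted=0.0)
        probs = [
            p_choose_anger(base, StimulusCondition(1, "female", "fear", 7, "direct")),
            p_choose_anger(base, StimulusCondition(1, "female", "fear", 2, "direct")),
            p_choose_anger(base, StimulusCondition(1, "female", "neutral", 0, "direct")),
            p_choose_anger(base, StimulusCondition(1, "female", "anger", 2, "direct")),
            p_choose_anger(base, StimulusCondition(1, "female", "anger", 7, "direct")),
        ]
        assert all(a < b for a, b in zip(probs, probs[1:]))
        shifted = ObserverParameters("M2", w=1.5, b_direct=0.4, b_averted=0.0)
        s = StimulusCondition(1, "female", "anger", 3, "direct")
        assert p_choose_anger(shifted, s) > p_choose_anger(base, s)

    def test_probability_floored(self):
        p = ObserverParameters("M2", w=20.0, b_direct=5.0, b_averted=-5.0)
        s = StimulusCondition(1, "female", "anger", 7, "direct")
        assert p_choose_anger(p, s) <= 1 - P_FLOOR


class TestNegativeLogLikelihood:
    def test_chance_model_is_n_ln2(self, rng):
        trials = random_trials(rng, 10)
        p = ObserverParameters("M2", w=0.0, b_direct=0.0, b_averted=0.0)
        assert negative_log_likelihood(p, trials, n_levels=7) == pytest.approx(
            10 * math.log(2), abs=1e-12
        )

    def test_duplicating_trials_doubles_nll(self, rng):
        trials = random_trials(rng, 25)
        p = ObserverParameters("M1", w_plus=1.3, w_minus=0.7, b=0.2)
        single = negative_log_likelihood(p, trials, n_levels=7)
        double = negative_log_likelihood(
            p, pd.concat([trials, trials], ignore_index=True), n_levels=7
        )
        assert double == pytest.approx(2 * single, rel=1e-12)

    @pytest.mark.parametrize("model_id", ["M1", "M2", "M3"])
    def test_matches_per_trial_summation_oracle(self, model_id, rng):
        trials = random_trials(rng, 60)
        for _ in range(5):
            vec = rng.uniform([0.0] * 2 + [-2.0] * 2, [3.0] * 2 + [2.0] * 2)
            names = tg.PARAM_NAMES[model_id]
            theta = vec[: len(names)]
            theta[: sum(n.startswith("w") for n in names)] = np.abs(
                theta[: sum(n.startswith("w") for n in names)]
            )
            params = ObserverParameters.from_vector(model_id, theta)
            assert negative_log_likelihood(params, trials, n_levels=7) == pytest.approx(
                nll_by_hand(params, trials), abs=1e-10
            )

    def test_invariant_to_trial_order(self, rng):
        trials = random_trials(rng, 40)
        shuffled = trials.sample(frac=1.0, random_state=0).reset_index(drop=True)
        p = ObserverParameters("M2", w=1.0, b_direct=0.4, b_averted=-0.2)
        assert negative_log_likelihood(p, trials, n_levels=7) == pytest.approx(
            negative_log_likelihood(p, shuffled, n_levels=7), rel=1e-14
        )

    @settings(max_examples=20, derandomize=True)
    @given(w=st.floats(0.1, 4.0), b=st.floats(-1.5, 1.5), seed=st.integers(0, 500))
    def test_m1_m2_collapse_to_common_model(self, w, b, seed):
        """Equal slopes (M1) and equal criteria (M2) are the same 2-parameter
        model: identical likelihood on any dataset."""
        trials = random_trials(np.random.default_rng(seed), 30)
        m1 = ObserverParameters("M1", w_plus=w, w_minus=w, b=b)
        m2 = ObserverParameters("M2", w=w, b_direct=b, b_averted=b)
        assert negative_log_likelihood(m1, trials, n_levels=7) == pytest.approx(
            negative_log_likelihood(m2, trials, n_levels=7), rel=1e-14
        )

    def test_empty_table_rejected(self):
        p = ObserverParameters("M2", w=1.0, b_direct=0.0, b_averted=0.0)
        with pytest.raises(ValueError):
            negative_log_likelihood(p, pd.DataFrame(columns=["emotion", "morph_level", "gaze", "response"]))

    def test_bounded_below_by_floor(self, rng):
        trials = random_trials(rng, 50)
        p = ObserverParameters("M2", w=20.0, b_direct=5.0, b_averted=5.0)
        nll = negative_log_likelihood(p, trials, n_levels=7)
        assert 0 <= nll <= -50 * math.log(P_FLOOR)


def grid_search_oracle(trials, model_id, n_levels, step=0.01, w_hi=8.0, b_hi=4.0):
    """Dense grid-search NLL minimum, exact by additive decomposition.

    The likelihood splits into sums over trial subsets (by congruence for the
    sensitivity model, by gaze for the bias model) that each depend on only
    one (slope, criterion) pair, so the full 3-D grid minimum at the given
    step is recovered exactly from 2-D grids.
    """
    arrs = prepare_trials(trials, n_levels=n_levels)
    w_grid = np.arange(0.0, w_hi + step / 2, step)
    b_grid = np.arange(-b_hi, b_hi + step / 2, step)

    def pair_nll(mask, use_u=True):
        # sum over masked trials of NLL on a (w, b) grid
        acc = np.zeros((len(w_grid), len(b_grid)))
        u = arrs.u[mask]
        y = arrs.response_anger[mask]
        for ui, yi in zip(u, y):
            eta = (w_grid[:, None] * ui if use_u else 0.0) + b_grid[None, :]
            p = np.clip(norm.cdf(eta), P_FLOOR, 1 - P_FLOOR)
            acc += -np.log(p if yi else 1 - p)
        return acc

    if model_id == "M2":
        # the two criteria optimise independently given the shared slope
        total = pair_nll(arrs.direct).min(axis=1) + pair_nll(~arrs.direct).min(axis=1)
        return float(total.min())
    if model_id == "M1":
        # the two slopes optimise independently given the shared criterion;
        # neutral trials (u = 0) depend on the criterion only
        f_neutral = pair_nll(arrs.neutral, use_u=False)[0]
        total = (pair_nll(arrs.threat_plus).min(axis=0)
                 + pair_nll(arrs.threat_minus).min(axis=0) + f_neutral)
        return float(total.min())
    raise ValueError(model_id)


@pytest.fixture(scope="module")
def subject_5600():
    """One simulated observer over 6000 trials (M1 generative)."""
    rng = np.random.default_rng(202)
    truth = ObserverParameters("M1", w_plus=1.5, w_minus=0.8, b=0.2)
    stimuli = enumerate_stimuli(20, 7)
    frames = []
    for rep in range(10):  # 10 passes over the 560 emotion+40 neutral grid
        sched = build_schedule(stimuli, 5, seed=rep)
        frames.append(simulate_trials(truth, sched, rng))
    return truth, pd.concat(frames, ignore_index=True)


class TestFitML:
    def test_parameter_recovery_large_n(self, subject_5600):
        truth, trials = subject_5600
        fit = tg.fit_ml(trials, "M1", n_levels=7)
        assert fit.converged
        for name in tg.PARAM_NAMES["M1"]:
            assert getattr(fit.parameters, name) == pytest.approx(
                getattr(truth, name), abs=0.1
            )

    def test_fitted_nll_beats_generating_parameters(self, subject_5600):
        truth, trials = subject_5600
        fit = tg.fit_ml(trials, "M1", n_levels=7)
        nll_truth = negative_log_likelihood(truth, trials, n_levels=7)
        assert -fit.log_likelihood <= nll_truth + 1e-9

    @pytest.mark.parametrize("model_id", ["M1", "M2"])
    def test_matches_dense_grid_search(self, model_id, rng):
        truth = ObserverParameters("M2", w=1.2, b_direct=0.4, b_averted=-0.3)
        sched = build_schedule(enumerate_stimuli(4, 3), 1, seed=9)
        trials = simulate_trials(truth, sched, rng)  # 56 trials
        trials = pd.concat([trials, simulate_trials(truth, sched, rng)],
                           ignore_index=True).head(100)
        fit = tg.fit_ml(trials, model_id, n_levels=3)
        oracle = grid_search_oracle(trials, model_id, n_levels=3)
        assert -fit.log_likelihood <= oracle + 1e-9
        assert abs(-fit.log_likelihood - oracle) <= 1e-3

    def test_deterministic(self, rng):
        truth = ObserverParameters("M1", w_plus=1.4, w_minus=0.9, b=0.1)
        sched = build_schedule(enumerate_stimuli(4, 3), 2, seed=4)
        trials = simulate_trials(truth, sched, rng)
        a = tg.fit_ml(trials, "M1", n_levels=3)
        b = tg.fit_ml(trials, "M1", n_levels=3)
        assert a.parameters == b.parameters
        assert a.log_likelihood == b.log_likelihood

    def test_degenerate_all_anger_flagged_not_raised(self):
        sched = build_schedule(enumerate_stimuli(2, 3), 1, seed=0)
        trials = sched.trials.assign(response="anger")
        fit = tg.fit_ml(trials, "M2", n_levels=3)
        assert fit.at_bound

    def test_wide_prior_recovery_correlation(self):
        """Parameters drawn across the plausible range are recovered with
        r >= 0.9 per parameter at 600 trials per observer."""
        rng = np.random.default_rng(77)
        stimuli = enumerate_stimuli(20, 7)
        true_rows, fit_rows = [], []
        for i in range(50):
            truth = ObserverParameters(
                "M2",
                w=float(rng.uniform(0.3, 3.0)),
                b_direct=float(rng.uniform(-1.0, 1.0)),
                b_averted=float(rng.uniform(-1.0, 1.0)),
            )
            sched = build_schedule(stimuli, 5, seed=1000 + i)
            trials = simulate_trials(truth, sched, rng)
            fit = tg.fit_ml(trials, "M2", n_levels=7)
            true_rows.append(truth.as_dict())
            fit_rows.append(fit.parameters.as_dict())
        true_df = pd.DataFrame(true_rows)
        fit_df = pd.DataFrame(fit_rows)
        for name in tg.PARAM_NAMES["M2"]:
            r = np.corrcoef(true_df[name], fit_df[name])[0, 1]
            assert r >= 0.9, f"{name}: r={r:.3f}"
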