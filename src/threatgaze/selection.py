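"""Group-level model comparison: fixed-effects Bayes factors and
random-effects Bayesian model selection (BMS).

Per-subject model evidence is the maximised log-likelihood (models with equal
parameter counts need no complexity penalty; a BIC-penalised evidence is
available for unequal counts, e.g. the 4-parameter combined model).

The fixed-effects comparison assumes every subject uses the same mechanism:
the group Bayes factor is the product of subject-level evidence ratios.  The
random-effects comparison lets the governing model vary across subjects and
estimates a Dirichlet posterior over model frequencies in the population via
the variational scheme of Stephan et al. (2009, NeuroImage 46:1004-17),
summarised by the exceedance probability — the posterior probability that one
model is the most frequent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma
from scipy.stats import beta as beta_dist
from scipy.stats import dirichlet

from .models import ModelFit

__all__ = [
    "EvidenceMatrix",
    "FFXResult",
    "BMSResult",
    "evidence_matrix",
    "ffx_bayes_factor",
    "rfx_bms",
    "exceedance_probabilities",
]


@dataclass(frozen=True)
class EvidenceMatrix:
    """Subjects x models array of log model evidence (nats)."""

    log_evidence: np.ndarray
    model_ids: tuple[str, ...]
    subject_ids: tuple

    def __post_init__(self) -> None:
        le = np.asarray(self.log_evidence, dtype=float)
        if le.ndim != 2:
            raise ValueError("log_evidence must be 2-D (subjects x models)")
        if le.shape != (len(self.subject_ids), len(self.model_ids)):
            raise ValueError("log_evidence shape does not match the id lists")
        if le.shape[0] < 1 or le.shape[1] < 2:
            raise ValueError("need >= 1 subject and >= 2 models")
        if not np.all(np.isfinite(le)):
            raise ValueError("log evidences must be finite")
        object.__setattr__(self, "log_evidence", le)

    def column(self, model_id: str) -> np.ndarray:
        try:
            k = self.model_ids.index(model_id)
        except ValueError:
            raise KeyError(f"model {model_id!r} not in {self.model_ids}") from None
        return self.log_evidence[:, k]


def evidence_matrix(
    fits: Iterable[ModelFit] | pd.DataFrame,
    model_ids: Sequence[str] | None = None,
    penalty: str = "none",
) -> EvidenceMatrix:
    """Assemble an evidence matrix from per-subject model fits.

    ``penalty="none"`` uses the raw maximised log-likelihood (appropriate
    when all compared models have equal parameter counts);
    ``penalty="bic"`` uses LL - (k/2) ln n.
    """
    if penalty not in ("none", "bic"):
        raise ValueError("penalty must be 'none' or 'bic'")
    if isinstance(fits, pd.DataFrame):
        df = fits.copy()
        if penalty == "bic":
            raise ValueError(
                "BIC penalty requires ModelFit objects (parameter counts)"
            )
        df = df.rename(columns={"model": "model_id", "logL": "evidence"})
    else:
        rows = []
        for f in fits:
            ev = f.log_likelihood if penalty == "none" else f.bic_evidence()
            rows.append(
                {"subject": f.subject_id, "model_id": f.model_id, "evidence": ev}
            )
        df = pd.DataFrame(rows)

    wide = df.pivot(index="subject", columns="model_id", values="evidence")
    if model_ids is not None:
        wide = wide[list(model_ids)]
    if wide.isna().any().any():
        missing = wide.isna().stack()
        missing = missing[missing].index.tolist()
        raise ValueError(f"missing subject x model evidences: {missing}")
    return EvidenceMatrix(
        log_evidence=wide.to_numpy(dtype=float),
        model_ids=tuple(wide.columns),
        subject_ids=tuple(wide.index),
    )


@dataclass(frozen=True)
class FFXResult:
    """Fixed-effects group comparison of two models."""

    model_a: str
    model_b: str
    log10_group_bayes_factor: float

    @property
    def winning_model(self) -> str:
        return self.model_a if self.log10_group_bayes_factor >= 0 else self.model_b


def ffx_bayes_factor(
    evidence: EvidenceMatrix, model_a: str, model_b: str
) -> FFXResult:
    """Fixed-effects group Bayes factor of ``model_a`` over ``model_b``.

    log10 BF = sum over subjects of (LL_a - LL_b) / ln 10; positive values
    favour ``model_a``.  Antisymmetric under swapping the two models.
    """
    delta = evidence.column(model_a) - evidence.column(model_b)
    return FFXResult(
        model_a=model_a,
        model_b=model_b,
        log10_group_bayes_factor=float(np.sum(delta) / math.log(10.0)),
    )


@dataclass(frozen=True)
class BMSResult:
    """Random-effects BMS posterior over model frequencies."""

    model_ids: tuple[str, ...]
    alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance_probabilities: np.ndarray
    n_iterations: int
    converged: bool

    def p_exc(self, model_id: str) -> float:
        return float(
            self.exceedance_probabilities[self.model_ids.index(model_id)]
        )


def rfx_bms(
    evidence: EvidenceMatrix,
    alpha0: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    mc_draws: int = 1_000_000,
    mc_seed: int = 0,
) -> BMSResult:
    """Random-effects BMS by variational Dirichlet estimation.

    Iterates subject-wise posterior model assignments
    ``u_nk ∝ exp(LL_nk + psi(alpha_k) - psi(sum alpha))`` and the Dirichlet
    update ``alpha_k = alpha0 + sum_n u_nk`` until ``max |d alpha| < tol``.
    Exceedance probabilities use the Beta closed form for two models and
    seeded Monte-Carlo Dirichlet sampling otherwise.
    """
    le = evidence.log_evidence
    n, K = le.shape
    alpha = np.full(K, float(alpha0))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_u = le + digamma(alpha) - digamma(alpha.sum())
        log_u = log_u - log_u.max(axis=1, keepdims=True)
        u = np.exp(log_u)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new

    p_exc = exceedance_probabilities(alpha, n_draws=mc_draws, seed=mc_seed)
    return BMSResult(
        model_ids=evidence.model_ids,
        alpha=alpha,
        expected_frequencies=alpha / alpha.sum(),
        exceedance_probabilities=p_exc,
        n_iterations=it,
        converged=converged,
    )


def exceedance_probabilities(
    alpha: Sequence[float], n_draws: int = 1_000_000, seed: int = 0
) -> np.ndarray:
    """P(model k is the most frequent) under a Dirichlet(alpha) posterior.

    For two models the exact closed form via the regularised incomplete beta
    function is used: ``p_exc(1) = P(r1 > 1/2) = 1 - I_{1/2}(alpha1, alpha2)``.
    For three or more, frequencies are sampled from the Dirichlet with a
    fixed seed and the argmax tallied.
    """
    a = np.asarray(alpha, dtype=float)
    if a.ndim != 1 or len(a) < 2:
        raise ValueError("alpha must be a vector of length >= 2")
    if np.any(a <= 0):
        raise ValueError("all alpha must be > 0")
    if len(a) == 2:
        p1 = float(beta_dist.sf(0.5, a[0], a[1]))
        return np.array([p1, 1.0 - p1])
    rng = np.random.default_rng(seed)
    draws = dirichlet.rvs(a, size=n_draws, random_state=rng)
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=len(a)) / float(n_draws)
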