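"""Generative equal-variance SDT observer for tracking trials.

The observer answers "target" with probability Phi(-c + d'X), where X
indicates that the queried object really was a target, d' is
sensitivity and c is the decision criterion measured from the
distractor-distribution mean (positive c = conservative, miss-prone).
Both d' and c are linear in tracking load with per-participant random
intercepts and slopes, optional per-condition offsets, and an optional
linear effect of the number of sudden target/distractor motions.

Hit rate Phi(-c + d') and false-alarm rate Phi(-c) follow in closed
form; with queries balanced 50/50 the expected accuracy is their
average with the false-alarm rate complemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .design import Condition, TrialSpec
from .errors import InvalidInputError

__all__ = [
    "PopulationParams",
    "ObserverParams",
    "sample_observers",
    "simulate_responses",
    "hit_rate",
    "false_alarm_rate",
    "expected_accuracy",
]


def hit_rate(dprime: float, criterion: float) -> float:
    """P(respond "target" | queried object was a target)."""
    return float(ndtr(-criterion + dprime))


def false_alarm_rate(criterion: float) -> float:
    """P(respond "target" | queried object was a distractor)."""
    return float(ndtr(-criterion))


def expected_accuracy(dprime: float, criterion: float, p_target: float = 0.5) -> float:
    """Expected proportion correct under the query-probability mix."""
    return p_target * hit_rate(dprime, criterion) + (1 - p_target) * (
        1 - false_alarm_rate(criterion)
    )


@dataclass
class PopulationParams:
    """Population-level SDT parameters of the generative model.

    ``alpha_d``/``beta_d`` are the d' intercept and change per added
    target (load uncentered), ``alpha_c``/``beta_c`` the same for the
    criterion.  ``condition_offsets`` maps a condition to its
    (delta_d, delta_c) deviation from the grand parameters.  The four
    sigmas are the SDs of the per-participant intercept/slope
    deviations; ``rho`` correlates a participant's condition-specific
    d' intercept deviations across conditions.  ``gamma_d``/``gamma_c``
    are the changes per sudden target motion.
    """

    alpha_d: float = 3.58
    beta_d: float = -0.50
    alpha_c: float = 1.97
    beta_c: float = -0.22
    condition_offsets: dict = field(default_factory=dict)
    sigma_ad: float = 0.5
    sigma_bd: float = 0.1
    sigma_ac: float = 0.3
    sigma_bc: float = 0.05
    rho: float = 1.0
    gamma_d: float = 0.0
    gamma_c: float = 0.0

    def __post_init__(self) -> None:
        for s in (self.sigma_ad, self.sigma_bd, self.sigma_ac, self.sigma_bc):
            if s < 0:
                raise InvalidInputError("random-effect SDs must be non-negative")
        if not -1.0 <= self.rho <= 1.0:
            raise InvalidInputError("|rho| must be <= 1")

    def offsets(self, condition: Condition) -> tuple[float, float]:
        return self.condition_offsets.get(condition, (0.0, 0.0))


@dataclass
class ObserverParams:
    """One participant's deviations from the population parameters.

    ``a_p`` is either a scalar d'-intercept deviation or, when
    condition-specific deviations were requested, a mapping
    condition -> deviation.
    """

    participant_id: str
    a_p: float | dict
    b_p: float
    u_p: float
    v_p: float

    def a_for(self, condition: Condition) -> float:
        if isinstance(self.a_p, dict):
            return self.a_p[condition]
        return self.a_p


def sample_observers(
    pop: PopulationParams,
    n: int,
    seed: int = 0,
    conditions: list[Condition] | None = None,
) -> list[ObserverParams]:
    """Draw per-participant deviations from the population.

    With ``conditions`` given and ``rho < 1``, the d'-intercept
    deviations are drawn per condition from an exchangeable
    multivariate Gaussian with correlation ``rho``; otherwise a single
    shared deviation is drawn (equivalent to ``rho = 1``).
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    observers = []
    for p in range(n):
        if conditions is not None and pop.rho < 1.0:
            m = len(conditions)
            cov = pop.sigma_ad**2 * (
                (1 - pop.rho) * np.eye(m) + pop.rho * np.ones((m, m))
            )
            draws = rng.multivariate_normal(np.zeros(m), cov, method="cholesky")
            a_p: float | dict = dict(zip(conditions, draws))
        else:
            a_p = float(rng.normal(0, pop.sigma_ad)) if pop.sigma_ad > 0 else 0.0
            if conditions is not None:
                a_p = {c: a_p for c in conditions}
        observers.append(
            ObserverParams(
                participant_id=f"p{p:03d}",
                a_p=a_p,
                b_p=float(rng.normal(0, pop.sigma_bd)) if pop.sigma_bd > 0 else 0.0,
                u_p=float(rng.normal(0, pop.sigma_ac)) if pop.sigma_ac > 0 else 0.0,
                v_p=float(rng.normal(0, pop.sigma_bc)) if pop.sigma_bc > 0 else 0.0,
            )
        )
    return observers


def simulate_responses(
    observers: list[ObserverParams],
    trials: list[TrialSpec],
    pop: PopulationParams,
    seed: int = 0,
    trial_covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Bernoulli responses of every observer to every trial.

    ``trial_covariates`` may provide per-trial ``sudden_target`` and
    ``sudden_distractor`` counts (indexed by trial_id); missing
    covariates default to zero.  Output columns match the response-CSV
    interface: participant, trial_id, condition, n_targets,
    queried_is_target, sudden_target, sudden_distractor, response,
    correct.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for obs in observers:
        for trial in trials:
            cond = trial.condition
            delta_d, delta_c = pop.offsets(cond)
            if trial_covariates is not None and trial.trial_id in trial_covariates.index:
                cov_t = float(trial_covariates.loc[trial.trial_id, "sudden_target"])
                cov_dd = float(trial_covariates.loc[trial.trial_id, "sudden_distractor"])
            else:
                cov_t = cov_dd = 0.0
            n = trial.n_targets
            dprime = (
                pop.alpha_d + delta_d + obs.a_for(cond) + (pop.beta_d + obs.b_p) * n
                + pop.gamma_d * cov_t
            )
            criterion = (
                pop.alpha_c + delta_c + obs.u_p + (pop.beta_c + obs.v_p) * n
                + pop.gamma_c * cov_t
            )
            x = 1.0 if trial.queried_is_target else 0.0
            p_target = ndtr(-criterion + dprime * x)
            says_target = bool(rng.uniform() < p_target)
            rows.append(
                {
                    "participant": obs.participant_id,
                    "trial_id": trial.trial_id,
                    "condition": cond.value,
                    "n_targets": n,
                    "queried_is_target": trial.queried_is_target,
                    "sudden_target": cov_t,
                    "sudden_distractor": cov_dd,
                    "response": "target" if says_target else "distractor",
                    "correct": says_target == trial.queried_is_target,
                }
            )
    return pd.DataFrame(rows)
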