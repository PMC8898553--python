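"""Hierarchical Bayesian signal-detection analysis of tracking responses.

The observation model is an equal-variance SDT probit regression: a
"target" response occurs with probability Phi(eta), where

    eta = -c + d' * X,
    d'  = d_intercept + d_load * n + d_cond[g] + d_cond_load[g] * n + covariates,
    c   = c_intercept + c_load * n + c_cond[g] + c_cond_load[g] * n + covariates,

X indicates a target query, n is the number of targets (uncentered,
so d_load is the change per added target) and g the condition
(deviation coded against the grand mean).  Every participant gets
Gaussian random intercept and slope deviations on both d' and c.
Fixed effects carry N(0, 1) priors; random-effect SDs carry
half-normal(1) priors.  Estimation is exact conditional Gibbs sampling
(see :mod:`fishmot._gibbs`), diagnosed with split-R-hat and ESS.

Also provided: posterior d'/bias summaries at given loads, pooled
condition contrasts, Savage-Dickey Bayes factors, the 50%-accuracy
exclusion rule, closed-form per-participant d' with continuity
correction, cross-condition Gaussian prediction models, and Bayesian
R-squared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from ._gibbs import GibbsResult, sample_gaussian, sample_probit
from .errors import (
    ConvergenceError,
    DegenerateDesignError,
    InsufficientDataError,
    InvalidInputError,
)

__all__ = [
    "PosteriorSummary",
    "BayesFactorResult",
    "SDTPosterior",
    "PredictionPosterior",
    "fit_sdt_probit",
    "summarize_dprime_bias",
    "contrast_conditions",
    "savage_dickey_bf",
    "apply_exclusion",
    "per_participant_dprime",
    "fit_prediction_model",
    "bayesian_r2",
]


@dataclass
class PosteriorSummary:
    """Posterior mean with central credible interval."""

    mean: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    @classmethod
    def from_draws(cls, draws: np.ndarray, level: float = 0.95) -> "PosteriorSummary":
        lo, hi = np.quantile(draws, [(1 - level) / 2, 1 - (1 - level) / 2])
        return cls(mean=float(np.mean(draws)), ci_low=float(lo), ci_high=float(hi), level=level)


@dataclass
class BayesFactorResult:
    """Savage-Dickey Bayes factor for a point null at zero."""

    parameter: str
    bf10: float
    method: str = "savage-dickey-kde"
    unstable: bool = False


def _deviation_row(levels: list, value) -> np.ndarray:
    """Deviation (sum-to-zero) coding: L-1 columns, last level = -1s."""
    row = np.zeros(len(levels) - 1)
    idx = levels.index(value)
    if idx < len(levels) - 1:
        row[idx] = 1.0
    else:
        row[:] = -1.0
    return row


class _DrawsMixin:
    """Named access to flat posterior draws plus arviz diagnostics."""

    names: list[str]
    result: GibbsResult

    def draws(self, name: str) -> np.ndarray:
        """All post-warmup draws of a named parameter, chains concatenated."""
        idx = self.names.index(name)
        if idx < self.result.beta.shape[2]:
            return self.result.beta[:, :, idx].reshape(-1)
        raise KeyError(name)

    def _chain_draws(self, name: str) -> np.ndarray:
        idx = self.names.index(name)
        return self.result.beta[:, :, idx]

    def to_inference_data(self) -> az.InferenceData:
        post = {name: self._chain_draws(name) for name in self.names}
        for k, sd_name in enumerate(self.sd_names):
            post[sd_name] = self.result.sigma[:, :, k]
        if self.result.sigma_resid is not None:
            post["sigma_resid"] = self.result.sigma_resid
        return az.from_dict(posterior=post)

    def diagnostics(self) -> pd.DataFrame:
        """Split-R-hat and bulk ESS for the reported parameters."""
        idata = self.to_inference_data()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = az.rhat(idata)
            ess = az.ess(idata)
        return pd.DataFrame(
            {
                "rhat": {k: float(rhat[k].values) for k in rhat.data_vars},
                "ess_bulk": {k: float(ess[k].values) for k in ess.data_vars},
            }
        )


@dataclass
class SDTPosterior(_DrawsMixin):
    """Posterior draws of the hierarchical SDT probit model."""

    result: GibbsResult
    names: list[str]          # fixed-effect names, then random-effect names
    n_fixed: int
    sd_names: list[str]
    participants: list[str]
    condition_levels: list[str]
    loads: list[int]
    covariates: list[str]
    seed: int
    prior_sd: float = 1.0
    centers: dict = field(default_factory=dict)  # predictor -> subtracted mean

    def draws(self, name: str) -> np.ndarray:
        """Flat draws on the reporting (uncentered) scale.

        The model is fitted with load and covariates centered (the
        N(0,1) intercept prior then acts at the design mean, as in
        standard practice); intercept draws are mapped back to the
        load-0 scale here.  Slopes are unaffected by centering.
        """
        if name in ("d_intercept", "c_intercept"):
            part = name[0]
            out = super().draws(name) - super().draws(f"{part}_load") * self.centers["load"]
            for cov in self.covariates:
                out = out - super().draws(f"{part}_{cov}") * self.centers[cov]
            return out
        return super().draws(name)

    def _cond_offset(self, part: str, condition: str, load_scaled: bool) -> np.ndarray:
        """Deviation-coded condition offset draws for `part` in {'d','c'}."""
        if len(self.condition_levels) < 2:
            return 0.0
        tag = f"{part}_cond_load" if load_scaled else f"{part}_cond"
        cols = [f"{tag}[{lev}]" for lev in self.condition_levels[:-1]]
        draws = np.stack([self.draws(c) for c in cols])
        if condition == self.condition_levels[-1]:
            return -draws.sum(axis=0)
        return draws[self.condition_levels.index(condition)]

    def _linear(self, part: str, load: float, condition: str | None) -> np.ndarray:
        out = self.draws(f"{part}_intercept") + self.draws(f"{part}_load") * load
        if condition is not None:
            if condition not in self.condition_levels:
                raise KeyError(f"condition {condition!r} not in fitted model")
            out = out + self._cond_offset(part, condition, False)
            # the condition x load interaction is fitted on centered load
            out = out + self._cond_offset(part, condition, True) * (
                load - self.centers["load"]
            )
        elif len(self.condition_levels) > 1:
            raise KeyError("model has conditions; specify one")
        return out

    def dprime_draws(self, load: float, condition: str | None = None) -> np.ndarray:
        """Posterior draws of population d' at a load (and condition)."""
        return self._linear("d", load, condition)

    def bias_draws(self, load: float, condition: str | None = None) -> np.ndarray:
        """Posterior draws of the population criterion c at a load."""
        return self._linear("c", load, condition)

    def participant_effect_draws(self, participant: str, effect: str) -> np.ndarray:
        """Draws of one participant's deviation; effect in
        {'d_intercept', 'd_load', 'c_intercept', 'c_load'}."""
        return self.draws(f"re_{effect}[{participant}]")


def _build_probit_design(
    responses: pd.DataFrame,
    condition_levels: list[str],
    covariates: list[str],
    covariate_on: tuple[str, ...],
):
    x = responses["queried_is_target"].to_numpy(dtype=float)
    n_raw = responses["n_targets"].to_numpy(dtype=float)
    # fit on centered predictors so the N(0,1) intercept prior acts at
    # the design mean; reporting transforms back (see SDTPosterior.draws)
    centers = {"load": float(n_raw.mean())}
    n = n_raw - centers["load"]
    for cov in covariates:
        centers[cov] = float(responses[cov].mean())
    participants = sorted(responses["participant"].unique())
    p_idx = pd.Categorical(responses["participant"], categories=participants).codes

    use_cond = len(condition_levels) > 1
    cond_rows = (
        np.stack([_deviation_row(condition_levels, c) for c in responses["condition"]])
        if use_cond
        else None
    )

    def part_columns(prefix: str, sign: np.ndarray):
        """Columns of one linear predictor (d' or c), scaled by `sign`."""
        cols, names = [], []
        cols += [sign, sign * n]
        names += [f"{prefix}_intercept", f"{prefix}_load"]
        if use_cond:
            for j, lev in enumerate(condition_levels[:-1]):
                cols.append(sign * cond_rows[:, j])
                names.append(f"{prefix}_cond[{lev}]")
            for j, lev in enumerate(condition_levels[:-1]):
                cols.append(sign * cond_rows[:, j] * n)
                names.append(f"{prefix}_cond_load[{lev}]")
        tag = "dprime" if prefix == "d" else "criterion"
        if tag in covariate_on or prefix in covariate_on:
            for cov in covariates:
                cols.append(sign * (responses[cov].to_numpy(dtype=float) - centers[cov]))
                names.append(f"{prefix}_{cov}")
        return cols, names

    d_cols, d_names = part_columns("d", x)
    c_cols, c_names = part_columns("c", -np.ones_like(x))
    fixed = np.column_stack(d_cols + c_cols)
    fixed_names = d_names + c_names

    # random effects: 4 deviation types per participant
    n_obs, n_p = len(responses), len(participants)
    re_specs = [
        ("d_intercept", x),
        ("d_load", x * n),
        ("c_intercept", -np.ones(n_obs)),
        ("c_load", -n),
    ]
    re_blocks, re_names, group_cols = [], [], []
    col0 = fixed.shape[1]
    for effect, base in re_specs:
        block = np.zeros((n_obs, n_p))
        block[np.arange(n_obs), p_idx] = base
        re_blocks.append(block)
        re_names += [f"re_{effect}[{p}]" for p in participants]
        group_cols.append(np.arange(col0, col0 + n_p))
        col0 += n_p
    W = np.column_stack([fixed] + re_blocks)
    names = fixed_names + re_names
    sd_names = [f"sigma_{e}" for e, _ in re_specs]
    return W, names, len(fixed_names), group_cols, sd_names, participants, centers


def fit_sdt_probit(
    responses: pd.DataFrame,
    covariates: list[str] | None = None,
    covariate_on: tuple[str, ...] = ("dprime", "criterion"),
    prior_sd: float = 1.0,
    sd_prior_scale: float = 1.0,
    n_chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    seed: int = 0,
    require_convergence: bool = False,
    rhat_threshold: float = 1.01,
) -> SDTPosterior:
    """Fit the hierarchical probit SDT model to a response table.

    ``responses`` needs columns participant, condition, n_targets,
    queried_is_target, response; conditions are deviation coded
    (with a condition x load interaction) whenever more than one is
    present.  ``covariates`` names additional response columns entering
    the d' and/or c linear predictors.  With
    ``require_convergence=True`` a split-R-hat above
    ``rhat_threshold`` on any reported parameter raises
    :class:`ConvergenceError`.
    """
    required = {"participant", "condition", "n_targets", "queried_is_target", "response"}
    missing = required - set(responses.columns)
    if missing:
        raise InvalidInputError(f"responses missing columns: {sorted(missing)}")
    if responses["queried_is_target"].nunique() < 2:
        raise InvalidInputError("need both target and distractor queries")
    covariates = list(covariates or [])
    condition_levels = sorted(responses["condition"].unique())

    # perfect separation is harmless under the N(0,1) priors, but worth a note
    separated = False
    if "correct" in responses:
        separated = bool((responses.groupby("participant")["correct"].mean() >= 1.0).any())
    one_sided = bool((responses.groupby("participant")["response"].nunique() < 2).any())
    if separated or one_sided:
        warnings.warn(
            "participant(s) with perfectly separated responses; "
            "estimates rely on the priors",
            stacklevel=2,
        )

    W, names, n_fixed, group_cols, sd_names, participants, centers = _build_probit_design(
        responses, condition_levels, covariates, covariate_on
    )
    y = (responses["response"] == "target").to_numpy(dtype=float)
    result = sample_probit(
        W,
        y,
        fixed_prior_sd=np.full(n_fixed, prior_sd),
        group_cols=group_cols,
        sd_prior_scale=sd_prior_scale,
        n_chains=n_chains,
        warmup=warmup,
        draws=draws,
        seed=seed,
    )
    post = SDTPosterior(
        result=result,
        names=names,
        n_fixed=n_fixed,
        sd_names=sd_names,
        participants=participants,
        condition_levels=condition_levels if len(condition_levels) > 1 else condition_levels[:1],
        loads=sorted(responses["n_targets"].unique()),
        covariates=covariates,
        seed=seed,
        prior_sd=prior_sd,
        centers=centers,
    )
    if require_convergence:
        diag = post.diagnostics()
        fixed_diag = diag.loc[[n for n in names[:n_fixed]] + sd_names]
        bad = fixed_diag[fixed_diag["rhat"] > rhat_threshold]
        if not bad.empty:
            raise ConvergenceError(f"split-R-hat above {rhat_threshold}:\n{bad}")
    return post


def summarize_dprime_bias(
    post: SDTPosterior,
    at_loads: list[int],
    by_condition: bool = False,
    level: float = 0.95,
) -> pd.DataFrame:
    """Posterior mean and CI of d' and bias at each requested load
    (and condition).  Warns when extrapolating beyond the fitted loads."""
    lo, hi = min(post.loads), max(post.loads)
    if any(load < lo or load > hi for load in at_loads):
        warnings.warn(f"extrapolating beyond fitted loads [{lo}, {hi}]", stacklevel=2)
    conditions = post.condition_levels if by_condition else [None]
    rows = []
    for load in at_loads:
        for cond in conditions:
            for measure, fn in (("dprime", post.dprime_draws), ("bias", post.bias_draws)):
                summ = PosteriorSummary.from_draws(fn(load, cond), level)
                rows.append(
                    {
                        "load": load,
                        "condition": cond,
                        "measure": measure,
                        "mean": summ.mean,
                        "ci_low": summ.ci_low,
                        "ci_high": summ.ci_high,
                    }
                )
    return pd.DataFrame(rows)


def contrast_conditions(
    post: SDTPosterior,
    pair: tuple[str, str],
    pooled_over_loads: tuple[int, ...] = (2, 4),
    level: float = 0.95,
) -> dict[str, PosteriorSummary]:
    """Pooled condition contrast: per draw, average d' (and bias) over
    the given loads in each condition, then take condition A minus B."""
    a, b = pair
    out = {}
    for measure, fn in (("dprime", post.dprime_draws), ("bias", post.bias_draws)):
        da = np.mean([fn(load, a) for load in pooled_over_loads], axis=0)
        db = np.mean([fn(load, b) for load in pooled_over_loads], axis=0)
        out[measure] = PosteriorSummary.from_draws(da - db, level)
    return out


def savage_dickey_bf(
    post: _DrawsMixin | np.ndarray,
    parameter: str | None = None,
    prior_sd: float = 1.0,
    min_local_draws: int = 50,
) -> BayesFactorResult:
    """BF10 for `parameter` = 0 by the Savage-Dickey density ratio.

    The posterior density at zero is a Gaussian KDE (Silverman
    bandwidth) of the draws; the prior is N(0, prior_sd).  The result
    is flagged unstable when fewer than ``min_local_draws`` draws fall
    within one bandwidth of zero.
    """
    if isinstance(post, np.ndarray):
        draws, name = np.asarray(post, float).ravel(), parameter or "parameter"
    else:
        name = parameter
        draws = post.draws(parameter)
    if np.std(draws) == 0:
        raise DegenerateDesignError("posterior draws are constant")
    kde = stats.gaussian_kde(draws, bw_method="silverman")
    bw = kde.factor * float(np.std(draws, ddof=1))
    post_at_0 = max(float(kde(0.0)[0]), 1e-300)
    prior_at_0 = float(stats.norm.pdf(0.0, scale=prior_sd))
    unstable = int(np.sum(np.abs(draws) < bw)) < min_local_draws
    return BayesFactorResult(parameter=name, bf10=prior_at_0 / post_at_0, unstable=unstable)


def apply_exclusion(
    responses: pd.DataFrame,
    condition: str = "TRADITIONAL",
    n_targets: int = 2,
    threshold: float = 0.5,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Attention-check exclusion: drop participants whose accuracy in
    the reference cell (default: traditional MOT with two targets) is
    strictly below ``threshold``.  Returns (kept responses, excluded
    participant ids, participants flagged for missing the cell)."""
    cell = responses[
        (responses["condition"] == condition) & (responses["n_targets"] == n_targets)
    ]
    acc = cell.groupby("participant")["correct"].mean()
    excluded = sorted(acc[acc < threshold].index)
    flagged = sorted(set(responses["participant"]) - set(acc.index))
    kept = responses[~responses["participant"].isin(excluded)].reset_index(drop=True)
    return kept, excluded, flagged


def per_participant_dprime(responses: pd.DataFrame) -> pd.DataFrame:
    """Closed-form equal-variance d' and criterion per participant x
    condition x load.

    Hit and false-alarm rates of 0 or 1 are continuity-corrected to
    1/(2N) and 1 - 1/(2N); a cell missing either query type yields NaN
    rather than an error.
    """

    def correct_rate(k: int, n: int) -> float:
        rate = k / n
        if rate <= 0.0:
            return 1.0 / (2 * n)
        if rate >= 1.0:
            return 1.0 - 1.0 / (2 * n)
        return rate

    rows = []
    grouped = responses.groupby(["participant", "condition", "n_targets"])
    for (part, cond, load), grp in grouped:
        says_target = grp["response"] == "target"
        tq = grp["queried_is_target"].astype(bool)
        n_t, n_d = int(tq.sum()), int((~tq).sum())
        if n_t == 0 or n_d == 0:
            d = c = h = f = np.nan
        else:
            h = correct_rate(int(says_target[tq].sum()), n_t)
            f = correct_rate(int(says_target[~tq].sum()), n_d)
            d = float(ndtri(h) - ndtri(f))
            c = float(-ndtri(f))
        rows.append(
            {
                "participant": part,
                "condition": cond,
                "n_targets": load,
                "hit_rate": h,
                "fa_rate": f,
                "dprime": d,
                "criterion": c,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PredictionPosterior(_DrawsMixin):
    """Posterior of the cross-condition Gaussian prediction model."""

    result: GibbsResult
    names: list[str]
    sd_names: list[str]
    X: np.ndarray
    y: np.ndarray
    prior_sd: float = 1.0

    def sigma_resid_draws(self) -> np.ndarray:
        return self.result.sigma_resid.reshape(-1)


def fit_prediction_model(
    dprime_table: pd.DataFrame,
    predictor_condition: str,
    outcome_condition: str,
    loads: tuple[int, ...] = (2, 4),
    value: str = "dprime",
    prior_sd: float = 1.0,
    n_chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    seed: int = 0,
) -> PredictionPosterior:
    """Predict one condition's per-participant sensitivity (or bias)
    from another's.

    A multilevel Gaussian regression on the participant x load table:
    outcome ~ intercept + slope * predictor + load (deviation coded
    -1/2, +1/2) + predictor x load interaction + participant random
    intercept.  N(0,1) priors on coefficients, half-normal(1) on both
    SDs.
    """
    wide = dprime_table.pivot_table(
        index=["participant", "n_targets"], columns="condition", values=value
    ).reset_index()
    wide = wide[wide["n_targets"].isin(loads)].dropna(
        subset=[predictor_condition, outcome_condition]
    )
    participants = sorted(wide["participant"].unique())
    if len(participants) < 3:
        raise InsufficientDataError("need >= 3 participants with both conditions")
    xv = wide[predictor_condition].to_numpy(dtype=float)
    if np.std(xv) < 1e-12:
        raise DegenerateDesignError("predictor is constant")
    yv = wide[outcome_condition].to_numpy(dtype=float)
    load_dev = np.where(wide["n_targets"] == max(loads), 0.5, -0.5)
    fixed = np.column_stack([np.ones_like(xv), xv, load_dev, xv * load_dev])
    names = ["intercept", "slope", "load", "interaction"]
    p_idx = pd.Categorical(wide["participant"], categories=participants).codes
    block = np.zeros((len(wide), len(participants)))
    block[np.arange(len(wide)), p_idx] = 1.0
    X = np.column_stack([fixed, block])
    result = sample_gaussian(
        X,
        yv,
        fixed_prior_sd=np.full(4, prior_sd),
        group_cols=[np.arange(4, 4 + len(participants))],
        n_chains=n_chains,
        warmup=warmup,
        draws=draws,
        seed=seed,
    )
    return PredictionPosterior(
        result=result,
        names=names + [f"re_intercept[{p}]" for p in participants],
        sd_names=["sigma_participant"],
        X=X,
        y=yv,
        prior_sd=prior_sd,
    )


def bayesian_r2(pred: PredictionPosterior, level: float = 0.95) -> PosteriorSummary:
    """Bayesian R-squared: per posterior draw, the variance of the
    fitted values over fitted-plus-residual variance."""
    if len(pred.y) < 2:
        raise InvalidInputError("R-squared undefined for fewer than 2 observations")
    beta = pred.result.beta.reshape(-1, pred.result.beta.shape[2])
    fitted = beta @ pred.X.T
    var_fit = fitted.var(axis=1)
    sigma2 = pred.sigma_resid_draws() ** 2
    r2 = var_fit / (var_fit + sigma2)
    return PosteriorSummary.from_draws(r2, level)
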