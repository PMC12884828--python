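"""Scikit-learn-style estimator interfaces over the modelling pipeline.

``LagTransformer`` turns a raw beep table into the lagged analysis
dataset; ``InertiaModel`` fits the Bayesian multilevel AR(1) model and
exposes posterior summaries, decay contrasts and the overnight-process
classification as fitted attributes; ``ModerationModel`` fits the
one-covariate extension. All three follow the sklearn contract
(get_params/set_params, fit returning self, trailing-underscore fitted
attributes) so they compose with sklearn model-selection utilities.
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .derived import DerivedSummary, IntervalSummary, overnight_contrasts
from .model import MCMCConfig, ModelSpec, Priors, fit
from .moderation import ModerationSpec, fit_moderation, moderation_table
from .preprocess import DEFAULT_GAP_BOUNDS, center_and_decompose, construct_lags
from .reliability import variance_r2


class LagTransformer(TransformerMixin, BaseEstimator):
    """Construct adjacent-beep lags, interval dummies and centering.

    Parameters
    ----------
    withinday_bounds, overnight_bounds : tuple of float
        Admissible gap ranges in hours (defaults 1-4 h and 10-17 h).
    mode : str
        ``"uncentered"`` keeps the raw lag; ``"person_mean"`` adds
        person-mean-centered lag columns for moderation models.
    """

    def __init__(
        self,
        withinday_bounds: tuple[float, float] = DEFAULT_GAP_BOUNDS["withinday"],
        overnight_bounds: tuple[float, float] = DEFAULT_GAP_BOUNDS["overnight"],
        mode: str = "uncentered",
        outcomes: tuple[str, ...] = ("na", "pa"),
    ):
        self.withinday_bounds = withinday_bounds
        self.overnight_bounds = overnight_bounds
        self.mode = mode
        self.outcomes = outcomes

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        bounds = {"withinday": self.withinday_bounds, "overnight": self.overnight_bounds}
        lagged = construct_lags(X, gap_bounds=bounds, outcomes=self.outcomes)
        return center_and_decompose(lagged, mode=self.mode, outcomes=self.outcomes)


class InertiaModel(BaseEstimator):
    """Bayesian multilevel model of within-day and overnight inertia.

    Attributes after ``fit`` include ``draws_`` (posterior samples),
    ``convergence_`` (split-R-hat report), ``summary_`` (medians, HDIs,
    decay contrasts), ``classification_`` (continue/pause/stop/different)
    and ``r2_`` (marginal/conditional R^2).
    """

    def __init__(
        self,
        outcome: str = "na",
        centering: str = "uncentered",
        chains: int = 4,
        iterations: int = 1500,
        warmup: int = 500,
        random_state: int = 0,
        fixed_scale: float | None = 10.0,
        sd_scale: float = 5.0,
        dt_withinday: float = 2.6,
        dt_night: float = 13.7,
        time_in_bed: float = 7.7,
        use_reported_ratios: bool = True,
    ):
        self.outcome = outcome
        self.centering = centering
        self.chains = chains
        self.iterations = iterations
        self.warmup = warmup
        self.random_state = random_state
        self.fixed_scale = fixed_scale
        self.sd_scale = sd_scale
        self.dt_withinday = dt_withinday
        self.dt_night = dt_night
        self.time_in_bed = time_in_bed
        self.use_reported_ratios = use_reported_ratios

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            outcome=self.outcome,
            centering=self.centering,
            priors=Priors(fixed_scale=self.fixed_scale, sd_scale=self.sd_scale),
        )

    def fit(self, X: pd.DataFrame, y=None):
        mcmc = MCMCConfig(
            chains=self.chains,
            iterations=self.iterations,
            warmup=self.warmup,
            seed=self.random_state,
        )
        self.draws_ = fit(X, self._spec(), mcmc)
        self.convergence_ = self.draws_.convergence
        intervals = IntervalSummary(self.dt_withinday, self.dt_night, self.time_in_bed)
        self.summary_: DerivedSummary = overnight_contrasts(
            self.draws_, intervals, use_reported_ratios=self.use_reported_ratios
        )
        self.classification_ = self.summary_.classification
        self.r2_ = variance_r2(self.draws_)
        self.n_obs_ = len(self.draws_.data.y)
        return self


class ModerationModel(BaseEstimator):
    """One-covariate moderation extension of the inertia model."""

    def __init__(
        self,
        covariate: str,
        kind: str = "time_varying",
        rule: str = "momentary_at_t",
        outcome: str = "na",
        chains: int = 4,
        iterations: int = 1500,
        warmup: int = 500,
        random_state: int = 0,
    ):
        self.covariate = covariate
        self.kind = kind
        self.rule = rule
        self.outcome = outcome
        self.chains = chains
        self.iterations = iterations
        self.warmup = warmup
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None, mornings: pd.DataFrame | None = None):
        spec = ModerationSpec(
            covariate=self.covariate, kind=self.kind, rule=self.rule, outcome=self.outcome
        )
        mcmc = MCMCConfig(
            chains=self.chains,
            iterations=self.iterations,
            warmup=self.warmup,
            seed=self.random_state,
        )
        self.draws_ = fit_moderation(X, spec, mornings=mornings, mcmc=mcmc)
        self.convergence_ = self.draws_.convergence
        self.summary_ = moderation_table(self.draws_, spec)
        self.table_ = self.summary_.to_frame()
        return self
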