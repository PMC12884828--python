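"""Moderation of within-day and overnight inertia by covariates.

Each covariate of interest extends the base model in a separate fit: its
within- and between-person components (or the grand-mean-centered trait)
enter as main effects plus cross-level interactions with the overnight
dummy and both inertia terms. The time-lagged affect variable is
person-mean centered in these models, which sharpens between-person
effects on the within-person slope. Moderation coefficients are fixed
effects; the person-level random structure stays on the base terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import MCMCConfig, ModelSpec, PosteriorDraws, fit
from .preprocess import SchemaError

ALIGNMENT_RULES = ("momentary_at_t", "interval_event", "morning_of_day")


@dataclass
class ModerationSpec:
    """One covariate's entry into the extended model."""

    covariate: str
    kind: str = "time_varying"  # or "between_only"
    rule: str = "momentary_at_t"
    outcome: str = "na"
    base: ModelSpec | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("time_varying", "between_only"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.rule not in ALIGNMENT_RULES:
            raise ValueError(f"unknown alignment rule {self.rule!r}")


def align_covariate(
    lagged: pd.DataFrame,
    covariate: str,
    rule: str,
    mornings: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach the covariate value that moderates each lag interval.

    ``momentary_at_t`` uses the beep-t report (e.g. perseverative
    thoughts in the past 5 min); ``interval_event`` uses the beep-t
    report as covering the interval (t-1, t] (e.g. a stressor since the
    previous beep); ``morning_of_day`` attaches day d's morning report
    (e.g. sleep quality) to day d's overnight row and to all of day d's
    within-day rows.
    """
    if rule not in ALIGNMENT_RULES:
        raise ValueError(f"unknown alignment rule {rule!r}")
    df = lagged.copy()
    if rule in ("momentary_at_t", "interval_event"):
        if covariate not in df.columns:
            raise SchemaError(f"missing covariate column {covariate!r}")
        return df
    if mornings is None:
        raise SchemaError("morning_of_day alignment needs the mornings table")
    if covariate not in mornings.columns:
        raise SchemaError(f"missing covariate column {covariate!r} in mornings")
    keys = ["person_id", "wave", "day"]
    merged = df.merge(mornings[keys + [covariate]], on=keys, how="left", suffixes=("", "_m"))
    if covariate + "_m" in merged.columns:  # beep table already had the name
        merged[covariate] = merged.pop(covariate + "_m")
    return merged


@dataclass
class ModerationSummary:
    """Medians, 95% HDIs and HDI-excludes-zero flags per model term."""

    covariate: str
    outcome: str
    rows: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.rows, orient="index")

    def to_dict(self) -> dict:
        return {"covariate": self.covariate, "outcome": self.outcome, "rows": self.rows}


def _interaction_columns(df: pd.DataFrame, spec: ModerationSpec) -> tuple[pd.DataFrame, list[str]]:
    cov = spec.covariate
    lagc = f"{spec.outcome}_lag_centered"
    if lagc not in df.columns:
        grp = df.groupby("person_id", sort=False)[f"{spec.outcome}_lag"]
        df[lagc] = df[f"{spec.outcome}_lag"] - grp.transform("mean")
    wd_term = df[lagc] * df["withinday"]
    on_term = df[lagc] * df["overnight"]

    if spec.kind == "time_varying":
        pmean = df.groupby("person_id", sort=False)[cov].transform("mean")
        comps = {f"{cov}_within": df[cov] - pmean, f"{cov}_between": pmean - pmean.mean()}
    else:
        comps = {f"{cov}_between": df[cov] - df[cov].mean()}
    names = []
    for cname, cvals in comps.items():
        df[cname] = cvals
        df[f"{cname}_x_overnight"] = cvals * df["overnight"]
        df[f"{cname}_x_withinday_inertia"] = cvals * wd_term
        df[f"{cname}_x_overnight_inertia"] = cvals * on_term
        names += [
            cname,
            f"{cname}_x_overnight",
            f"{cname}_x_withinday_inertia",
            f"{cname}_x_overnight_inertia",
        ]
    return df, names


def build_moderation_model(
    lagged: pd.DataFrame,
    spec: ModerationSpec,
    mornings: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, ModelSpec]:
    """Extended dataset + ModelSpec for one covariate's moderation fit.

    A time-varying covariate contributes 8 new fixed effects (2 main
    effects and 2 x 3 interactions); a between-only covariate contributes
    4 (1 main effect and 3 interactions).
    """
    df = align_covariate(lagged, spec.covariate, spec.rule, mornings)
    if df[spec.covariate].isna().all():
        raise SchemaError(f"covariate {spec.covariate!r} has no data")
    df = df.copy()
    # rows lacking the covariate cannot enter the extended likelihood
    df["eligible"] = df["eligible"] & df[spec.covariate].notna()
    df, names = _interaction_columns(df, spec)
    base = spec.base or ModelSpec(outcome=spec.outcome)
    model = replace(base, outcome=spec.outcome, centering="person_mean", extra_terms=tuple(names))
    return df, model


def fit_moderation(
    lagged: pd.DataFrame,
    spec: ModerationSpec,
    mornings: pd.DataFrame | None = None,
    mcmc: MCMCConfig | None = None,
) -> PosteriorDraws:
    """Fit the one-covariate extended model (all covariates fit separately)."""
    df, model = build_moderation_model(lagged, spec, mornings)
    if float(np.nanvar(df.loc[df["eligible"], spec.covariate])) == 0.0:
        raise ValueError(f"covariate {spec.covariate!r} is constant on eligible rows")
    return fit(df, model, mcmc)


def moderation_table(draws: PosteriorDraws, spec: ModerationSpec) -> ModerationSummary:
    """Summary table of the covariate's main and interaction effects."""
    summary = ModerationSummary(covariate=spec.covariate, outcome=spec.outcome)
    for name in draws.data.extra_names:
        pname = f"b_{name}"
        if pname not in draws.param_names:
            raise KeyError(f"draws lack parameter {pname!r}")
        row = draws.summary_row(pname)
        row["significant"] = bool(row["hdi_low"] > 0 or row["hdi_high"] < 0)
        summary.rows[name] = row
    return summary
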