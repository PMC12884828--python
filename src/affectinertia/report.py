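"""Assembly of summary tables for fitted inertia models.

Produces a fixed-effects table per outcome (intercept, morning effect,
the two inertia coefficients, the two decay contrasts, six random-effect
SDs, observation count and marginal/conditional R^2), a moderation grid
with HDI-excludes-zero bolding, individual-slope exports, and a plain
markdown report.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .derived import DerivedSummary
from .model import PosteriorDraws
from .moderation import ModerationSummary

_FIXED_ROWS = [
    ("Intercept", "gamma00"),
    ("overnight", "gamma10"),
    ("within-day inertia", "gamma20"),
    ("overnight inertia", "gamma30"),
]
_CALC_ROWS = [
    ("overnight - withinday^full", "contrast_continue"),
    ("overnight - withinday^corrected", "contrast_pause"),
]
_SD_ROWS = [
    ("SD intercept id", "sd_u0"),
    ("SD intercept id wave", "sd_wave"),
    ("SD intercept id wave day", "sd_day"),
    ("SD overnight", "sd_u1"),
    ("SD within-day inertia", "sd_u2"),
    ("SD overnight inertia", "sd_u3"),
]


def fixed_effects_table(
    draws: PosteriorDraws,
    derived: DerivedSummary,
    r2: dict | None = None,
) -> pd.DataFrame:
    """Model-results table: fixed effects, calculated parameters, SDs."""
    rows = []
    for label, name in _FIXED_ROWS:
        row = draws.summary_row(name)
        rows.append({"parameter": label, **row})
    for label, name in _CALC_ROWS:
        est = derived.estimates[name]
        rows.append({"parameter": label, "median": est["median"],
                     "hdi_low": est["hdi_low"], "hdi_high": est["hdi_high"]})
    for label, name in _SD_ROWS:
        if name in draws.param_names:
            rows.append({"parameter": label, **draws.summary_row(name)})
    rows.append({"parameter": "Observations", "median": float(len(draws.data.y)),
                 "hdi_low": np.nan, "hdi_high": np.nan})
    if r2 is not None:
        rows.append({"parameter": "Marginal R2", "median": r2["marginal_r2"],
                     "hdi_low": np.nan, "hdi_high": np.nan})
        rows.append({"parameter": "Conditional R2", "median": r2["conditional_r2"],
                     "hdi_low": np.nan, "hdi_high": np.nan})
    return pd.DataFrame(rows)


def moderation_grid(summaries: list[ModerationSummary]) -> pd.DataFrame:
    """Interaction grid across covariates: inertia moderation estimates."""
    rows = []
    for s in summaries:
        for term, est in s.rows.items():
            if not term.endswith("_inertia"):
                continue
            level = "within-person" if "_within_x" in term else "between-person"
            target = "within-day inertia" if "withinday" in term else "overnight inertia"
            rows.append(
                {
                    "outcome": s.outcome,
                    "covariate": s.covariate,
                    "level": level,
                    "target": target,
                    "median": est["median"],
                    "hdi_low": est["hdi_low"],
                    "hdi_high": est["hdi_high"],
                    "significant": est["significant"],
                }
            )
    return pd.DataFrame(rows)


def assemble_tables(
    derived_by_outcome: dict[str, DerivedSummary],
    draws_by_outcome: dict[str, PosteriorDraws],
    moderation_summaries: list[ModerationSummary] | None = None,
    r2_by_outcome: dict[str, dict] | None = None,
    slopes: pd.DataFrame | None = None,
    slope_corr: pd.DataFrame | None = None,
) -> dict:
    """Bundle every reporting artifact; values are DataFrames/dicts."""
    tables = {}
    main = []
    for outcome, derived in derived_by_outcome.items():
        r2 = (r2_by_outcome or {}).get(outcome)
        tab = fixed_effects_table(draws_by_outcome[outcome], derived, r2)
        tab.insert(0, "outcome", outcome)
        main.append(tab)
    tables["model_table"] = pd.concat(main, ignore_index=True)
    tables["classification"] = {
        o: d.classification for o, d in derived_by_outcome.items()
    }
    tables["convergence"] = {
        o: (dr.convergence.to_dict() if dr.convergence else None)
        for o, dr in draws_by_outcome.items()
    }
    if moderation_summaries:
        tables["moderation_table"] = moderation_grid(moderation_summaries)
    else:
        tables["moderation_note"] = "no moderation models were fitted"
    if slopes is not None:
        tables["slopes"] = slopes
    if slope_corr is not None:
        tables["slope_correlations"] = slope_corr
    return tables


def write_report(tables: dict, outdir) -> None:
    """Write the bundle: CSV tables, JSON metadata and report.md."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables["model_table"].to_csv(outdir / "table_model.csv", index=False)
    if "moderation_table" in tables:
        tables["moderation_table"].to_csv(outdir / "table_moderation.csv", index=False)
    if "slopes" in tables:
        tables["slopes"].to_csv(outdir / "slopes.csv", index=False)
    meta = {
        "classification": tables["classification"],
        "convergence": tables["convergence"],
        "r2_partition": (
            "marginal R2 = var(fixed predictions) / (var(fixed) + random-effect "
            "variances + residual variance); conditional R2 adds the random-effect "
            "variances to the numerator; computed per posterior draw, median reported"
        ),
    }
    with open(outdir / "report_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)

    lines = ["# Within-day vs overnight affective inertia", ""]
    for outcome, label in tables["classification"].items():
        lines.append(f"- `{outcome}`: overnight process classified as **{label}**")
    lines.append("")
    lines.append(tables["model_table"].round(3).to_string(index=False))
    if "moderation_table" in tables:
        lines += ["", "## Moderation", "", tables["moderation_table"].round(3).to_string(index=False)]
    elif "moderation_note" in tables:
        lines += ["", f"_{tables['moderation_note']}_"]
    if "slope_correlations" in tables:
        lines += ["", "## Individual slope correlations", "",
                  tables["slope_correlations"].round(3).to_string()]
    (outdir / "report.md").write_text("\n".join(lines) + "\n")


def plot_slopes(slopes, path) -> None:
    """Scatter matrix of individual inertia slopes (shrunken estimates)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = [c for c in slopes.columns if c != "person_id"]
    k = len(cols)
    fig, axes = plt.subplots(k, k, figsize=(2.2 * k, 2.2 * k), squeeze=False)
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            ax = axes[i][j]
            if i == j:
                ax.hist(slopes[ci], bins=20, color="steelblue")
            else:
                ax.scatter(slopes[cj], slopes[ci], s=8, alpha=0.6, color="steelblue")
            if i == k - 1:
                ax.set_xlabel(cj, fontsize=8)
            if j == 0:
                ax.set_ylabel(ci, fontsize=8)
            ax.tick_params(labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
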