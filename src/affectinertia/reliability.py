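"""Multilevel composite reliability, variance explained, and person slopes.

McDonald's omega is computed separately at the within- and between-person
levels: the item covariance matrix is decomposed into a pooled
within-cluster component and a between-cluster component (method-of-
moments), a one-factor model is fit to each by maximum likelihood, and

    omega = (sum lambda)^2 / ((sum lambda)^2 + sum theta)

with unit factor variance at that level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .model import PosteriorDraws


class OmegaEstimationError(RuntimeError):
    pass


@dataclass
class OmegaEstimate:
    omega_within: float
    omega_between: float | None
    loadings_within: np.ndarray
    uniquenesses_within: np.ndarray
    loadings_between: np.ndarray | None
    uniquenesses_between: np.ndarray | None
    cov_within: np.ndarray = field(repr=False, default=None)
    cov_between: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "omega_within": self.omega_within,
            "omega_between": self.omega_between,
            "loadings_within": self.loadings_within.tolist(),
            "uniquenesses_within": self.uniquenesses_within.tolist(),
        }


def _one_factor_ml(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ML one-factor fit to a covariance matrix: S ~ ll' + diag(theta)."""
    p = S.shape[0]
    evals, evecs = np.linalg.eigh(S)
    if evals[-1] <= 0:
        raise OmegaEstimationError("covariance matrix is not positive definite")
    lam0 = evecs[:, -1] * np.sqrt(max(evals[-1] - np.mean(evals[:-1]), 1e-3))
    if lam0.sum() < 0:
        lam0 = -lam0
    theta0 = np.clip(np.diag(S) - lam0**2, 1e-4, None)
    x0 = np.concatenate([lam0, np.log(theta0)])

    # discrepancy log|Sigma| + tr(Sigma^-1 S): valid for singular S
    # (noiseless items drive the uniquenesses to their lower bound)
    def nll(x):
        lam, theta = x[:p], np.exp(x[p:])
        Sigma = np.outer(lam, lam) + np.diag(theta)
        try:
            L = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            return 1e10
        logdet = 2 * np.sum(np.log(np.diag(L)))
        return logdet + np.trace(np.linalg.solve(Sigma, S))

    scale = float(np.trace(S)) / p
    bounds = [(None, None)] * p + [(np.log(scale * 1e-9), None)] * p
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    lam, theta = res.x[:p], np.exp(res.x[p:])
    if lam.sum() < 0:
        lam = -lam
    return lam, theta


def _omega_from_fit(lam: np.ndarray, theta: np.ndarray) -> float:
    s = lam.sum()
    return float(s**2 / (s**2 + theta.sum()))


def decompose_covariance(
    items: pd.DataFrame, cluster: pd.Series
) -> tuple[np.ndarray, np.ndarray | None, int]:
    """Pooled within-cluster and between-cluster item covariance matrices.

    Uses the standard method-of-moments two-level decomposition: the
    scaled between-cluster matrix estimates Sigma_W + c * Sigma_B where c
    is the adjusted average cluster size.
    """
    df = items.copy()
    df["_g"] = np.asarray(cluster)
    df = df.dropna()
    groups = df.groupby("_g")
    sizes = groups.size().to_numpy()
    J = len(sizes)
    N = sizes.sum()
    if J < 2 or (sizes >= 2).sum() < 1:
        raise OmegaEstimationError("need >= 2 clusters with >= 2 observations")
    X = df.drop(columns="_g").to_numpy(float)
    gmeans = groups.mean().to_numpy(float)
    centered = X - np.repeat(gmeans, sizes, axis=0)
    S_pw = centered.T @ centered / (N - J)
    grand = X.mean(axis=0)
    dev = gmeans - grand
    S_b_star = (dev.T * sizes) @ dev / (J - 1)
    c = (N - np.sum(sizes**2) / N) / (J - 1)
    Sigma_B = (S_b_star - S_pw) / c
    return S_pw, Sigma_B, J


def multilevel_omega(items: pd.DataFrame, cluster: pd.Series) -> OmegaEstimate:
    """Within- and between-level McDonald's omega for a composite.

    The between-level omega is flagged undefined (None) when the
    between-cluster covariance estimate is not positive definite (e.g.
    single-level data disguised as clusters).
    """
    if items.shape[1] < 2:
        raise OmegaEstimationError("need at least 2 items")
    S_pw, Sigma_B, _ = decompose_covariance(items, cluster)
    lam_w, th_w = _one_factor_ml(S_pw)
    omega_w = _omega_from_fit(lam_w, th_w)
    lam_b = th_b = None
    omega_b = None
    evals_b = np.linalg.eigvalsh(Sigma_B)
    # PSD (possibly singular: zero between-level uniqueness) is fine;
    # indefinite or all-zero between variance leaves omega_b undefined
    if evals_b.max() > 1e-8 and evals_b.min() > -1e-8 * evals_b.max():
        lam_b, th_b = _one_factor_ml(Sigma_B)
        omega_b = _omega_from_fit(lam_b, th_b)
    else:
        warnings.warn("no usable between-cluster covariance; omega_between undefined")
    return OmegaEstimate(
        omega_within=omega_w,
        omega_between=omega_b,
        loadings_within=lam_w,
        uniquenesses_within=th_w,
        loadings_between=lam_b,
        uniquenesses_between=th_b,
        cov_within=S_pw,
        cov_between=Sigma_B,
    )


# ----------------------------------------------------------------------
# variance explained
# ----------------------------------------------------------------------
def variance_r2(draws: PosteriorDraws) -> dict:
    """Marginal and conditional R^2 of the fitted model, per-draw medians.

    Variance partition: marginal R^2 = var(fixed-effect predictions) /
    total model-implied variance; conditional R^2 additionally credits
    all random-effect variance (person, wave, day); the denominator adds
    the residual variance. Computed on each posterior draw and summarised
    by the median. The conditional value is >= the marginal one on every
    draw by construction.
    """
    data = draws.data
    post = draws.idata.posterior
    gam = np.stack([post[n].to_numpy() for n in ("gamma00", "gamma10", "gamma20", "gamma30")], -1)
    C, Dn = gam.shape[0], gam.shape[1]
    gam = gam.reshape(-1, 4)
    extra = None
    if data.extra_names:
        extra = np.stack([post[f"b_{n}"].to_numpy() for n in data.extra_names], -1).reshape(
            -1, len(data.extra_names)
        )
    pred_fixed = gam @ data.Z.T
    if extra is not None:
        pred_fixed = pred_fixed + extra @ data.Xe.T
    var_fixed = pred_fixed.var(axis=1)

    var_random = np.zeros_like(var_fixed)
    if "sd_u0" in post:
        sds = np.stack([post[f"sd_u{j}"].to_numpy().reshape(-1) for j in range(4)], -1)
        corr = np.zeros((sds.shape[0], 4, 4))
        for j in range(4):
            corr[:, j, j] = 1.0
            for k in range(j):
                r = post[f"corr_u{k}{j}"].to_numpy().reshape(-1)
                corr[:, k, j] = r
                corr[:, j, k] = r
        Sigma = corr * (sds[:, :, None] * sds[:, None, :])
        # average over rows of z' Sigma z
        M = data.Z.T @ data.Z / len(data.y)  # (4,4) second-moment matrix
        var_random = var_random + np.einsum("djk,jk->d", Sigma, M)
    if "sd_wave" in post:
        var_random = var_random + post["sd_wave"].to_numpy().reshape(-1) ** 2
    if "sd_day" in post:
        var_random = var_random + post["sd_day"].to_numpy().reshape(-1) ** 2
    sig2 = post["sigma_eps"].to_numpy().reshape(-1) ** 2

    total = var_fixed + var_random + sig2
    marginal = var_fixed / total
    conditional = (var_fixed + var_random) / total
    return {
        "marginal_r2": float(np.median(marginal)),
        "conditional_r2": float(np.median(conditional)),
        "marginal_draws": marginal.reshape(C, Dn),
        "conditional_draws": conditional.reshape(C, Dn),
    }


# ----------------------------------------------------------------------
# individual slopes
# ----------------------------------------------------------------------
def person_slopes(draws_by_outcome: dict[str, PosteriorDraws]) -> pd.DataFrame:
    """Posterior-mean conditional inertia slopes per person.

    Columns ``<outcome>_withinday`` and ``<outcome>_overnight`` hold the
    shrunken person-specific slopes (gamma + u posterior means). Outcomes
    fitted on different person sets are aligned on the intersection.
    """
    frames = []
    for outcome, draws in draws_by_outcome.items():
        if "u" not in draws.param_names:
            raise KeyError("draws lack person effects; fit with person_effects=True")
        u = draws.draws("u")  # (chain, draw, person, 4)
        g20 = draws.draws("gamma20")[..., None]
        g30 = draws.draws("gamma30")[..., None]
        wd = (g20 + u[..., 2]).mean(axis=(0, 1))
        on = (g30 + u[..., 3]).mean(axis=(0, 1))
        frames.append(
            pd.DataFrame(
                {
                    "person_id": draws.data.person_ids,
                    f"{outcome}_withinday": wd,
                    f"{outcome}_overnight": on,
                }
            ).set_index("person_id")
        )
    out = frames[0]
    for f in frames[1:]:
        n_before = len(out)
        out = out.join(f, how="inner")
        if len(out) < max(n_before, len(f)):
            warnings.warn("outcomes fitted on different person sets; aligned on intersection")
    return out.reset_index()


def slope_correlations(slopes: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among the individual inertia slope columns."""
    cols = [c for c in slopes.columns if c != "person_id"]
    sub = slopes[cols]
    degenerate = [c for c in cols if float(sub[c].var()) < 1e-10]
    if degenerate:
        warnings.warn(f"zero-variance slope columns (no person heterogeneity): {degenerate}")
    return sub.corr()
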