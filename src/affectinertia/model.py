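"""Bayesian multilevel AR(1) model separating within-day and overnight inertia.

The observation model for beep t of person i is

    y_t = b0_{d,w,i} + b1_i * overnight_t + b2_i * lag_t * withinday_t
        + b3_i * lag_t * overnight_t + [extra fixed effects] + eps_t

with jointly correlated person-level random effects on the four base
terms, independent wave- and day-level intercept deviations and normal
residuals. Only rows with a non-missing, in-bounds lag enter the
likelihood.

Priors
------
Fixed effects get broad zero-centered normals (or improper flat priors);
scalar SDs (residual, wave, day) get half-Cauchy priors; the person
random-effect covariance gets the Huang-Wand (2013) prior, whose marginals
are half-t SDs and uniform correlations. All of these admit conjugate
conditionals (the half-Cauchy and Huang-Wand priors via inverse-gamma
mixture representations), so the posterior is explored with a blocked
Gibbs sampler in the centered parametrization, which mixes well when each
person contributes many beeps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

BASE_TERMS = ("intercept", "overnight", "withinday_inertia", "overnight_inertia")


class FittingError(RuntimeError):
    """The dataset is degenerate for the requested model."""


@dataclass
class Priors:
    """Prior settings. ``fixed_scale=None`` means improper flat priors."""

    fixed_scale: float | None = 10.0
    sd_scale: float = 5.0  # half-Cauchy / Huang-Wand scale for all SDs
    hw_nu: float = 2.0  # Huang-Wand nu; 2 => marginally uniform correlations


@dataclass
class MCMCConfig:
    chains: int = 4
    iterations: int = 1500
    warmup: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= self.warmup:
            raise ValueError("iterations must exceed warmup")


@dataclass
class ModelSpec:
    """Formula-level description of the inertia model."""

    outcome: str = "na"
    centering: str = "uncentered"
    extra_terms: tuple[str, ...] = ()
    person_effects: bool = True
    wave_intercepts: bool = True
    day_intercepts: bool = True
    priors: Priors = field(default_factory=Priors)

    @property
    def lag_column(self) -> str:
        base = f"{self.outcome}_lag"
        return base + "_centered" if self.centering == "person_mean" else base


@dataclass
class ModelData:
    """Design arrays extracted from a lagged dataset (eligible rows only)."""

    y: np.ndarray
    Z: np.ndarray  # (N, 4) base design: 1, overnight, lag*wd, lag*on
    Xe: np.ndarray  # (N, k) extra fixed-effect columns
    pidx: np.ndarray
    widx: np.ndarray | None
    didx: np.ndarray | None
    person_ids: np.ndarray
    n_waves_present: int
    extra_names: tuple[str, ...]


def build_model_data(lagged: pd.DataFrame, spec: ModelSpec) -> ModelData:
    lag_col = spec.lag_column
    for col in (spec.outcome, lag_col, "withinday", "overnight", "eligible"):
        if col not in lagged.columns:
            raise KeyError(f"lagged dataset lacks column {col!r}")
    df = lagged[lagged["eligible"].astype(bool)].copy()
    df = df[df[spec.outcome].notna() & df[lag_col].notna()]
    if len(df) == 0:
        y = np.empty(0)
    else:
        y = df[spec.outcome].to_numpy(float)
    lag = df[lag_col].to_numpy(float) if len(df) else np.empty(0)
    on = df["overnight"].to_numpy(float) if len(df) else np.empty(0)
    wd = df["withinday"].to_numpy(float) if len(df) else np.empty(0)
    Z = np.column_stack([np.ones_like(y), on, lag * wd, lag * on]) if len(df) else np.empty((0, 4))
    for name in spec.extra_terms:
        if name not in df.columns:
            raise KeyError(f"lagged dataset lacks extra term {name!r}")
    Xe = df[list(spec.extra_terms)].to_numpy(float) if spec.extra_terms and len(df) else np.empty((len(df), len(spec.extra_terms)))

    person_ids, pidx = (np.unique(df["person_id"].to_numpy(), return_inverse=True)
                        if len(df) else (np.empty(0, int), np.empty(0, int)))
    n_waves = int(df["wave"].nunique()) if len(df) else 0
    widx = didx = None
    if spec.wave_intercepts and n_waves > 1:
        _, widx = np.unique(df[["person_id", "wave"]].to_numpy(), axis=0, return_inverse=True)
    if spec.day_intercepts and len(df):
        _, didx = np.unique(df[["person_id", "wave", "day"]].to_numpy(), axis=0, return_inverse=True)
    return ModelData(
        y=y, Z=Z, Xe=Xe, pidx=pidx, widx=widx, didx=didx,
        person_ids=person_ids, n_waves_present=n_waves,
        extra_names=tuple(spec.extra_terms),
    )


# ----------------------------------------------------------------------
# log posterior (the backend contract)
# ----------------------------------------------------------------------
_LOG2PI = math.log(2.0 * math.pi)


def _log_halfcauchy(x: float, scale: float) -> float:
    if x < 0:
        return -np.inf
    return math.log(2.0 / (math.pi * scale)) - math.log1p((x / scale) ** 2)


def log_posterior(params: dict, data: ModelData, spec: ModelSpec) -> float:
    """Log joint density of Eq.-style model at one parameter point.

    ``params`` holds ``gamma`` (4 base + extras), and, when the respective
    component is active, ``u`` (n_persons, 4), ``Sigma_u`` (4, 4), ``xi``/
    ``sigma_wave``, ``zeta``/``sigma_day``, plus ``sigma_eps``. Rows with
    missing lag never reach ``data`` and contribute nothing.
    """
    pr = spec.priors
    gamma = np.asarray(params["gamma"], float)
    sigma_eps = float(params["sigma_eps"])
    if not np.all(np.isfinite(gamma)) or not np.isfinite(sigma_eps):
        raise ValueError("non-finite parameters")
    if sigma_eps <= 0:
        return -np.inf

    mu = data.Z @ gamma[:4]
    if data.Xe.shape[1]:
        mu = mu + data.Xe @ gamma[4:]
    if spec.person_effects:
        u = np.asarray(params["u"], float)
        mu = mu + np.einsum("nj,nj->n", data.Z, u[data.pidx])
    if data.widx is not None:
        mu = mu + np.asarray(params["xi"], float)[data.widx]
    if data.didx is not None:
        mu = mu + np.asarray(params["zeta"], float)[data.didx]
    resid = data.y - mu
    lp = -0.5 * np.sum((resid / sigma_eps) ** 2) - len(resid) * (
        math.log(sigma_eps) + 0.5 * _LOG2PI
    )

    # priors on fixed effects
    if pr.fixed_scale is not None:
        lp += float(
            -0.5 * np.sum((gamma / pr.fixed_scale) ** 2)
            - len(gamma) * (math.log(pr.fixed_scale) + 0.5 * _LOG2PI)
        )
    lp += _log_halfcauchy(sigma_eps, pr.sd_scale)

    if spec.person_effects:
        Sigma = np.asarray(params["Sigma_u"], float)
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            return -np.inf
        Sinv = np.linalg.inv(Sigma)
        u = np.asarray(params["u"], float)
        n_p = u.shape[0]
        lp += -0.5 * float(np.einsum("ij,jk,ik->", u, Sinv, u))
        lp += -0.5 * n_p * (logdet + 4 * _LOG2PI)
        # Huang-Wand marginal prior on Sigma (unnormalised)
        q, nu, A = 4, pr.hw_nu, pr.sd_scale
        lp += -0.5 * (nu + 2 * q) * logdet
        lp += -0.5 * (nu + q) * float(np.sum(np.log(nu * np.diag(Sinv) + 1.0 / A**2)))

    for name_sd, name_re in (("sigma_wave", "xi"), ("sigma_day", "zeta")):
        if (data.widx is not None and name_re == "xi") or (
            data.didx is not None and name_re == "zeta"
        ):
            sd = float(params[name_sd])
            if sd <= 0:
                return -np.inf
            re = np.asarray(params[name_re], float)
            lp += -0.5 * np.sum((re / sd) ** 2) - len(re) * (math.log(sd) + 0.5 * _LOG2PI)
            lp += _log_halfcauchy(sd, pr.sd_scale)
    return float(lp)


# ----------------------------------------------------------------------
# Gibbs sampler
# ----------------------------------------------------------------------
def _sample_mvn(rng, prec, rhs):
    """One draw from N(prec^-1 rhs, prec^-1)."""
    L = np.linalg.cholesky(prec)
    mean = np.linalg.solve(prec, rhs)
    z = rng.standard_normal(len(rhs))
    return mean + np.linalg.solve(L.T, z)


def _sample_invwishart(rng, df: float, scale: np.ndarray) -> np.ndarray:
    """Inverse-Wishart draw via the Bartlett decomposition."""
    q = scale.shape[0]
    L = np.linalg.cholesky(np.linalg.inv(scale))
    A = np.zeros((q, q))
    for j in range(q):
        A[j, j] = math.sqrt(rng.chisquare(df - j))
        for k in range(j):
            A[j, k] = rng.standard_normal()
    W = L @ A @ A.T @ L.T
    return np.linalg.inv(W)


def _chain(data: ModelData, spec: ModelSpec, n_iter: int, warmup: int, seed) -> dict:
    rng = np.random.default_rng(seed)
    pr = spec.priors
    A2 = pr.sd_scale**2
    nu, q = pr.hw_nu, 4
    N = len(data.y)
    n_p = len(data.person_ids)
    use_u = spec.person_effects and n_p > 0
    use_w = data.widx is not None
    use_d = data.didx is not None
    k_extra = data.Xe.shape[1]

    Z, Xe, y = data.Z, data.Xe, data.y
    pidx, widx, didx = data.pidx, data.widx, data.didx
    n_w = int(widx.max()) + 1 if use_w else 0
    n_d = int(didx.max()) + 1 if use_d else 0

    # fixed-per-run sufficient statistics
    if use_u:
        ZtZ = np.zeros((n_p, 4, 4))
        for j in range(4):
            for k in range(j + 1):
                v = np.bincount(pidx, Z[:, j] * Z[:, k], minlength=n_p)
                ZtZ[:, j, k] = v
                ZtZ[:, k, j] = v
    if use_w:
        cnt_w = np.bincount(widx, minlength=n_w)
    if use_d:
        cnt_d = np.bincount(didx, minlength=n_d)
    if k_extra:
        XtX = Xe.T @ Xe
    tau_inv2 = 0.0 if pr.fixed_scale is None else 1.0 / pr.fixed_scale**2

    # ---- initial state (data-informed + chain-specific jitter) --------
    Xfull = np.column_stack([Z, Xe]) if k_extra else Z
    if N > 4:
        coef, *_ = np.linalg.lstsq(Xfull, y, rcond=None)
        resid0 = y - Xfull @ coef
        s0 = float(np.std(resid0)) or 1.0
    else:
        coef = np.zeros(4 + k_extra)
        s0 = 1.0
    jit = rng.standard_normal(4 + k_extra)
    gamma_base = coef[:4] + 0.3 * jit[:4]
    gamma_extra = coef[4:] + 0.1 * jit[4:]
    sig2_eps = (s0 * math.exp(0.3 * rng.standard_normal())) ** 2
    b = np.tile(gamma_base, (n_p, 1)) + 0.1 * rng.standard_normal((n_p, 4)) if use_u else None
    Sigma = np.eye(4) * (0.5 * s0) ** 2
    a_u = np.full(4, 1.0)
    xi = np.zeros(n_w)
    zeta = np.zeros(n_d)
    sig2_w = (0.3 * s0) ** 2
    sig2_d = (0.3 * s0) ** 2
    a_eps = a_w = a_d = 1.0

    kept = n_iter - warmup
    out = {
        "gamma": np.empty((kept, 4 + k_extra)),
        "sigma_eps": np.empty(kept),
        "sd_u": np.empty((kept, 4)) if use_u else None,
        "corr_u": np.empty((kept, 4, 4)) if use_u else None,
        "u": np.empty((kept, n_p, 4)) if use_u else None,
        "sd_wave": np.empty(kept) if use_w else None,
        "sd_day": np.empty(kept) if use_d else None,
    }

    pe = np.einsum("nj,nj->n", Z, b[pidx]) if use_u else Z @ gamma_base
    xe = Xe @ gamma_extra if k_extra else 0.0

    for it in range(n_iter):
        wi = xi[widx] if use_w else 0.0
        di = zeta[didx] if use_d else 0.0

        if use_u:
            # blocked draw of (gamma_base, b): gamma_base is sampled from
            # its conditional with the person effects integrated out
            # (Woodbury on the per-person 4x4 statistics), then b | gamma.
            # This removes the gamma <-> mean(u) random-walk coupling.
            Sinv = np.linalg.inv(Sigma)
            r = y - xe - wi - di
            t = (
                np.stack(
                    [np.bincount(pidx, Z[:, j] * r, minlength=n_p) for j in range(4)], axis=1
                )
                / sig2_eps
            )
            C = ZtZ / sig2_eps
            M = np.linalg.inv(Sinv[None, :, :] + C)
            CM = np.einsum("nij,njk->nik", C, M)
            prec_g = C.sum(axis=0) - np.einsum("nij,njk->ik", CM, C) + tau_inv2 * np.eye(4)
            rhs_g = t.sum(axis=0) - np.einsum("nij,nj->i", CM, t)
            gamma_base = _sample_mvn(rng, prec_g, rhs_g)

            prec = Sinv[None, :, :] + C
            rhs = t + Sinv @ gamma_base
            Lp = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, rhs[:, :, None])[:, :, 0]
            zdraw = rng.standard_normal((n_p, 4))
            b = mean + np.linalg.solve(np.transpose(Lp, (0, 2, 1)), zdraw[:, :, None])[:, :, 0]
            pe = np.einsum("nj,nj->n", Z, b[pidx])

            # Sigma | b, gamma_base (Huang-Wand augmented)
            dev = b - gamma_base
            S = dev.T @ dev
            scale = 2.0 * nu * np.diag(1.0 / a_u) + S
            Sigma = _sample_invwishart(rng, nu + q - 1 + n_p, scale)
            Sinv = np.linalg.inv(Sigma)
            a_u = 1.0 / rng.gamma(
                0.5 * (nu + q), 1.0 / (nu * np.diag(Sinv) + 1.0 / A2), size=4
            )
        else:
            # no person effects: base terms are ordinary fixed effects
            r = y - xe - wi - di
            prec_g = Z.T @ Z / sig2_eps + tau_inv2 * np.eye(4)
            if N == 0:
                prec_g = prec_g + (1e-12 if tau_inv2 else 1.0) * np.eye(4) * (
                    0 if tau_inv2 else 1
                )
            rhs_g = Z.T @ r / sig2_eps if N else np.zeros(4)
            if tau_inv2 == 0.0 and N == 0:
                gamma_base = rng.standard_normal(4) * 1e3  # flat prior, no data
            else:
                gamma_base = _sample_mvn(rng, prec_g, rhs_g)
            pe = Z @ gamma_base

        if k_extra:
            r = y - pe - wi - di
            prec_e = XtX / sig2_eps + tau_inv2 * np.eye(k_extra)
            rhs_e = Xe.T @ r / sig2_eps
            gamma_extra = _sample_mvn(rng, prec_e, rhs_e)
            xe = Xe @ gamma_extra

        if use_w:
            r = y - pe - xe - (zeta[didx] if use_d else 0.0)
            ssum = np.bincount(widx, r, minlength=n_w)
            var = 1.0 / (cnt_w / sig2_eps + 1.0 / sig2_w)
            xi = var * ssum / sig2_eps + np.sqrt(var) * rng.standard_normal(n_w)
            sig2_w = 1.0 / rng.gamma(0.5 * (n_w + 1), 1.0 / (0.5 * np.sum(xi**2) + 1.0 / a_w))
            a_w = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / sig2_w + 1.0 / A2))
            wi = xi[widx]

        if use_d:
            r = y - pe - xe - wi
            ssum = np.bincount(didx, r, minlength=n_d)
            var = 1.0 / (cnt_d / sig2_eps + 1.0 / sig2_d)
            zeta = var * ssum / sig2_eps + np.sqrt(var) * rng.standard_normal(n_d)
            sig2_d = 1.0 / rng.gamma(0.5 * (n_d + 1), 1.0 / (0.5 * np.sum(zeta**2) + 1.0 / a_d))
            a_d = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / sig2_d + 1.0 / A2))
            di = zeta[didx]

        resid = y - pe - xe - wi - di
        sig2_eps = 1.0 / rng.gamma(
            0.5 * (N + 1), 1.0 / (0.5 * float(resid @ resid) + 1.0 / a_eps)
        )
        a_eps = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / sig2_eps + 1.0 / A2))

        if it >= warmup:
            j = it - warmup
            gam = np.concatenate([gamma_base, gamma_extra]) if k_extra else gamma_base.copy()
            out["gamma"][j] = gam
            out["sigma_eps"][j] = math.sqrt(sig2_eps)
            if use_u:
                sds = np.sqrt(np.diag(Sigma))
                out["sd_u"][j] = sds
                out["corr_u"][j] = Sigma / np.outer(sds, sds)
                out["u"][j] = b - gamma_base
            if use_w:
                out["sd_wave"][j] = math.sqrt(sig2_w)
            if use_d:
                out["sd_day"][j] = math.sqrt(sig2_d)
    return out


@dataclass
class ConvergenceReport:
    rhat: dict[str, float]
    ess_bulk: dict[str, float]
    ess_tail: dict[str, float]
    threshold: float
    converged: bool

    def to_dict(self) -> dict:
        return {
            "rhat": self.rhat,
            "ess_bulk": self.ess_bulk,
            "ess_tail": self.ess_tail,
            "threshold": self.threshold,
            "converged": self.converged,
        }


@dataclass
class PosteriorDraws:
    """Posterior samples plus metadata; ``idata`` is an arviz InferenceData."""

    idata: az.InferenceData
    spec: ModelSpec
    data: ModelData
    config: MCMCConfig
    convergence: ConvergenceReport | None = None

    @property
    def param_names(self) -> list[str]:
        return list(self.idata.posterior.data_vars)

    def draws(self, name: str) -> np.ndarray:
        """Samples of one parameter, shape (chains, draws, ...)."""
        return self.idata.posterior[name].to_numpy()

    def median(self, name: str) -> float:
        return float(np.median(self.draws(name)))

    def hdi(self, name: str, prob: float = 0.95) -> tuple[float, float]:
        lo, hi = az.hdi(self.draws(name).reshape(-1), hdi_prob=prob)
        return float(lo), float(hi)

    def summary_row(self, name: str) -> dict:
        lo, hi = self.hdi(name)
        return {"median": self.median(name), "hdi_low": lo, "hdi_high": hi}


_GAMMA_NAMES = ("gamma00", "gamma10", "gamma20", "gamma30")


def _to_idata(chains: list[dict], data: ModelData, k_extra: int) -> az.InferenceData:
    post = {}
    gam = np.stack([c["gamma"] for c in chains])  # (chains, draws, 4+k)
    for j, nm in enumerate(_GAMMA_NAMES):
        post[nm] = gam[:, :, j]
    for j, nm in enumerate(data.extra_names):
        post[f"b_{nm}"] = gam[:, :, 4 + j]
    post["sigma_eps"] = np.stack([c["sigma_eps"] for c in chains])
    if chains[0]["sd_u"] is not None:
        sd_u = np.stack([c["sd_u"] for c in chains])
        for j in range(4):
            post[f"sd_u{j}"] = sd_u[:, :, j]
        corr = np.stack([c["corr_u"] for c in chains])
        for j in range(4):
            for k in range(j):
                post[f"corr_u{k}{j}"] = corr[:, :, k, j]
        post["u"] = np.stack([c["u"] for c in chains])
    if chains[0]["sd_wave"] is not None:
        post["sd_wave"] = np.stack([c["sd_wave"] for c in chains])
    if chains[0]["sd_day"] is not None:
        post["sd_day"] = np.stack([c["sd_day"] for c in chains])
    dims = {"u": ["person", "effect"]}
    coords = {"person": data.person_ids, "effect": list(range(4))}
    return az.from_dict(posterior=post, dims=dims, coords=coords)


def diagnose(draws: PosteriorDraws, threshold: float = 1.05) -> ConvergenceReport:
    """Split-R-hat and bulk/tail effective sample size for scalar parameters."""
    post = draws.idata.posterior
    if post.sizes["chain"] < 2:
        raise ValueError("convergence diagnostics need at least 2 chains")
    names = [v for v in post.data_vars if post[v].ndim == 2]
    sub = post[names]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(sub, method="split")
        essb = az.ess(sub, method="bulk")
        esst = az.ess(sub, method="tail")
    rh = {v: float(rhat[v]) for v in names}
    finite = [v for v in rh.values() if np.isfinite(v)]
    return ConvergenceReport(
        rhat=rh,
        ess_bulk={v: float(essb[v]) for v in names},
        ess_tail={v: float(esst[v]) for v in names},
        threshold=threshold,
        converged=bool(all(v < threshold for v in finite)),
    )


def fit(
    lagged: pd.DataFrame,
    spec: ModelSpec | None = None,
    mcmc: MCMCConfig | None = None,
) -> PosteriorDraws:
    """Fit the inertia model by blocked Gibbs sampling.

    Emits a ConvergenceReport (warning, not failing, when any split-R-hat
    exceeds the threshold). Wave-level intercept deviations are skipped
    automatically when the data contain a single wave, where they are not
    separately identified from the person intercept.
    """
    spec = spec or ModelSpec()
    mcmc = mcmc or MCMCConfig()
    data = build_model_data(lagged, spec)
    if len(data.y) and float(np.var(data.y)) == 0.0:
        raise FittingError(f"outcome {spec.outcome!r} has zero variance on eligible rows")
    if len(data.y):
        if not (data.Z[:, 1] == 1).any() or not (data.Z[:, 1] == 0).any():
            raise FittingError("need eligible rows of both dummy types (within-day and overnight)")

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    chains = [_chain(data, spec, mcmc.iterations, mcmc.warmup, s) for s in seeds]
    idata = _to_idata(chains, data, data.Xe.shape[1])
    draws = PosteriorDraws(idata=idata, spec=spec, data=data, config=mcmc)
    try:
        report = diagnose(draws)
    except ValueError:
        report = None
    draws.convergence = report
    if report is not None and not report.converged:
        worst = max((v for v in report.rhat.values() if np.isfinite(v)), default=float("nan"))
        warnings.warn(f"MCMC may not have converged: max split-R-hat = {worst:.3f}")
    return draws
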