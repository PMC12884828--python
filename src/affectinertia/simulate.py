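"""Synthetic EMA data with a known multilevel AR(1) ground truth.

The generative model mirrors the analysis model: momentary affect follows

    y_t = b0_{d,w,i} + b1_i * overnight_t
        + b2_i * y_{t-1} * withinday_t + b3_i * y_{t-1} * overnight_t + eps_t

with person-level random effects (u0..u3) on intercept, morning effect and
both inertia slopes, wave- and day-level intercept deviations, and normal
residuals. The overnight coefficient can be pinned to a regime:
``continue`` (within-day decay over the full overnight gap), ``pause``
(decay over awake time only), ``stop`` (zero) or ``different`` (free).

Dynamics follow the linear model exactly on a continuous 0-10 scale.
Item scores are loading-scaled process values plus noise clipped to
[0, 100], which reproduces the mild floor skew typical of negative-affect
sliders; ``TruthParams.clip_composites`` additionally bounds the stored
composites to [0, 10] (floor-censoring induces spurious persistence, so
the default keeps the exact linear process for recovery studies).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import ModerationEffect, StudyDesign, TruthParams
from .schedule import build_beep_schedule, schedule_wake_times

NA_ITEMS = ["na_angry", "na_depressed", "na_frustrated", "na_unhappy"]
PA_ITEMS = ["pa_happy", "pa_pleased", "pa_joyful", "pa_enjoyment"]
URT_ITEMS = ["urt_stuck", "urt_worries", "urt_anticipation"]
SLEEP_ITEMS = ["sq_quality", "sq_refreshing", "sq_difficulty_falling", "sq_trouble_staying"]
#: sleep items reverse-scored before compositing
SLEEP_REVERSED = ["sq_difficulty_falling", "sq_trouble_staying"]
TRAITS = [
    "neuroticism",
    "rumination",
    "perceived_stress",
    "depression",
    "anxiety",
    "life_satisfaction",
]


@dataclass
class EmaData:
    """Long-format EMA tables: beep-level, morning-level and person-level."""

    beeps: pd.DataFrame
    mornings: pd.DataFrame
    persons: pd.DataFrame

    def to_csv(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.beeps.to_csv(outdir / "beeps.csv", index=False)
        self.mornings.to_csv(outdir / "mornings.csv", index=False)
        self.persons.to_csv(outdir / "persons.csv", index=False)

    @classmethod
    def from_csv(cls, indir) -> "EmaData":
        from pathlib import Path

        indir = Path(indir)
        return cls(
            beeps=pd.read_csv(indir / "beeps.csv"),
            mornings=pd.read_csv(indir / "mornings.csv"),
            persons=pd.read_csv(indir / "persons.csv"),
        )


def _clock_string(hours: float) -> str:
    h = hours % 24.0
    minutes = int(round(h * 60)) % (24 * 60)
    hh, mm = divmod(minutes, 60)
    suffix = "AM" if hh < 12 else "PM"
    h12 = hh % 12
    if h12 == 0:
        h12 = 12
    return f"{h12}:{mm:02d} {suffix}"


class EmaSimulator:
    """Simulate a measurement-burst EMA study from a known truth.

    Parameters
    ----------
    design : StudyDesign
        Sampling scheme (persons, waves, days, beeps, compliance, ...).
    truth : TruthParams
        Generating parameters for the modeled outcome.
    outcome : str
        Which composite ("na" or "pa") follows ``truth``; the other
        composite is generated from ``other_truth`` (defaults to the
        complementary reference parameterisation with no moderation).
    """

    def __init__(
        self,
        design: StudyDesign,
        truth: TruthParams,
        outcome: str = "na",
        other_truth: TruthParams | None = None,
    ) -> None:
        if outcome not in ("na", "pa"):
            raise ValueError("outcome must be 'na' or 'pa'")
        self.design = design
        self.truth = truth
        self.outcome = outcome
        if other_truth is None:
            from .design import negative_affect_truth, positive_affect_truth

            other_truth = (
                positive_affect_truth() if outcome == "na" else negative_affect_truth()
            )
            other_truth = replace(other_truth, moderation_effects={})
        self.other_truth = other_truth

    # ------------------------------------------------------------------
    def simulate(self, seed: int | None = None, apply_compliance: bool = True) -> EmaData:
        """Generate a full study; thin beeps/mornings to the compliance rate."""
        design = self.design
        root = np.random.SeedSequence(design.seed if seed is None else seed)
        (s_sched, s_person, s_cov, s_affect, s_other, s_items, s_miss) = [
            np.random.default_rng(c) for c in root.spawn(7)
        ]

        n, W, D, B = (
            design.n_persons,
            design.n_waves,
            design.n_days_per_wave,
            design.beeps_per_day,
        )

        # -- persons: schedules and traits -----------------------------
        wakes_pool = schedule_wake_times(design)
        wake = wakes_pool[s_person.integers(0, len(wakes_pool), size=n)]
        truth = self.truth
        traits = {
            t: truth.trait_means[t] + truth.trait_sds[t] * s_person.standard_normal(n)
            for t in TRAITS
        }
        # Beta-distributed person probabilities keep the marginal stressor
        # rate at stressor_prob (a clipped normal would inflate it)
        mu, sd = truth.stressor_prob, truth.stressor_prob_between_sd
        nu = mu * (1 - mu) / sd**2 - 1
        if nu > 0:
            p_stress = s_person.beta(mu * nu, (1 - mu) * nu, size=n)
        else:
            p_stress = np.full(n, mu)
        urt_pm = truth.urt_mean + truth.urt_between_sd * s_person.standard_normal(n)
        sq_pm = (
            truth.sleep_quality_mean
            + truth.sleep_quality_between_sd * s_person.standard_normal(n)
        )
        tib_pm = (
            truth.mean_time_in_bed
            + truth.time_in_bed_between_sd * s_person.standard_normal(n)
        )

        # -- schedules --------------------------------------------------
        tod = np.empty((n, W, D, B))
        for i in range(n):
            for w in range(W):
                tod[i, w] = build_beep_schedule(design, wake[i], s_sched, n_days=D)
        day_offset = (
            np.arange(W)[None, :, None, None] * design.wave_spacing_days
            + np.arange(D)[None, None, :, None]
        ) * 24.0
        timestamp = tod + day_offset

        # -- covariates -------------------------------------------------
        urt = np.clip(
            urt_pm[:, None, None, None]
            + truth.urt_within_sd * s_cov.standard_normal((n, W, D, B)),
            0.0,
            10.0,
        )
        stressor = (s_cov.random((n, W, D, B)) < p_stress[:, None, None, None]).astype(int)
        sq = np.clip(
            sq_pm[:, None, None]
            + truth.sleep_quality_within_sd * s_cov.standard_normal((n, W, D)),
            0.0,
            10.0,
        )
        tib = np.clip(
            tib_pm[:, None, None]
            + truth.time_in_bed_within_sd * s_cov.standard_normal((n, W, D)),
            3.0,
            14.0,
        )

        # true within-person deviations drive generative moderation
        cov_dev = {
            "urt": urt - urt_pm[:, None, None, None],
            "stressor": stressor - p_stress[:, None, None, None],
            "sleep_quality": (sq - sq_pm[:, None, None])[:, :, :, None] * np.ones(B),
        }

        # -- latent affect ----------------------------------------------
        latent = self._simulate_latent(truth, s_person, s_affect, cov_dev, traits, n, W, D, B)
        other = self._simulate_latent(
            self.other_truth,
            np.random.default_rng(root.spawn(1)[0]),
            s_other,
            cov_dev,
            traits,
            n,
            W,
            D,
            B,
        )
        na_latent, pa_latent = (latent, other) if self.outcome == "na" else (other, latent)

        # -- assemble beep table ----------------------------------------
        idx_p, idx_w, idx_d, idx_b = np.meshgrid(
            np.arange(n), np.arange(W), np.arange(D), np.arange(B), indexing="ij"
        )
        beeps = pd.DataFrame(
            {
                "person_id": idx_p.ravel() + 1,
                "wave": idx_w.ravel() + 1,
                "day": idx_d.ravel() + 1,
                "beep": idx_b.ravel() + 1,
                "timestamp": timestamp.ravel(),
                "na": (np.clip(na_latent, 0, 10) if truth.clip_composites else na_latent).ravel(),
                "pa": (np.clip(pa_latent, 0, 10) if truth.clip_composites else pa_latent).ravel(),
                "urt": urt.ravel(),
                "stressor": stressor.ravel(),
            }
        )
        self._add_items(beeps, NA_ITEMS, na_latent.ravel(), truth, s_items)
        self._add_items(beeps, PA_ITEMS, pa_latent.ravel(), truth, s_items)
        self._add_items(beeps, URT_ITEMS, urt.ravel(), truth, s_items)

        # -- mornings ----------------------------------------------------
        mp, mw, md = np.meshgrid(np.arange(n), np.arange(W), np.arange(D), indexing="ij")
        rise = wake[:, None, None] + s_cov.normal(0.0, 0.25, size=(n, W, D))
        bed = rise - tib
        mornings = pd.DataFrame(
            {
                "person_id": mp.ravel() + 1,
                "wave": mw.ravel() + 1,
                "day": md.ravel() + 1,
                "sleep_quality": sq.ravel(),
                "time_in_bed": tib.ravel(),
                "bed_time": [_clock_string(v) for v in bed.ravel()],
                "rise_time": [_clock_string(v) for v in rise.ravel()],
            }
        )
        sq_flat = sq.ravel()
        noise = s_items.normal(0.0, truth.item_error_sd, size=(sq_flat.size, 4))
        mornings[SLEEP_ITEMS[0]] = np.clip(sq_flat * 10 + noise[:, 0], 0, 100)
        mornings[SLEEP_ITEMS[1]] = np.clip(sq_flat * 10 + noise[:, 1], 0, 100)
        mornings[SLEEP_ITEMS[2]] = np.clip(100 - sq_flat * 10 + noise[:, 2], 0, 100)
        mornings[SLEEP_ITEMS[3]] = np.clip(100 - sq_flat * 10 + noise[:, 3], 0, 100)

        persons = pd.DataFrame({"person_id": np.arange(n) + 1, "wake_time": wake})
        for t in TRAITS:
            persons[t] = traits[t]

        data = EmaData(beeps=beeps, mornings=mornings, persons=persons)
        if apply_compliance and design.compliance < 1.0:
            data = apply_missingness(data, design.compliance, s_miss)
        return data

    # ------------------------------------------------------------------
    def _simulate_latent(self, truth, rng_person, rng_eps, cov_dev, traits, n, W, D, B):
        """Run the AR recursion on the latent 0-10 scale for one outcome."""
        design = self.design
        # person random effects via a matrix square root of the correlation
        cov = truth.re_covariance()
        vals, vecs = np.linalg.eigh(cov)
        L = vecs * np.sqrt(np.clip(vals, 0.0, None))
        u = rng_person.standard_normal((n, 4)) @ L.T

        g30 = truth.implied_gamma30(design)
        b0 = truth.gamma00 + u[:, 0]
        b1 = truth.gamma10 + u[:, 1]
        b2 = truth.gamma20 + u[:, 2]
        b3 = g30 + u[:, 3]
        for name, eff in truth.moderation_effects.items():
            if name in TRAITS:
                dev = traits[name] - truth.trait_means[name]
                b0 = b0 + eff.on_level * dev
                b2 = b2 + eff.on_within_ar * dev
                b3 = b3 + eff.on_overnight_ar * dev

        xi = rng_eps.normal(0.0, truth.sd_wave, size=(n, W))
        zeta = rng_eps.normal(0.0, truth.sd_day, size=(n, W, D))
        eps = rng_eps.normal(0.0, truth.sd_resid, size=(n, W, D, B))

        tv_effects = {
            name: eff
            for name, eff in truth.moderation_effects.items()
            if name in cov_dev
        }

        y = np.empty((n, W, D, B))
        b2_safe = np.clip(b2, -0.95, 0.95)
        for w in range(W):
            prev = None
            for d in range(D):
                for b in range(B):
                    mean = b0 + xi[:, w] + zeta[:, w, d]
                    slope_w = b2.copy()
                    slope_o = b3.copy()
                    for name, eff in tv_effects.items():
                        dev = cov_dev[name][:, w, d, b]
                        mean = mean + eff.on_level * dev
                        slope_w = slope_w + eff.on_within_ar * dev
                        slope_o = slope_o + eff.on_overnight_ar * dev
                    if d == 0 and b == 0:
                        # burst start: stationary mean of the within-day process
                        y[:, w, d, b] = (b0 + xi[:, w] + zeta[:, w, d]) / (1.0 - b2_safe) + eps[
                            :, w, d, b
                        ]
                    elif b == 0:  # first beep of the day: overnight carry-over
                        y[:, w, d, b] = mean + b1 + slope_o * prev + eps[:, w, d, b]
                    else:
                        y[:, w, d, b] = mean + slope_w * prev + eps[:, w, d, b]
                    prev = y[:, w, d, b]
        return y

    @staticmethod
    def _add_items(frame, names, latent, truth, rng) -> None:
        loadings = truth.item_loadings[: len(names)]
        for k, name in enumerate(names):
            load = loadings[k % len(loadings)]
            noise = rng.normal(0.0, truth.item_error_sd, size=latent.size)
            frame[name] = np.clip(load * latent * 10.0 + noise, 0.0, 100.0)


# ----------------------------------------------------------------------
def simulate_affect(
    design: StudyDesign,
    truth: TruthParams,
    seed: int | None = None,
    outcome: str = "na",
    apply_compliance: bool = False,
) -> EmaData:
    """Generate affect (and covariate columns) with moderation switched off."""
    bare = replace(truth, moderation_effects={})
    return EmaSimulator(design, bare, outcome=outcome).simulate(
        seed=seed, apply_compliance=apply_compliance
    )


def simulate_covariates(
    design: StudyDesign,
    truth: TruthParams,
    seed: int | None = None,
    outcome: str = "na",
    apply_compliance: bool = False,
) -> EmaData:
    """Generate the study with covariate moderation effects applied.

    Uses the same seed discipline as :func:`simulate_affect`: with an empty
    ``moderation_effects`` map the output is identical.
    """
    unknown = set(truth.moderation_effects) - set(TRAITS) - {"urt", "stressor", "sleep_quality"}
    if unknown:
        raise ValueError(f"unknown moderation covariates: {sorted(unknown)}")
    return EmaSimulator(design, truth, outcome=outcome).simulate(
        seed=seed, apply_compliance=apply_compliance
    )


def apply_missingness(
    data: EmaData, compliance: float, rng: np.random.Generator | int
) -> EmaData:
    """Thin beep and morning rows completely at random to the compliance rate."""
    if not (0 < compliance <= 1):
        raise ValueError("compliance must be in (0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if compliance == 1.0:
        return EmaData(data.beeps.copy(), data.mornings.copy(), data.persons.copy())
    keep_b = rng.random(len(data.beeps)) < compliance
    keep_m = rng.random(len(data.mornings)) < compliance
    return EmaData(
        beeps=data.beeps.loc[keep_b].reset_index(drop=True),
        mornings=data.mornings.loc[keep_m].reset_index(drop=True),
        persons=data.persons.copy(),
    )
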