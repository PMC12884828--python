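"""Study-design and data-generating-process descriptions for EMA simulations.

The simulator emulates a measurement-burst experience-sampling design:
repeated 14-day bursts ("waves") with five semi-random daily beeps anchored
to one of seven wake-time schedules, an ~80% answer rate, 0-100 slider
items averaged into 0-10 composites, and person-level heterogeneity in
both affect level and inertia.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Literal

import numpy as np
import yaml

Regime = Literal["continue", "pause", "stop", "different"]

#: magnitudes below this are treated as exactly zero in the power transform
_EPS = 1e-12


@dataclass
class StudyDesign:
    """Sampling-scheme parameters of the simulated EMA study.

    Defaults reproduce a 3-wave x 14-day x 5-beep burst design with beeps
    every 2-3 h (mean gap ~2.6 h), overnight gaps averaging ~13.6-13.7 h,
    seven wake-time-anchored schedules and 80% compliance.
    """

    n_persons: int = 100
    n_waves: int = 3
    n_days_per_wave: int = 14
    beeps_per_day: int = 5
    n_schedules: int = 7
    wake_time_range: tuple[float, float] = (5.0, 11.0)  # clock hours
    min_first_beep_offset: float = 55.0 / 60.0  # hours after wake
    first_beep_jitter: float = 0.5  # uniform jitter added on top of the offset
    latest_beep_after_wake: float = 12.0 + 55.0 / 60.0  # 23:55 for an 11 AM wake
    beep_gap_range: tuple[float, float] = (2.0, 3.0)
    target_mean_within_gap: float = 2.6
    target_mean_overnight_gap: float = 13.7
    wave_spacing_days: int = 270  # ~9 months between burst onsets
    compliance: float = 0.80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beep_gap_range[0] <= 0:
            raise ValueError("beep_gap_range lower bound must be > 0")
        if not (0 < self.compliance <= 1):
            raise ValueError("compliance must be in (0, 1]")
        if self.beeps_per_day < 2:
            raise ValueError("beeps_per_day must be >= 2")
        if self.wake_time_range[0] >= self.wake_time_range[1]:
            raise ValueError("wake_time_range must be increasing")

    @property
    def gap_window(self) -> tuple[float, float]:
        """Uniform sampling window for same-day gaps.

        The window is the widest symmetric interval around
        ``target_mean_within_gap`` contained in ``beep_gap_range`` so that
        drawn gaps respect the range while averaging to the target.
        """
        lo, hi = self.beep_gap_range
        t = self.target_mean_within_gap
        w = min(t - lo, hi - t)
        if w < 0:
            raise ValueError("target_mean_within_gap outside beep_gap_range")
        return (t - w, t + w)


@dataclass
class ModerationEffect:
    """Effects of one covariate on affect level and the two inertia slopes."""

    on_level: float = 0.0
    on_within_ar: float = 0.0
    on_overnight_ar: float = 0.0


def _default_corr() -> np.ndarray:
    return np.eye(4)


@dataclass
class TruthParams:
    """Ground-truth parameters of the generative multilevel AR(1) process.

    ``gamma00`` is the fixed intercept (0-10 affect units), ``gamma10`` the
    morning (overnight-dummy) main effect, ``gamma20``/``gamma30`` the
    within-day and overnight autoregressive coefficients.  ``sd_u0..sd_u3``
    and ``re_correlations`` parameterise the person-level random effects,
    ``sd_wave``/``sd_day`` the wave- and day-level intercept deviations and
    ``sd_resid`` the beep-level residual.
    """

    gamma00: float = 1.549
    gamma10: float = 0.180
    gamma20: float = 0.280
    gamma30: float = 0.190
    sd_u0: float = 1.049
    sd_u1: float = 0.241
    sd_u2: float = 0.157
    sd_u3: float = 0.147
    re_correlations: np.ndarray = field(default_factory=_default_corr)
    sd_wave: float = 0.431
    sd_day: float = 0.337
    sd_resid: float = 0.97
    regime: Regime = "different"
    clip_composites: bool = False
    mean_time_in_bed: float = 7.7
    moderation_effects: dict[str, ModerationEffect] = field(default_factory=dict)
    item_loadings: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    item_error_sd: float = 8.0  # on the 0-100 item scale
    # covariate-process parameters (0-10 composites unless noted)
    urt_mean: float = 3.52
    urt_between_sd: float = 1.91
    urt_within_sd: float = 1.78
    stressor_prob: float = 0.16
    stressor_prob_between_sd: float = 0.15
    sleep_quality_mean: float = 6.38
    sleep_quality_between_sd: float = 1.76
    sleep_quality_within_sd: float = 1.62
    time_in_bed_between_sd: float = 1.42
    time_in_bed_within_sd: float = 1.85
    trait_means: dict[str, float] = field(
        default_factory=lambda: {
            "neuroticism": 2.49,
            "rumination": 3.01,
            "perceived_stress": 1.76,
            "depression": 1.93,
            "anxiety": 2.39,
            "life_satisfaction": 3.67,
        }
    )
    trait_sds: dict[str, float] = field(
        default_factory=lambda: {
            "neuroticism": 0.63,
            "rumination": 0.78,
            "perceived_stress": 0.49,
            "depression": 0.80,
            "anxiety": 0.75,
            "life_satisfaction": 1.34,
        }
    )

    def __post_init__(self) -> None:
        self.re_correlations = np.asarray(self.re_correlations, dtype=float)
        for name in ("sd_u0", "sd_u1", "sd_u2", "sd_u3", "sd_wave", "sd_day", "sd_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        R = self.re_correlations
        if R.shape != (4, 4) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("re_correlations must be a symmetric 4x4 matrix with unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-10:
            raise ValueError("re_correlations must be positive semi-definite")
        if self.regime not in ("continue", "pause", "stop", "different"):
            raise ValueError(f"unknown regime {self.regime!r}")

    def re_covariance(self) -> np.ndarray:
        sds = np.array([self.sd_u0, self.sd_u1, self.sd_u2, self.sd_u3])
        return self.re_correlations * np.outer(sds, sds)

    def implied_gamma30(self, design: StudyDesign) -> float:
        """Overnight AR coefficient implied by the regime.

        continue: within-day decay over the full overnight gap; pause:
        decay over awake time only (overnight gap minus time in bed);
        stop: zero; different: the free ``gamma30``.
        """
        if self.regime == "different":
            return self.gamma30
        if self.regime == "stop":
            return 0.0
        gap = design.target_mean_overnight_gap
        if self.regime == "pause":
            gap = gap - self.mean_time_in_bed
            if gap <= 0:
                raise ValueError("mean_time_in_bed must be < overnight gap")
        ratio = gap / design.target_mean_within_gap
        return signed_power(self.gamma20, ratio)


def signed_power(gamma: float, ratio: float) -> float:
    """Sign-preserving power ``sign(gamma) * |gamma|**ratio`` (0 at 0)."""
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    a = abs(gamma)
    if a < _EPS:
        return 0.0
    return float(np.sign(gamma) * a**ratio)


def negative_affect_truth(**overrides) -> TruthParams:
    """Reference generating truth for negative-affect dynamics.

    Fixed effects and variance components follow published multilevel
    estimates for momentary negative affect in an adult community EMA
    sample (intercept 1.549, morning effect 0.180, within-day inertia
    0.280, overnight inertia 0.190); the residual SD (0.97) is backed out
    from the accompanying marginal/conditional R^2 of 0.092/0.647.
    """
    return TruthParams(**overrides)


def positive_affect_truth(**overrides) -> TruthParams:
    """Reference generating truth for positive-affect dynamics."""
    params = dict(
        gamma00=3.962,
        gamma10=0.785,
        gamma20=0.355,
        gamma30=0.186,
        sd_u0=1.455,
        sd_u1=0.735,
        sd_u2=0.138,
        sd_u3=0.148,
        sd_wave=0.409,
        sd_day=0.365,
        sd_resid=1.26,
    )
    params.update(overrides)
    return TruthParams(**params)


def _to_plain(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def design_to_yaml(design: StudyDesign, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(asdict(design)), fh, sort_keys=False)


def design_from_yaml(path) -> StudyDesign:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("wake_time_range", "beep_gap_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return StudyDesign(**raw)


def truth_to_yaml(truth: TruthParams, path) -> None:
    raw = asdict(truth)
    raw["moderation_effects"] = {
        k: asdict(v) if isinstance(v, ModerationEffect) else v
        for k, v in truth.moderation_effects.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(raw), fh, sort_keys=False)


def truth_from_yaml(path) -> TruthParams:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "re_correlations" in raw:
        raw["re_correlations"] = np.asarray(raw["re_correlations"])
    if "item_loadings" in raw:
        raw["item_loadings"] = tuple(raw["item_loadings"])
    if "moderation_effects" in raw:
        raw["moderation_effects"] = {
            k: ModerationEffect(**v) for k, v in raw["moderation_effects"].items()
        }
    return TruthParams(**raw)


__all__ = [
    "StudyDesign",
    "TruthParams",
    "ModerationEffect",
    "Regime",
    "signed_power",
    "negative_affect_truth",
    "positive_affect_truth",
    "design_to_yaml",
    "design_from_yaml",
    "truth_to_yaml",
    "truth_from_yaml",
    "replace",
]
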