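"""Shared fixtures: small simulated studies and reusable MCMC fits."""

from __future__ import annotations

import warnings

import pytest

from affectinertia.design import StudyDesign, negative_affect_truth, positive_affect_truth
from affectinertia.model import MCMCConfig, ModelSpec, fit
from affectinertia.preprocess import construct_lags
from affectinertia.simulate import EmaSimulator

warnings.filterwarnings("ignore", message="MCMC may not have converged")


@pytest.fixture(scope="session")
def na_truth():
    return negative_affect_truth()


@pytest.fixture(scope="session")
def na_fit_bundle(na_truth):
    """One moderate negative-affect study, lagged dataset and fitted model.

    Full compliance keeps every scheduled-adjacent pair intact so that
    parameter-recovery checks are free of exclusion-rule selection
    effects.
    """
    design = StudyDesign(
        n_persons=60, n_waves=1, n_days_per_wave=10, beeps_per_day=5, compliance=1.0
    )
    data = EmaSimulator(design, na_truth).simulate(seed=11)
    lagged = construct_lags(data.beeps)
    draws = fit(
        lagged,
        ModelSpec(outcome="na"),
        MCMCConfig(chains=2, iterations=1200, warmup=400, seed=7),
    )
    return {"design": design, "truth": na_truth, "data": data, "lagged": lagged, "draws": draws}


@pytest.fixture(scope="session")
def multiwave_fit_bundle():
    """Small 3-wave study with fits for both outcomes (reporting tests)."""
    design = StudyDesign(
        n_persons=30, n_waves=3, n_days_per_wave=5, beeps_per_day=5, compliance=0.9
    )
    data = EmaSimulator(design, negative_affect_truth(), other_truth=positive_affect_truth()).simulate(seed=21)
    lagged = construct_lags(data.beeps)
    cfg = MCMCConfig(chains=2, iterations=500, warmup=200, seed=5)
    draws = {
        "na": fit(lagged, ModelSpec(outcome="na"), cfg),
        "pa": fit(lagged, ModelSpec(outcome="pa"), cfg),
    }
    return {"design": design, "data": data, "lagged": lagged, "draws": draws}
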