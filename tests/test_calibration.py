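"""Survival calibration: AFT conversions, cycle probabilities, model selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renalcea import (
    GeneratorConfig,
    WeibullParams,
    aft_to_weibull,
    apply_hazard_ratio,
    calibrate,
    fit_parametric,
    generate_cohort,
    select_best,
    transition_probability,
)
from renalcea.calibration import AFTFit, calibration_report

from conftest import DEATH_PARAMS, DIALYSIS_PARAMS

# ranges keep cumulative hazards well inside floating-point range so the
# survival-function oracle stays finite
params_st = st.builds(
    WeibullParams,
    lam=st.floats(1e-4, 0.1),
    gamma=st.floats(0.3, 1.8),
)


# ---------------------------------------------------------------------------
# aft_to_weibull


@pytest.mark.parametrize(
    "intercept, scale, lam, gamma",
    [
        (0.0, 1.0, 1.0, 1.0),
        (4.0, 1.0, math.exp(-4.0), 1.0),
        (5.0, 2.0, math.exp(-2.5), 0.5),
    ],
)
def test_aft_to_weibull_closed_form(intercept, scale, lam, gamma):
    wp = aft_to_weibull(intercept, scale)
    assert wp.lam == pytest.approx(lam, rel=1e-12)
    assert wp.gamma == pytest.approx(gamma, rel=1e-12)


@given(lam=st.floats(1e-6, 10.0), gamma=st.floats(0.05, 20.0))
@settings(max_examples=200, deadline=None)
def test_aft_to_weibull_round_trip(lam, gamma):
    """Inverting the conversion recovers (lambda, gamma) to machine precision."""
    scale = 1.0 / gamma
    intercept = -math.log(lam) * scale
    wp = aft_to_weibull(intercept, scale)
    assert wp.lam == pytest.approx(lam, rel=1e-12)
    assert wp.gamma == pytest.approx(gamma, rel=1e-12)


def test_aft_to_weibull_rejects_nonpositive_scale():
    with pytest.raises(ValueError):
        aft_to_weibull(1.0, 0.0)


# ---------------------------------------------------------------------------
# transition_probability


@pytest.mark.parametrize(
    "lam, gamma, cycle, expected",
    [
        (0.008, 0.938, 1, 1 - math.exp(-0.008)),
        (0.043, 1.143, 2, 1 - math.exp(-0.043 * (2**1.143 - 1))),
    ],
)
def test_transition_probability_closed_form(lam, gamma, cycle, expected):
    p = transition_probability(WeibullParams(lam, gamma), cycle)
    assert p == pytest.approx(expected, rel=1e-12)


@given(params=params_st, cycle=st.integers(1, 60))
@settings(max_examples=300, deadline=None)
def test_transition_probability_equals_conditional_survival(params, cycle):
    """p(c) = 1 - S(c)/S(c-1) from the survival function, to <= 1e-12."""
    oracle = 1.0 - params.survival(cycle) / params.survival(cycle - 1)
    p = transition_probability(params, cycle)
    assert abs(p - oracle) <= 1e-12
    assert 0.0 < p <= 1.0  # saturates to 1.0 in floating point for huge hazards


@given(params=params_st, T=st.integers(1, 50))
@settings(max_examples=200, deadline=None)
def test_unconditional_probabilities_telescope_to_cumulative_incidence(params, T):
    """Sum of per-cycle unconditional event probabilities equals 1 - S(T)."""
    surv = 1.0
    total = 0.0
    for c in range(1, T + 1):
        p = transition_probability(params, c)
        total += surv * p
        surv *= 1.0 - p
    assert total == pytest.approx(1.0 - float(params.survival(T)), abs=1e-12)


def test_exponential_limit_is_cycle_constant():
    params = WeibullParams(0.1, 1.0)
    probs = {transition_probability(params, c) for c in range(1, 20)}
    assert max(probs) - min(probs) < 1e-15
    assert probs.pop() == pytest.approx(1 - math.exp(-0.1), rel=1e-12)


def test_transition_probability_rejects_cycle_below_one():
    with pytest.raises(ValueError):
        transition_probability(DIALYSIS_PARAMS, 0)


# ---------------------------------------------------------------------------
# apply_hazard_ratio


def test_hazard_ratio_identity_and_scaling():
    assert apply_hazard_ratio(DIALYSIS_PARAMS, 1.0) == DIALYSIS_PARAMS
    adj = apply_hazard_ratio(DIALYSIS_PARAMS, 0.42)
    assert adj.lam == pytest.approx(0.00336, rel=1e-12)
    assert adj.gamma == DIALYSIS_PARAMS.gamma
    with pytest.raises(ValueError):
        apply_hazard_ratio(DIALYSIS_PARAMS, 0.0)


@given(params=params_st, hr=st.floats(0.01, 0.999), cycle=st.integers(1, 40))
@settings(max_examples=200, deadline=None)
def test_protective_hazard_ratio_strictly_lowers_cycle_probability(params, hr, cycle):
    base = transition_probability(params, cycle)
    adj = transition_probability(apply_hazard_ratio(params, hr), cycle)
    assert adj < base


# ---------------------------------------------------------------------------
# fitting and selection


@pytest.fixture(scope="module")
def exponential_cohort():
    # gamma = 1 for both causes: data is exponential, nested in Weibull
    return generate_cohort(
        GeneratorConfig(
            n_subjects=20_000,
            dialysis_params=WeibullParams(0.05, 1.0),
            death_params=WeibullParams(0.02, 1.0),
            censor_horizon=10.0,
            seed=42,
        )
    )


def test_exponential_fit_recovers_rate(exponential_cohort):
    fit = fit_parametric(exponential_cohort, "dialysis", "exponential")
    lam_hat = fit.to_weibull().lam
    # events ~ Bin(n, p); rate MLE rel-SE ~ 1/sqrt(events)
    n_events = int((exponential_cohort["event"] == "dialysis").sum())
    assert abs(lam_hat - 0.05) / 0.05 < 3 / math.sqrt(n_events)


def test_weibull_fit_on_exponential_data_gives_unit_shape(exponential_cohort):
    fit = fit_parametric(exponential_cohort, "dialysis", "weibull")
    assert fit.to_weibull().gamma == pytest.approx(1.0, abs=0.05)


def test_weibull_loglik_dominates_nested_exponential(exponential_cohort):
    fw = fit_parametric(exponential_cohort, "dialysis", "weibull")
    fe = fit_parametric(exponential_cohort, "dialysis", "exponential")
    assert fw.loglik >= fe.loglik - 1e-6
    # on truly exponential data the 2-point AIC penalty favours the 1-param fit
    sel = select_best([fw, fe], "aic")
    assert sel.selected.distribution == "exponential"


def test_weibull_parameter_recovery_from_base_case_cohort():
    coh = generate_cohort(
        GeneratorConfig(20_000, DIALYSIS_PARAMS, DEATH_PARAMS, 5.0, seed=12345)
    )
    wp = fit_parametric(coh, "death", "weibull").to_weibull()
    assert wp.lam == pytest.approx(DEATH_PARAMS.lam, rel=0.10)
    assert wp.gamma == pytest.approx(DEATH_PARAMS.gamma, rel=0.10)


def test_fit_requires_events_of_the_requested_cause():
    data = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": ["censored"] * 3})
    with pytest.raises(ValueError, match="degenerate"):
        fit_parametric(data, "death", "weibull")


def test_fit_rejects_unknown_distribution_and_cause(exponential_cohort):
    with pytest.raises(ValueError, match="unknown distribution"):
        fit_parametric(exponential_cohort, "death", "gamma")
    with pytest.raises(ValueError, match="cause"):
        fit_parametric(exponential_cohort, "transplant", "weibull")


def test_information_criteria_definitions():
    fit = AFTFit("weibull", intercept=1.0, scale=0.5, loglik=-100.0, n_params=2, n_obs=50)
    assert fit.aic == pytest.approx(2 * 2 - 2 * (-100.0))
    assert fit.bic == pytest.approx(2 * math.log(50) - 2 * (-100.0))


def test_select_best_singleton_and_empty():
    fit = AFTFit("weibull", 1.0, 0.5, -10.0, 2, 20)
    assert select_best([fit]).selected is fit
    with pytest.raises(ValueError):
        select_best([])


def test_select_best_tie_breaks_by_canonical_order():
    # identical criteria: weibull precedes lognormal in the canonical ordering
    a = AFTFit("lognormal", 1.0, 0.5, -10.0, 2, 20)
    b = AFTFit("weibull", 1.0, 0.5, -10.0, 2, 20)
    assert select_best([a, b]).selected.distribution == "weibull"


def test_nonconvertible_distribution_rejected_for_weibull_params():
    fit = AFTFit("logistic", 1.0, 0.5, -10.0, 2, 20)
    with pytest.raises(ValueError, match="convert"):
        fit.to_weibull()


def test_calibration_report_structure_and_selection_consistency():
    coh = generate_cohort(
        GeneratorConfig(5_000, DIALYSIS_PARAMS, DEATH_PARAMS, 5.0, seed=2)
    )
    report = calibration_report(coh)
    for cause in ("dialysis", "death"):
        entry = report["causes"][cause]
        assert len(entry["fits"]) == 5
        best = min(entry["fits"], key=lambda f: f["aic"])
        assert entry["selected"] == best["distribution"]
        # derived (lambda, gamma) accompany the winner exactly when it converts
        assert ("weibull_params" in entry) == (entry["selected"] in ("weibull", "exponential"))
    sel = calibrate(coh, "death")
    assert sel.selected.aic == min(f.aic for f in sel.fits)
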