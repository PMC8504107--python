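import pytest
from hypothesis import settings as hyp_settings

from renalcea import (
    CostInputs,
    ModelSettings,
    TransitionSet,
    WeibullParams,
    apply_hazard_ratio,
    load_config,
)

hyp_settings.register_profile("deterministic", derandomize=True)
hyp_settings.load_profile("deterministic")

# Published base-case parameter set, used across the suite.
DIALYSIS_PARAMS = WeibullParams(lam=0.008, gamma=0.938)
DEATH_PARAMS = WeibullParams(lam=0.043, gamma=1.143)
HR_DIALYSIS = 0.42


@pytest.fixture(scope="session")
def base_config():
    cfg, _ = load_config()
    return cfg


@pytest.fixture(scope="session")
def base_settings():
    return ModelSettings()


@pytest.fixture(scope="session")
def base_costs():
    return CostInputs(
        rhp_treatment_annual=531.18,
        soc_treatment_annual=45.18,
        dialysis_annual=13458.79,
        rhp_initial=30412.0,
        rhp_operational_annual=4995.0,
        cohort_size=1000,
    )


@pytest.fixture(scope="session")
def soc_transitions():
    return TransitionSet(
        ckd_to_dialysis=DIALYSIS_PARAMS,
        ckd_to_death=DEATH_PARAMS,
        dialysis_to_death=0.05,
    )


@pytest.fixture(scope="session")
def rhp_transitions():
    return TransitionSet(
        ckd_to_dialysis=apply_hazard_ratio(DIALYSIS_PARAMS, HR_DIALYSIS),
        ckd_to_death=DEATH_PARAMS,
        dialysis_to_death=0.05,
    )
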