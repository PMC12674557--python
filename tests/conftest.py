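import numpy as np
import pytest

from hcc_cea import config as cfgmod
from hcc_cea import synthetic_trial as st

# the fitted comparator-arm baselines used throughout: Weibull OS and
# log-normal PFS, time in months
OS_WEIBULL = (0.01546928, 1.385069)
PFS_LOGNORMAL = (1.908634, 0.9985375)


@pytest.fixture(scope="session")
def base_config() -> dict:
    return cfgmod.default_config()


@pytest.fixture(scope="session")
def base_output(base_config):
    return cfgmod.run_model(base_config)


def make_trial(
    n=300,
    family="weibull",
    params=OS_WEIBULL,
    cutoff=40.0,
    accrual=20.0,
    seed=0,
):
    design = st.TrialDesign(
        n_subjects=n,
        event_family=family,
        event_params=params,
        cutoff_months=cutoff,
        accrual_months=accrual,
        seed=seed,
    )
    return st.simulate_trial_ipd(design)


@pytest.fixture(autouse=True)
def _silence_curve_clamp_warning():
    """The late-time PFS/OS curve crossing is clamped by design; keep test
    output readable."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="PFS curve exceeds OS curve", category=UserWarning
        )
        yield
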