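import numpy as np
import pytest
from hypothesis import settings

import lntransit as ln
from lntransit.synthetic import TruthSpec, simulate_cohort, simulate_open_loop

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def system_from(result):
    """Grid a synthetic experiment and estimate c, returning the system."""
    sys_ = ln.build_convolution_system(
        ln.interpolate_to_grid(result.timecourse, "linear")
    )
    ln.estimate_c(sys_)
    return sys_


@pytest.fixture(scope="session")
def ig_spec():
    """Noise-free inverse-Gaussian truth on the exact 2-hour schedule."""
    return TruthSpec(
        transit_family="inverse_gaussian",
        family_params={"mu": 30.0, "lam": 60.0},
        blood_tau=7.0,
        noise_model="none",
        schedule="uniform_2h",
        seed=1,
    )


@pytest.fixture(scope="session")
def ig_result(ig_spec):
    return simulate_open_loop(ig_spec)


@pytest.fixture(scope="session")
def ig_system(ig_result):
    return system_from(ig_result)


@pytest.fixture(scope="session")
def mc_truth_params():
    """Zero-drift walk used as a skewed ground truth throughout."""
    return {"q_fwd": 0.3, "q_bwd": 0.3, "q_stay": 0.4,
            "n_vertices": 10, "dt_min": 5.0}


@pytest.fixture(scope="session")
def noisy_cohort(mc_truth_params):
    """Eight replicate noisy experiments from the zero-drift walk truth."""
    spec = TruthSpec(
        transit_family="mc",
        family_params=mc_truth_params,
        noise_model="gaussian_multiplicative",
        noise_param=0.05,
        schedule="cannulation",
        seed=100,
    )
    return [system_from(r) for r in simulate_cohort(spec, 8)]
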