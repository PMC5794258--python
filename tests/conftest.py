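import numpy as np
import pytest

from cochsyn import KineticParams, RefractoryParams


@pytest.fixture(scope="session")
def wt_fm_params() -> KineticParams:
    """Wild-type forward-masking parameter column of the model table."""
    return KineticParams(n_slots=8.0, k_refill_spont=13.3,
                         k_refill_stim=29.5, k_fus_spont=0.6,
                         k_fus_stim=32.2, f=1.0)


@pytest.fixture(scope="session")
def wt_global_params() -> KineticParams:
    """Wild-type global tone-burst parameter column."""
    return KineticParams(n_slots=15.6, k_refill_spont=5.59,
                         k_refill_stim=18.4, k_fus_spont=0.63,
                         k_fus_stim=82.5, f=1.0)


@pytest.fixture(scope="session")
def refrac() -> RefractoryParams:
    return RefractoryParams(t_abs=0.6e-3, tau_rel=0.6e-3)


@pytest.fixture(scope="session")
def table1_wt() -> dict:
    """Wild-type double-exponential adaptation parameters (ms / Hz)."""
    return dict(tau_fast=6.31, tau_slow=95.63,
                amp_fast=484.61, amp_slow=58.42)
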