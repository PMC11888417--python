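import numpy as np
import pytest

from orgmodel import ResponseParams, SimulationConfig, simulate_single_flash_trace

#: exemplar single-flash parameters (8% bleach scale response)
EXEMPLAR = ResponseParams(a0=-36.4, a1=200.8, tau_a=9.5, tau_b=0.07)


@pytest.fixture(scope="session")
def exemplar_params() -> ResponseParams:
    return EXEMPLAR


@pytest.fixture(scope="session")
def noiseless_trace():
    """Noiseless 3 s / 400 Hz exemplar trace, flash at 200 ms."""
    return simulate_single_flash_trace(
        EXEMPLAR, SimulationConfig(noise_sigma_nm=0.0)
    )


def grid_argmax_tmax(params: ResponseParams, fine_step: float = 1e-5) -> float:
    """Independent brute-force argmax of the single-flash response.

    Two-stage search at effective 1e-5 s resolution: a coarse 1e-3 s scan
    over [0, 20/tau_b] followed by refinement around the coarse argmax.
    """
    from orgmodel import eval_single_flash

    span = 20.0 / params.tau_b
    coarse = np.arange(0.0, span, 1e-3)
    i = int(np.argmax(eval_single_flash(params, coarse)))
    lo = max(coarse[i] - 2e-3, 0.0)
    hi = coarse[i] + 2e-3
    fine = np.arange(lo, hi, fine_step)
    j = int(np.argmax(eval_single_flash(params, fine)))
    return float(fine[j])
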