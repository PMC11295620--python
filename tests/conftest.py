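"""Shared fixtures: parameter sets, synthetic datasets, small cohorts."""

import numpy as np
import pytest

from mirqsp.parameters import human_defaults, mouse_defaults


@pytest.fixture(scope="session")
def mouse_params():
    return mouse_defaults()


@pytest.fixture(scope="session")
def human_params():
    return human_defaults()


@pytest.fixture(scope="session")
def growth_only_mouse(mouse_params):
    """Mouse parameters with all death terms off and carrying capacity huge.

    In this limit untreated growth is exactly exponential with rate
    gamma * (1 + (A_ML - 1) * M*/(k_M + M*)).
    """
    return mouse_params.replace(delta_chemo=1e-12, delta_immun=1e-12, K=1e9)


@pytest.fixture(scope="session")
def noiseless_preclinical(mouse_params):
    from mirqsp.synthetic import generate_preclinical

    return generate_preclinical(mouse_params, noise_cv=0.0, seed=0)


@pytest.fixture(scope="session")
def small_cohort(human_params):
    from mirqsp.cohort import generate_cohort

    return generate_cohort(human_params, n=20, seed=1)


def growth_rate(params):
    """Closed-form net exponential rate in the growth-only limit."""
    m_t = params.g0_M_t / (params.delta_M + params.k_exo)
    m_c = (params.g0_M_c + params.k_exo * m_t) / params.delta_M
    return params.gamma * (1 + (params.A_ML - 1) * m_c / (params.k_M + m_c))


@pytest.fixture(scope="session")
def exp_growth_rate(growth_only_mouse):
    return growth_rate(growth_only_mouse)
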