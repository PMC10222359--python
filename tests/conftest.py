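import numpy as np
import pytest

from pilotbe.popsim import PopulationModel, TrialDesign, simulate_trial


@pytest.fixture(scope="session")
def baseline_model():
    return PopulationModel()


@pytest.fixture(scope="session")
def design12():
    return TrialDesign(n_subjects=12)


@pytest.fixture(scope="session")
def baseline_trial(baseline_model, design12):
    return simulate_trial(baseline_model, design12, seed=1234)


def make_noise_free_trial(multiplier=1.0, n_subjects=12, seed=7, **model_kwargs):
    """Deterministic trial: no residual error, no IIV/IOV unless overridden."""
    model = PopulationModel(
        residual_cv=0.0, test_ka_multiplier=multiplier, **model_kwargs
    )
    return simulate_trial(model, TrialDesign(n_subjects=n_subjects), seed)


@pytest.fixture(scope="session")
def noise_free_be_trial():
    return make_noise_free_trial(1.0)


@pytest.fixture(scope="session")
def noise_free_bie_trial():
    return make_noise_free_trial(0.3)


def ode_concentrations(ka, v, ke, f, dose_mg, times):
    """Independent stiff-ODE oracle for the one-compartment oral model.

    Integrates gut and central amounts (plus a cumulative-elimination
    state for mass-balance checks) and returns concentrations in ug/L.
    """
    from scipy.integrate import solve_ivp

    dose_ug = dose_mg * 1000.0

    def rhs(t, y):
        a_gi, a1, elim = y
        return [-ka * a_gi, ka * a_gi - ke * a1, ke * a1]

    t = np.asarray(times, dtype=float)
    sol = solve_ivp(
        rhs, (0.0, max(t[-1], 1e-9)), [f * dose_ug, 0.0, 0.0],
        t_eval=t, method="Radau", rtol=1e-10, atol=1e-10,
    )
    return sol.y[1] / v, sol.y


def analytic_auc_0_to_t(ka, v, ke, f, dose_mg, t_end):
    """Closed-form integral of the model concentration from 0 to t_end."""
    amp = f * dose_mg * 1000.0 * ka / (v * (ka - ke))
    return amp * ((1 - np.exp(-ke * t_end)) / ke - (1 - np.exp(-ka * t_end)) / ka)
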