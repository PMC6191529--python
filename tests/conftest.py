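import numpy as np
import pytest

from flsim import default_fl_parameters
from flsim.parameters import BetaParam, DirichletParam
from flsim.survival import TTESpec

YEAR = 365.25


@pytest.fixture(scope="session")
def default_ps():
    return default_fl_parameters()


@pytest.fixture()
def ps(default_ps):
    """A mutable copy of the default parameter set."""
    return default_ps.copy()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def make_not_treated_ps(base):
    """Degenerate parameter set: every patient is palliative (end-of-life
    exponential, mean 75 days), management assignment instantaneous."""
    ps = base.copy()
    for band in ps.age_bands.bands:
        band.management = DirichletParam((0, 0, 0, 0, 1))
    ps.transitions["pretreatment_to_management"] = TTESpec(
        "exponential", (1e6,))
    return ps


def make_markov_ps(base, lam1=0.5, mu0=0.3, rho=2.0, mu1=0.4, gam=0.4,
                   mu2=0.25):
    """All-exponential watch-and-wait / treatment / remission reduction with
    identical parameters across lines and (numerically) zero transformation
    and refractory rates, so occupancy follows a 4-state Markov chain."""
    ps = base.copy()
    for band in ps.age_bands.bands:
        band.management = DirichletParam((0, 0, 0, 1, 0))
        band.ww_rituximab = BetaParam(0, 1)
    ps.max_age = 1000.0  # remove the age cap so occupancy is uncensored
    t = ps.transitions
    t["pretreatment_to_management"] = TTESpec("exponential", (1e6,))
    t["ww_to_treatment"] = TTESpec("exponential", (lam1 / YEAR,))
    t["ww_to_death"] = TTESpec("exponential", (mu0 / YEAR,))
    t["ww_to_transform"] = TTESpec("exponential", (1e-15,))
    for line in (1, 2, 3):
        t[f"treatment{line}_response"] = TTESpec("exponential", (rho / YEAR,))
        t[f"treatment{line}_death"] = TTESpec("exponential", (mu1 / YEAR,))
        t[f"treatment{line}_refractory"] = TTESpec("exponential", (1e-15,))
        t[f"treatment{line}_transform"] = TTESpec("exponential", (1e-15,))
        t[f"remission{line}_relapse"] = TTESpec("exponential", (gam / YEAR,))
        t[f"remission{line}_death"] = TTESpec("exponential", (mu2 / YEAR,))
        t[f"remission{line}_transform"] = TTESpec("exponential", (1e-15,))
    return ps
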