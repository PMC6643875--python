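import numpy as np
import pandas as pd
import pytest

from screenmix.mixture import FitConfig, MixtureFit, fit_mixture, classify_fit
from screenmix.pipeline import build_screen_table
from screenmix.screen_io import PlateGeometry, colony_frame
from screenmix.simulate import SimConfig, simulate_screen


def make_fit(rho2, mu1, sigma1, mu2, sigma2, n=1000, classification=None) -> MixtureFit:
    """Hand-assembled MixtureFit for closed-form tests (no EM involved)."""
    fit = MixtureFit(rho2=rho2, mu1=mu1, sigma1=sigma1, mu2=mu2, sigma2=sigma2,
                     loglik=0.0, n=n, n_iter=0, converged=True)
    fit.classification = classification or classify_fit(fit)
    return fit


@pytest.fixture(scope="session")
def canonical_config() -> SimConfig:
    """The canonical simulated screen: n=4000, rho2=0.15, target null sd 0.2,
    hit peak at 1.0 with sd 0.4, 4 replicates, 2 controls."""
    return SimConfig.for_target_lgr(n_genes=4000, seed=1, rho2=0.15, mu2=1.0,
                                    sigma1=0.2, sigma2=0.4)


@pytest.fixture(scope="session")
def canonical_screen(canonical_config):
    """(screen_table, truth, fit) for the canonical screen — computed once."""
    obs, truth = simulate_screen(canonical_config)
    screen = build_screen_table(colony_frame(obs), canonical_config.geometry)
    fit = fit_mixture(screen.data["lgr_smoothed"].to_numpy(dtype=float),
                      FitConfig(seed=1))
    return screen, truth, fit


@pytest.fixture
def geometry() -> PlateGeometry:
    return PlateGeometry(16, 24)
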