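import numpy as np
import pandas as pd
import pytest

from emaclarity.simulate import StudyDesign, simulate_study, attach_traits
from emaclarity.wiener import sample_fpt
from emaclarity.irt import DiffusionIRT

B_TRUE = np.array([-1.0, -0.3, 0.4, 1.1])


@pytest.fixture(scope="session")
def tiny_study():
    """25 persons x 3 days of raw synthetic EMA data with ground truth."""
    design = StudyDesign(n_persons=25, n_days=3)
    ema, truth = simulate_study(design, seed=11)
    return ema, truth


@pytest.fixture(scope="session")
def model_sim():
    """Responses/RTs drawn directly from the D-diffusion model at known
    parameters (600 occasions, 4 items, constant ter)."""
    rng = np.random.default_rng(7)
    O, I = 600, 4
    z1 = rng.standard_normal(O)
    z2 = rng.standard_normal(O)
    theta = 1.0 * z1
    A = np.exp(np.log(2.0) + 0.15 * z2)
    ter = 0.35
    v = theta[:, None] - B_TRUE[None, :]
    resp, rt = sample_fpt(v.ravel(), np.repeat(A, I), np.full(O * I, ter), rng)
    return {
        "responses": resp.reshape(O, I).astype(float),
        "rts": rt.reshape(O, I),
        "theta": theta,
        "alpha": A,
        "ter": ter,
        "b": B_TRUE,
        "sd_theta": 1.0,
        "mu_logalpha": float(np.log(2.0)),
    }


@pytest.fixture(scope="session")
def fitted_small(model_sim):
    """A converged small-scale fit used by scoring/diagnostic tests."""
    mod = DiffusionIRT(model_sim["responses"], model_sim["rts"],
                       ter_policy="global", quadrature_nodes=7)
    return mod.fit(n_starts=1, seed=0)


@pytest.fixture(scope="session")
def traits_tiny(tiny_study):
    _, truth = tiny_study
    return attach_traits(truth, seed=13)
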