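import numpy as np
import pytest

import envpls as ep


@pytest.fixture(scope="session")
def small_sim():
    """A small unbalanced GE-dominated trial with environmental covariates."""
    cfg = ep.SimConfig(J=30, I=4, p=120, r=5, var_env=0.5, var_g=1.0,
                       var_ge=2.0, var_resid=1.0, missing_fraction=0.1, seed=42)
    return ep.simulate(cfg)


@pytest.fixture(scope="session")
def tiny_gblup_setup():
    """J=4 lines x I=3 environments toy with known variance components."""
    rng = np.random.default_rng(7)
    M = rng.integers(0, 3, (4, 60)).astype(float)
    G = ep.compute_G(M, line_ids=[f"L{j}" for j in range(1, 5)])
    H = ep.identity_H(3)
    idx = ep.ObservationIndex.balanced(H.ids, G.ids)
    vc = {"env": 0.8, "g": 1.2, "ge": 0.5, "resid": 0.7}
    ei, li = idx.env_positions(), idx.line_positions()
    LE = ep.matrix_sqrt(H).matrix
    Lg = ep.matrix_sqrt(G).matrix
    L = np.sqrt(vc["env"]) * LE @ rng.standard_normal(3)
    g = np.sqrt(vc["g"]) * Lg @ rng.standard_normal(4)
    gl = np.sqrt(vc["ge"]) * (LE @ rng.standard_normal((3, 4)) @ Lg).reshape(-1)
    y = 5.0 + L[ei] + g[li] + gl[ei * 4 + li] + np.sqrt(vc["resid"]) * rng.standard_normal(idx.n)
    return y, idx, G, H, vc
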