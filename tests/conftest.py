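import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # local oracles module

from uindel import SimulationConfig, build_template_pair, simulate_experiment


@pytest.fixture(scope="session")
def toy1():
    """4-ES template: two insertion sites (ES 1, 2) and two shared sites."""
    return build_template_pair("ACGAG", "ACGUUAUG")


@pytest.fixture(scope="session")
def toy2():
    """2-ES template: a deletion site (ES 2) and an insertion site (ES 1)."""
    return build_template_pair("AUUCG", "ACUG")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


def random_template(rng, n_es=None, max_u=3, allow_shared=True):
    """Random template pair as raw (pre, full) sequences plus the truth vectors."""
    if n_es is None:
        n_es = int(rng.integers(2, 31))
    backbone = "".join(rng.choice(list("ACG"), size=n_es + 1))
    while True:
        u_pre = rng.integers(0, max_u + 1, size=n_es)
        u_full = rng.integers(0, max_u + 1, size=n_es)
        if not allow_shared:
            bump = u_pre == u_full
            u_full[bump] += 1
        if (u_pre != u_full).any():
            break
    u5p, u3p = int(rng.integers(0, 3)), int(rng.integers(0, 3))
    u5f, u3f = int(rng.integers(0, 3)), int(rng.integers(0, 3))
    from uindel.template import synthesize

    pre = synthesize(backbone, u_pre, u5p, u3p)
    full = synthesize(backbone, u_full, u5f, u3f)
    return pre, full, backbone, u_pre, u_full


def random_standard_read(rng, pair, max_u=4):
    """Random standard read over a pair, with its true per-ES U counts."""
    from uindel.template import synthesize

    u = rng.integers(0, max_u + 1, size=pair.n_es)
    u5, u3 = int(rng.integers(0, 3)), int(rng.integers(0, 3))
    return synthesize(pair.backbone, u, u5, u3), u, u5, u3


@pytest.fixture(scope="session")
def organizer_experiment():
    """Full-scale planted-EPS experiment (shared across recovery tests)."""
    cfg = SimulationConfig(seed=1, junction_profile="organizer_like")
    pair, induced, controls, truth = simulate_experiment(cfg)
    return cfg, pair, induced, controls, truth
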