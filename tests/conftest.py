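"""Shared fixtures: default synthetic campaigns and trained models.

The expensive artifacts (generated campaigns, trained networks, the
kinetic-recovery experiment) are session-scoped so the unit tests and the
acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from biohybrid import digestion_model as dm
from biohybrid import hybrid_model as hm
from biohybrid import kinetics as kin
from biohybrid import synthetic_data as sd


@pytest.fixture(scope="session")
def transester_config():
    return sd.TransesterGenConfig()


@pytest.fixture(scope="session")
def transester_campaign(transester_config):
    return sd.gen_transester(transester_config)


@pytest.fixture(scope="session")
def ann1_dataset(transester_campaign):
    trajectories, _ = transester_campaign
    return hm.build_ann1_dataset(trajectories, seed=0)


@pytest.fixture(scope="session")
def trained_hnm(transester_campaign, transester_config):
    trajectories, _ = transester_campaign
    hnm, result = hm.train_hnm(trajectories, transester_config.true_params, seed=1)
    return hnm, result


@pytest.fixture(scope="session")
def digestion_config():
    return sd.DigestionGenConfig()


@pytest.fixture(scope="session")
def digestion_campaign(digestion_config):
    return sd.gen_digestion(digestion_config)


@pytest.fixture(scope="session")
def ann2_dataset(digestion_campaign):
    records, _ = digestion_campaign
    return dm.build_ann2_dataset(records, holdout_run=3, seed=0)


@pytest.fixture(scope="session")
def trained_ann2(ann2_dataset):
    return dm.train_ann2(ann2_dataset, seed=0)


@pytest.fixture(scope="session")
def demo_conditions():
    """A small, fast batch for closure/integration unit tests."""
    return sd.batch_conditions(
        run_id=99, e0_t0=1 / 8, Et0_T0=2.0, W0=0.0, omega=1, T0_Hex0=1.40
    )


@pytest.fixture(scope="session")
def kinetic_recovery():
    """Noiseless truth-closure campaign on runs 1, 8, 9 plus a perturbed fit.

    The sigmoid truth closure is used for generation and fitting: under
    the linear closure EO is proportional to P, which makes (K6, K7) and
    (K10, K12) structurally non-identifiable.
    """
    truth = sd.default_true_params()
    sig = sd.SigmoidParams()
    runs = [sd.TRANSESTER_DESIGN[i] for i in (0, 7, 8)]
    t_grid = np.linspace(0.0, 24.0, 16)

    def factory(conds):
        return sd.make_sigmoid_closure(conds, sig.for_conditions(conds))

    trajectories = [
        kin.integrate_batch(c, truth, factory(c), t_grid) for c in runs
    ]
    rng = np.random.default_rng(11)
    perturbed = truth.k * (1.0 + rng.uniform(-0.2, 0.2, 12))
    perturbed[truth.norm_index - 1] = 1.0
    init = kin.KineticParams(perturbed, truth.norm_index)
    fit = kin.fit_kinetic_params(trajectories, init, closure_factory=factory)
    return truth, init, fit
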