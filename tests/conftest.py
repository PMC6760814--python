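"""Shared fixtures: small simulated recordings and session-scoped experiment runs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fishrules import pipeline, simulator
from fishrules.features import SampleSet

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_ts():
    """Small deterministic zonal recording (10 agents) with injected gaps."""
    return pipeline.make_fixture(seed=7)


@pytest.fixture(scope="session")
def fixture_kin(fixture_ts):
    kin, border_mask = pipeline.preprocess(fixture_ts)
    return kin, border_mask


def make_toy_samples(
    n_samples: int = 512,
    n_neighbours: int = 5,
    seed: int = 0,
    rule: str = "nearest_x",
) -> SampleSet:
    """Synthetic decision samples with a known labelling rule.

    ``nearest_x``: the label is the side (sign of x) of the nearest
    neighbour — noiseless and linearly separable in the first neighbour's
    position.  ``random``: labels independent of the inputs.
    """
    rng = np.random.default_rng(seed)
    alpha = np.abs(rng.normal(3.0, 1.0, size=(n_samples, 2)))
    alpha[:, 1] = rng.normal(0.0, 5.0, size=n_samples)  # a_perp, sign-symmetric
    social = np.empty((n_samples, n_neighbours, 4))
    # positions sorted by distance to respect the SampleSet ordering
    # invariant, with a clear margin between the nearest neighbour and the
    # rest so the labelling rule below is smoothly representable
    r = np.sort(rng.uniform(4.0, 8.0, size=(n_samples, n_neighbours)), axis=1)
    r[:, 0] = rng.uniform(0.5, 2.5, size=n_samples)
    phi = rng.uniform(-np.pi, np.pi, size=(n_samples, n_neighbours))
    social[:, :, 0] = r * np.sin(phi)  # x
    social[:, :, 1] = r * np.cos(phi)  # y
    social[:, :, 2] = rng.normal(0, 2, size=(n_samples, n_neighbours))  # vx
    social[:, :, 3] = rng.normal(3, 2, size=(n_samples, n_neighbours))  # vy
    wfeat = np.stack(
        [
            np.broadcast_to(alpha[:, :1], (n_samples, n_neighbours)),
            np.hypot(social[:, :, 2], social[:, :, 3]),
            np.abs(social[:, :, 0]),
            social[:, :, 1],
        ],
        axis=-1,
    )
    if rule == "nearest_x":
        label = (social[:, 0, 0] > 0).astype(np.int8)
    elif rule == "random":
        label = rng.integers(0, 2, size=n_samples).astype(np.int8)
    else:
        raise ValueError(rule)
    return SampleSet(
        alpha=alpha,
        social=social,
        wfeat=wfeat[..., 0:4].reshape(n_samples, n_neighbours, 4),
        label=label,
        turn_angle=rng.uniform(0, 180, size=n_samples),
        frame=np.arange(n_samples, dtype=np.int64),
        focal_id=np.zeros(n_samples, dtype=np.int64),
    )


@pytest.fixture()
def toy_samples():
    return make_toy_samples()


# ---------------------------------------------------------------------------
# Session-scoped experiment runs shared by the acceptance and model-ordering
# tests.  Problem sizes are reduced relative to the published setup so the
# whole suite trains on one CPU; see docs/methods.md.


@pytest.fixture(scope="session")
def topo_experiment():
    """Pooled topological-range experiment (accuracy + count recovery)."""
    return pipeline.run_topological_range_experiment(
        seed=20,
        n_frames=3000,
        frame_stride=2,
        max_train_per_cap=4500,
        max_eval_per_cap=800,
        max_epochs=35,
        count_max_train=2500,
        count_max_epochs=16,
        count_samples_per_cap=1200,
    )


@pytest.fixture(scope="session")
def recovery_report():
    """Rule-recovery run over all geometry presets plus the shuffle control."""
    return pipeline.run_recovery(
        seed=21,
        n_frames=2000,
        frame_stride=2,
        max_train=6000,
        max_eval=800,
        max_epochs=16,
        include_shuffle_control=True,
    )


@pytest.fixture(scope="session")
def pooled_bundle_small():
    """One small zonal bundle reused for model-comparison tests."""
    ts, _ = simulator.simulate(
        simulator.ZonalConfig(topological_cap=15), 1500, seed=23
    )
    bundle = pipeline.prepare_bundle(
        ts, horizon=4, split_fractions=(0.8, 0.1, 0.1), frame_stride=4,
        **pipeline.SIM_PREPARE,
    )
    return bundle
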