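"""Shared fixtures: small synthetic joints generated once per session."""
import numpy as np
import pytest

from graspmorph.rig import generate_pose_grid, sweep
from graspmorph.synthetic import BallSocketSpec, make_ball_and_socket


@pytest.fixture(scope="session")
def ball_socket_small():
    """Ball-and-socket joint at reduced mesh resolution with its analytic
    clearance predicate: (model, predicate, params)."""
    return make_ball_and_socket(
        BallSocketSpec(opening_half_angle=30.0, mesh_resolution=1500, seed=0)
    )


@pytest.fixture(scope="session")
def ball_socket_sweep(ball_socket_small):
    """Full 5° sweep of the small ball-and-socket fixture."""
    model, _, _ = ball_socket_small
    grid = generate_pose_grid()
    return grid, sweep(model, grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
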