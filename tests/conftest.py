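"""Shared fixtures: the desk-scale study runs reused across test modules.

The heavyweight artefacts (the synthetic game corpus, the trained expertise
grid, the calibrated text models and the forgetting sweep) are computed
once per session and shared, so the full suite stays within a workstation
time budget.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from semcomp.experiments import (
    DrmConfig,
    ExpertiseConfig,
    SweepConfig,
    calibrate_beta,
    prepare_text_data,
    run_drm,
    run_expertise,
    run_forgetting_sweep,
)
from semcomp.synthetic import generate_legal_games


@pytest.fixture(scope="session")
def chess_games():
    """Desk-scale corpus of ~2000 uniformly random legal games."""
    return generate_legal_games(2000, max_plies=80, seed=101)


@pytest.fixture(scope="session")
def small_games():
    return generate_legal_games(30, max_plies=60, seed=7)


@pytest.fixture(scope="session")
def expertise_results(chess_games):
    cfg = ExpertiseConfig(seeds=(0, 1, 2))
    return cfg, run_expertise(cfg, games=chess_games)


@pytest.fixture(scope="session")
def text_data():
    """Desk-scale LDA corpus, vocabulary and synthetic DRM lists."""
    return prepare_text_data(DrmConfig())


@pytest.fixture(scope="session")
def calibration(text_data):
    cfg = DrmConfig()
    beta, table = calibrate_beta(text_data, cfg)
    return beta, table, cfg


@pytest.fixture(scope="session")
def drm_results(text_data, calibration):
    beta, _, cfg = calibration
    words, summary, used_beta = run_drm(replace(cfg, beta=beta), data=text_data)
    return words, summary, used_beta


@pytest.fixture(scope="session")
def sweep_results(text_data, calibration):
    beta, _, cfg = calibration
    grid = tuple(float(beta * m) for m in (0.1, 1.0, 4.0, 20.0, 100.0))
    scfg = SweepConfig(beta_grid=grid, drm=cfg)
    recall, rd = run_forgetting_sweep(scfg, data=text_data)
    return scfg, beta, recall, rd


def count_adjacent_inversions(values, direction: str) -> int:
    """Number of adjacent pairs violating a monotone ordering."""
    v = np.asarray(values, dtype=float)
    diffs = np.diff(v)
    return int(np.sum(diffs < 0) if direction == "nondecreasing" else np.sum(diffs > 0))
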