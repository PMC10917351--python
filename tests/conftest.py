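"""Shared fixtures: small seeded datasets, a rendered movie, the full benchmark."""

from __future__ import annotations

import numpy as np
import pytest

import catrace as ct
from catrace import preprocess as pp


@pytest.fixture(scope="session")
def tiny_dataset() -> ct.Dataset:
    """6 FOVs x 60 cells over 2 days, both conditions; traces only."""
    cfg = ct.SimulationConfig(n_fov=6, cells_per_fov=60, seed=42)
    return ct.simulate_dataset(
        cfg, n_days=2, conditions=("OVA_like", "OVA_like", "gp33_like"))


@pytest.fixture(scope="session")
def normalized_dataset() -> ct.Dataset:
    """Same structure as tiny_dataset but fold-change normalized."""
    cfg = ct.SimulationConfig(n_fov=6, cells_per_fov=60, seed=42)
    ds = ct.simulate_dataset(
        cfg, n_days=2, conditions=("OVA_like", "OVA_like", "gp33_like"))
    pp.normalize_dataset(ds)
    return ds


@pytest.fixture(scope="session")
def rendered_fov():
    """One 30-cell, 41-frame FOV rendered to a two-channel stack."""
    cfg = ct.SimulationConfig(n_fov=1, cells_per_fov=30, n_frames=41, seed=5,
                              fov_size_px=300)
    ds = ct.simulate_dataset(cfg, separate_cells=True)
    fov = ds.fovs[0]
    movie = ct.render_movie(fov, ct.RenderParams(), image_size=300,
                            ctfr_sample_count=cfg.ctfr_sample_count,
                            rng=np.random.default_rng(99))
    return cfg, fov, movie


@pytest.fixture(scope="session")
def study_results() -> dict:
    """The full synthetic benchmark (both classifiers, three label modes)."""
    from catrace.pipeline import run_study

    return run_study(seed=1)
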