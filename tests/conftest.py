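"""Shared fixtures: noiseless scene configs and session-scoped heavy experiments."""
from __future__ import annotations

import pytest

from tfscreen.config import PipelineConfig, SceneConfig
from tfscreen.experiments import localisation_recovery
from tfscreen.pipeline import run_screen


@pytest.fixture()
def noiseless_cfg() -> SceneConfig:
    """48x48 px scene, no background, no noise."""
    return SceneConfig(image_size_px=(48, 48), background_level=0.0, read_noise_sd=0.0)


@pytest.fixture()
def centred(noiseless_cfg) -> tuple[float, float]:
    h, w = noiseless_cfg.image_size_px
    p = noiseless_cfg.pixel_size_nm
    return ((w - 1) / 2 * p, (h - 1) / 2 * p)


@pytest.fixture(scope="session")
def recovery():
    """200-scene localisation/pairing recovery (shared across tests)."""
    return localisation_recovery(n_scenes=200, seed=1)


@pytest.fixture(scope="session")
def screen_runs(tmp_path_factory):
    """Two identical-seed end-to-end screen runs for determinism checks."""
    base = tmp_path_factory.mktemp("screen")
    cfg = PipelineConfig(seed=3)
    m1 = run_screen(cfg, base / "run1")
    m2 = run_screen(cfg, base / "run2")
    return base, m1, m2
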