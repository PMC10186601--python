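import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from apoeadmix import PopulationSpec, RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def whg_like():
    """Hunter-gatherer-like population: epsilon2-free, epsilon4-rich."""
    return PopulationSpec("WHG", 0.0, 0.60, 0.40, 200)


@pytest.fixture
def ef_like():
    """Early-farmer-like population: epsilon3-rich, epsilon4-poor."""
    return PopulationSpec("EF", 0.08, 0.87, 0.05, 200)


@pytest.fixture
def small_run_config(tmp_path):
    """Reduced-size end-to-end configuration for fast pipeline tests."""
    return RunConfig(
        seed=7,
        outdir=str(tmp_path / "run"),
        populations={
            "WHG": (0.00, 0.60, 0.40, 25),
            "EF": (0.08, 0.87, 0.05, 30),
            "Steppe": (0.06, 0.72, 0.22, 25),
        },
        offspring_n={"LF": 30, "Modern": 30},
        panel_sites=400,
        panel_ref_n=60,
        bootstrap_reps=20,
        scan_n_windows=30,
        scan_focal_windows=(12, 13, 14),
        scan_background_sites=150,
    )
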