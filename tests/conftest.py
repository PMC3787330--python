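import sys
from pathlib import Path

import pytest

REPO_ROOT = Path(__file__).resolve().parents[1]
MODELS_DIR = REPO_ROOT / "models"

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`


@pytest.fixture(scope="session")
def models_dir() -> Path:
    return MODELS_DIR


@pytest.fixture(scope="session")
def conveyor_model():
    from thymostate.statechart import parse_model

    return parse_model((MODELS_DIR / "conveyor_belt.yaml").read_text())


@pytest.fixture(scope="session")
def conveyor_system(conveyor_model):
    from thymostate.ode import compile_population_ode

    return compile_population_ode(conveyor_model)
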