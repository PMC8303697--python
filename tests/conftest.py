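import sys
from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))  # printed_tables

from sptdsc.composition import SolutionComposition, packing_state
from sptdsc.registry import load_registry
from sptdsc.report import load_dsc_table, load_solutions


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def solutions(registry):
    return load_solutions(registry=registry)


@pytest.fixture(scope="session")
def dsc_table():
    return load_dsc_table()


@pytest.fixture(scope="session")
def water_packing(registry):
    return packing_state(
        SolutionComposition(cosolutes=(), density=997.0, label="water"), registry
    )
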