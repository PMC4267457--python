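import gzip
import importlib.resources

import pytest
from hypothesis import HealthCheck, settings

from fluxkit.toys import ToySpec, make_toy

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def chain_toy():
    return make_toy(ToySpec("chain", cap=10.0))


@pytest.fixture
def branch_toy():
    return make_toy(ToySpec("branch", cap=10.0))


@pytest.fixture
def cycle_toy():
    return make_toy(ToySpec("cycle", cap=10.0))


@pytest.fixture
def lethal_pair_toy():
    return make_toy(ToySpec("lethal-pair", cap=10.0))


@pytest.fixture(params=["chain", "branch", "cycle", "lethal-pair"])
def any_toy(request):
    return make_toy(ToySpec(request.param, cap=10.0))


@pytest.fixture(scope="session")
def ecoli_core_sbml() -> str:
    """E. coli core model SBML shipped inside the installed cobra package."""
    data = importlib.resources.files("cobra") / "data" / "textbook.xml.gz"
    return gzip.decompress(data.read_bytes()).decode()
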