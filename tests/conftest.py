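import logging
from random import Random

import pytest

from bulkfhir.backend_auth import ClientRegistration
from bulkfhir.http_surface import BulkDataApp, BulkServer, ServerConfig
from bulkfhir.rsa_jws import generate_keypair
from bulkfhir.synthetic_population import PopulationConfig, generate

logging.getLogger("bulkfhir").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def keypair():
    # seeded so the (slow) prime search is reproducible across runs
    return generate_keypair(rng=Random(0xBEEF))


@pytest.fixture(scope="session")
def other_keypair():
    return generate_keypair(rng=Random(0xCAFE))


@pytest.fixture(scope="session")
def third_keypair():
    return generate_keypair(rng=Random(0xF00D))


@pytest.fixture(scope="session")
def small_repo():
    """A 12-patient population with two groups; read-only in tests."""
    return generate(PopulationConfig(n_patients=12, n_groups=2, group_fill=0.25, seed=42))


@pytest.fixture
def make_server():
    """Start BulkServers on ephemeral ports; all are stopped at teardown."""
    servers = []

    def _make(repository, config=None):
        server = BulkServer(BulkDataApp(repository, config or ServerConfig()))
        server.start()
        servers.append(server)
        return server

    yield _make
    for server in servers:
        server.stop()


@pytest.fixture
def wildcard_registration(keypair):
    return ClientRegistration(
        client_id="analytics-app",
        public_key=keypair.public_key,
        allowed_scopes=frozenset({"system/*.read"}),
    )
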