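import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def signature_matrix():
    """Deterministic 96x4 synthetic signature matrix shared across tests."""
    from mmrdkit.sim import synthetic_signature_matrix

    return synthetic_signature_matrix()


@pytest.fixture
def write_sam_file(tmp_path):
    """Write simulated reads to a SAM file in tmp_path and return the path."""
    from mmrdkit.sim import write_sam

    def _write(reads, name="reads.sam"):
        path = tmp_path / name
        write_sam(reads, path)
        return path

    return _write
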