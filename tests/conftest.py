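import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from rosegc import pipeline as pl
from rosegc.io import load_default_library


@pytest.fixture(scope="session")
def polar_library():
    return load_default_library("polar_wax")


@pytest.fixture(scope="session")
def chiral_library():
    return load_default_library("chiral_cd")


@pytest.fixture(scope="session")
def polar_fixture_table(polar_library):
    """Assigned peak table of the noiseless polar-column library trace."""
    chrom = pl.build_library_trace("polar_wax", fwhm=0.04)
    return pl.process_trace(chrom, polar_library)


@pytest.fixture(scope="session")
def chiral_fixture_table(chiral_library):
    """Assigned peak table of the noiseless chiral-column library trace."""
    chrom = pl.build_library_trace("chiral_cd", fwhm=0.03)
    return pl.process_trace(chrom, chiral_library)
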