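import numpy as np
import pytest

from kwbind import ExpNoiseParams, KWParams
from kwbind.simulate import noise_loci_for_alpha, synth_library


@pytest.fixture(scope="session")
def nanog_kw() -> KWParams:
    """Table-style K-W parameters of a strongly bound stem-cell TF."""
    return KWParams(theta=0.999, a=6.618, b=8.292)


@pytest.fixture(scope="session")
def study_noise() -> ExpNoiseParams:
    """Noise decay rate of the reference library."""
    return ExpNoiseParams(d=1.05)


@pytest.fixture(scope="session")
def small_library(nanog_kw, study_noise):
    """A reduced synthetic library for fast pipeline tests.

    10k specific loci with the reference K-W parameters, noise sized for a
    5% specific fragment share, full depth.
    """
    n_spec = 10_000
    n_noise = noise_loci_for_alpha(nanog_kw, n_spec, study_noise, 0.05)
    return synth_library(nanog_kw, n_spec, study_noise, n_noise, seed=42)
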