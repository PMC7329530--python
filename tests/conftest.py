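"""Shared fixtures.

The expensive artifacts (phantom studies and full-engine analyses) are built
once per session and shared by the module and acceptance tests; tracking
runtimes are recorded so the acceptance tests can assert their budgets
without re-running the engines.
"""

from __future__ import annotations

import time

import pytest

from tagtwist import io as tio
from tagtwist.phantom import PhantomConfig, generate_study


@pytest.fixture(scope="session")
def study_clean():
    """Default phantom, noise-free: 128x128, 22 frames, 8 mm tags,
    apical +8 deg, basal -4 deg."""
    return generate_study(PhantomConfig(noise_sd=0.0))


@pytest.fixture(scope="session")
def study_noisy():
    """Default phantom with SNR~20 additive noise, fixed seed."""
    return generate_study(PhantomConfig())


@pytest.fixture(scope="session")
def bundle_clean(study_clean):
    return tio.bundle_from_phantom(study_clean)


@pytest.fixture(scope="session")
def bundle_noisy(study_noisy):
    return tio.bundle_from_phantom(study_noisy)


def _timed_analysis(bundle, engine):
    t0 = time.monotonic()
    result = tio.analyze_study(bundle, engine)
    result["elapsed_s"] = time.monotonic() - t0
    return result


@pytest.fixture(scope="session")
def harp_clean(bundle_clean):
    return _timed_analysis(bundle_clean, "harp")


@pytest.fixture(scope="session")
def harp_noisy(bundle_noisy):
    return _timed_analysis(bundle_noisy, "harp")


@pytest.fixture(scope="session")
def ffd_clean(bundle_clean):
    return _timed_analysis(bundle_clean, "ffd")


@pytest.fixture(scope="session")
def ffd_noisy(bundle_noisy):
    return _timed_analysis(bundle_noisy, "ffd")
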