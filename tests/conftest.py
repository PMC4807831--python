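import numpy as np
import pytest
from hypothesis import settings

import petwashout as pw

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def isotope():
    return pw.IsotopeSpec.c11()


@pytest.fixture(scope="session")
def protocol():
    return pw.AcquisitionProtocol.default()


@pytest.fixture(scope="session")
def scanner():
    return pw.ScannerModel()


@pytest.fixture(scope="session")
def injection():
    return pw.InjectionSpec()


@pytest.fixture(scope="session")
def small_scanner():
    """Coarse 16 mm cube, cheap enough for exhaustive/replicated checks."""
    return pw.ScannerModel(voxel_size=(1.0, 1.0, 1.0), grid_shape=(16, 16, 16))


def make_series(
    halflife_tiss,
    halflife_wash,
    condition,
    *,
    noise=False,
    seed=0,
    a0=0.9e6,
    include_physical_decay=True,
    scanner=None,
    injection=None,
):
    """Render one noiseless or Poisson series with default instrument settings."""
    scanner = scanner or pw.ScannerModel()
    injection = injection or pw.InjectionSpec()
    protocol = pw.AcquisitionProtocol.default()
    isotope = pw.IsotopeSpec.c11()
    params = pw.TwoComponentParams.from_halflives(a0, halflife_tiss, halflife_wash)
    fa = pw.frame_average_activity(
        params, condition, isotope, protocol, include_physical_decay
    )
    return pw.render_frames(
        fa,
        scanner,
        injection,
        protocol,
        noise=noise,
        seed=seed,
        decay_corrected=not include_physical_decay,
    )


def recover_pair(halflife_tiss, halflife_wash, *, noise=False, seed=0, mode="subtraction"):
    """Full image pipeline for one alive/dead pair; returns (T_tiss, T_wash)."""
    isotope = pw.IsotopeSpec.c11()
    results = {}
    for i, cond in enumerate(pw.Condition):
        series = make_series(
            halflife_tiss, halflife_wash, cond, noise=noise, seed=seed + 7919 * i
        )
        roi = pw.select_roi(series)
        tac = pw.extract_tac(series, roi, isotope=isotope, decay_correct=True)
        results[cond] = pw.fit_single_exponential(tac)
    dec = pw.decompose(
        results[pw.Condition.ALIVE], results[pw.Condition.DEAD], mode=mode
    )
    return dec.halflife_tiss, dec.halflife_wash


@pytest.fixture(scope="session")
def pair_recovery():
    return recover_pair


@pytest.fixture(scope="session")
def series_factory():
    return make_series
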