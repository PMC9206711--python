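import numpy as np
import pytest

from dnflight import imaging as img
from dnflight import synthetic as syn
from dnflight.aero_power import drosophila_morphometrics


@pytest.fixture(scope="session")
def morph():
    """Default Drosophila-like morphometrics with the fixed measured drag (1.36)."""
    return drosophila_morphometrics()


@pytest.fixture(scope="session")
def morph_re_cd():
    """Same parameter set with the Reynolds-based 7/sqrt(Re) drag coefficient."""
    return drosophila_morphometrics(cd_pro_fixed=None)


@pytest.fixture(scope="session")
def noiseless_session():
    """Small noiseless imaging session shared across imaging tests."""
    cfg = syn.ImagingSimConfig.small_noiseless(seed=11)
    return syn.simulate_imaging_session(cfg)


@pytest.fixture(scope="session")
def moderate_session():
    """Moderate-noise imaging session (shot noise, +/-3 px jitter, z-drift)."""
    cfg = syn.ImagingSimConfig.small_moderate(seed=12)
    return syn.simulate_imaging_session(cfg)


@pytest.fixture(scope="session")
def registered_moderate(moderate_session):
    movie, behavior, protocol, truth = moderate_session
    registered, shifts = img.register_to_reference(movie)
    return registered, shifts, behavior, protocol, truth


def extract_dff_traces(movie):
    """Registration -> masks -> per-side dF/F, the standard pipeline head."""
    registered, shifts = img.register_to_reference(movie)
    left_mask, right_mask = img.select_variable_rois(registered.gcamp)
    bg = img.select_background(registered.gcamp)
    left = img.extract_side_trace(registered, left_mask, bg, "left")
    right = img.extract_side_trace(registered, right_mask, bg, "right")
    return registered, shifts, left, right
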