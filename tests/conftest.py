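"""Shared fixtures.

Expensive simulations used by several tests are session-scoped so each
is computed once.
"""

import numpy as np
import pytest
from hypothesis import settings

import ionsim as isim

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return isim.ModelParameters()


@pytest.fixture(scope="session")
def flags():
    return isim.VariantFlags()


@pytest.fixture(scope="session")
def geo_mid():
    return isim.geometry_from_radius(4.82)


@pytest.fixture(scope="session")
def rest_state(params, flags):
    """Newton-polished resting state at physiological bath (K_o_inf=4)."""
    geo = isim.geometry_from_radius(4.5)
    return geo, isim.equilibrate(params, flags, geo)


@pytest.fixture(scope="session")
def sz_sd_trace(params, flags):
    """Full-model (dynamic volume) run at r_in0 = 4.81 um, reservoir K+
    8 mM, volume relaxation 50 s: the spontaneous seizure-to-SD
    transition."""
    p = params.replace(K_o_inf=8.0, tau_v=50.0)
    return isim.run_seizure_sd(4.81, p, flags, duration=260.0)


@pytest.fixture(scope="session")
def fixedvol_trace_482(params, flags):
    """Fixed-volume run at r_in = 4.82 um, reservoir K+ 8 mM; long
    enough (450 s) to contain at least one complete high-amplitude
    event (the first fires ~120 s in, recurrences are >150 s apart)."""
    p = params.replace(K_o_inf=8.0)
    geo = isim.geometry_from_radius(4.82)
    proto = isim.Protocol(duration=450.0, transient_discard=100.0)
    return isim.integrate(isim.nominal_state(geo, p), proto, p, flags, geo)


def sweep_amplitudes(radii, params, flags, duration=250.0, transient=150.0):
    """[K]o oscillation amplitude and max per radius (fixed volume)."""
    p = params.replace(K_o_inf=8.0)
    out = []
    for r in radii:
        geo = isim.geometry_from_radius(float(r))
        proto = isim.Protocol(duration=duration,
                              transient_discard=transient)
        tr = isim.integrate(isim.nominal_state(geo, p), proto, p, flags,
                            geo).after(transient)
        ko = tr["K_o"]
        out.append((float(r), float(ko.max() - ko.min()), float(ko.max())))
    return out
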