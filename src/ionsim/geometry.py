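"""Sphere-in-shell geometry of the neuron and its extracellular space."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .parameters import FARADAY

UM_TO_CM = 1e-4
R_TOT_UM = 5.0


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class Geometry:
    """Spherical cell of radius ``r_in`` inside a shell of radius ``r_tot``.

    ``beta`` is the intra/extracellular volume ratio and ``gamma``
    (= A/(F*Vol_i), in mM/s per uA/cm^2) converts membrane current
    density to intracellular concentration rate.  ``A_ss`` is the
    reference (initial steady-state) area used for conductance rescaling
    when the volume is dynamic.
    """

    r_in: float          # um
    r_tot: float         # um
    A: float             # cm^2
    Vol_i: float         # cm^3
    Vol_o: float         # cm^3
    beta: float
    gamma: float         # mM/s per uA/cm^2
    A_ss: float          # cm^2

    @property
    def r_in_cm(self) -> float:
        return self.r_in * UM_TO_CM

    @property
    def r_tot_cm(self) -> float:
        return self.r_tot * UM_TO_CM


def geometry_from_radius(r_in: float, r_tot: float = R_TOT_UM,
                         a_ss: float | None = None) -> Geometry:
    """Geometry from the cell radius in um."""
    if not 0.0 < r_in < r_tot:
        raise GeometryError(
            f"r_in must lie in (0, r_tot={r_tot}); got {r_in}")
    r = r_in * UM_TO_CM
    rt = r_tot * UM_TO_CM
    vol_i = 4.0 * math.pi / 3.0 * r**3
    vol_o = 4.0 * math.pi / 3.0 * rt**3 - vol_i
    area = 4.0 * math.pi * r**2
    return Geometry(
        r_in=r_in, r_tot=r_tot, A=area, Vol_i=vol_i, Vol_o=vol_o,
        beta=vol_i / vol_o, gamma=area / (FARADAY * vol_i),
        A_ss=area if a_ss is None else a_ss)


def geometry_from_volume(vol: float, r_tot: float = R_TOT_UM,
                         a_ss: float | None = None) -> Geometry:
    """Geometry from the intracellular volume in cm^3."""
    rt = r_tot * UM_TO_CM
    vol_tot = 4.0 * math.pi / 3.0 * rt**3
    if not 0.0 < vol < vol_tot:
        raise GeometryError(
            f"Vol must lie in (0, shell volume {vol_tot:.3e} cm^3); got {vol}")
    r_in = (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0) / UM_TO_CM
    return geometry_from_radius(r_in, r_tot, a_ss)


def radius_from_volume(vol: float) -> float:
    """Radius in um of a sphere of volume ``vol`` (cm^3)."""
    return (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0) / UM_TO_CM
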