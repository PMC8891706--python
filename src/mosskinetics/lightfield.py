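"""Beer-Lambert light field in a side-illuminated cylindrical photobioreactor.

The vessel is treated as an infinite cylinder of radius ``r_R`` whose wall
is homogeneously illuminated from outside (the top and bottom faces are
ignored).  At a point located a distance ``a`` from the axis, light arrives
along straight chords from every direction; by symmetry only angles
``theta in [0, pi]`` need to be considered.  Each ray is attenuated
exponentially along its in-vessel path according to the Beer-Lambert law
with attenuation coefficient ``sigma_X * c_X`` (cell absorption
cross-section times biomass concentration), so the angle-averaged local
intensity is

    I(a, c_X) = (1/pi) * integral_0^pi  I0 * exp(-sigma_X * c_X * p(a, theta)) dtheta

with chord length ``p(a, theta) = -a cos(theta) + sqrt(r_R^2 - a^2 sin^2 theta)``.

Growth on light follows a Monod law in the local mean intensity; the
vessel-scale light-limited specific growth rate is the volume average of
the local Monod rate over the circular cross-section (rate-then-volume
averaging).

Units
-----
``sigma_X`` is in m^2 per g dry weight, ``c_X`` in g DW per litre
(converted internally to g/m^3), path lengths and the radius in metres,
intensities in µmol m^-2 s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss

from .steps import StepFunction

#: g/L -> g/m^3; makes sigma_X (m^2/g) * c_X * p (m) dimensionless.
G_PER_L_TO_G_PER_M3 = 1000.0

#: trapezoid points over theta in [0, pi].  The integrand has vanishing
#: derivative at both endpoints, so the trapezoid rule converges fast.
N_THETA = 64

#: Gauss-Legendre points over the radius (with cylindrical weight a).
N_RADIAL = 32

_THETA = np.linspace(0.0, np.pi, N_THETA)
_GL_NODES, _GL_WEIGHTS = leggauss(N_RADIAL)


@dataclass(frozen=True)
class OpticalGeometry:
    """Optical parameters of the illuminated cylindrical vessel.

    Parameters
    ----------
    incident_light : StepFunction
        Incident wall intensity I0 (µmol m^-2 s^-1) as a piecewise-constant
        function of time in days (supports e.g. a start-up light step).
    sigma_x : float
        Cell absorption cross-section (m^2 per g DW).
    radius : float
        Cylinder radius (m).
    """

    incident_light: StepFunction
    sigma_x: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.sigma_x < 0:
            raise ValueError("sigma_x must be non-negative")
        if any(v < 0 for v in self.incident_light.values):
            raise ValueError("incident light must be non-negative")

    @classmethod
    def from_cm(
        cls, incident_light, sigma_x: float, radius_cm: float
    ) -> "OpticalGeometry":
        """Build from the radius in cm (as usually reported) and either a
        constant intensity or a ``StepFunction``."""
        if not isinstance(incident_light, StepFunction):
            incident_light = StepFunction.constant(float(incident_light))
        return cls(incident_light=incident_light, sigma_x=sigma_x, radius=radius_cm / 100.0)

    def i0(self, time: float = 0.0) -> float:
        return self.incident_light(time)

    def replace_sigma(self, sigma_x: float) -> "OpticalGeometry":
        return OpticalGeometry(self.incident_light, sigma_x, self.radius)


def chord_path_length(radial_position, angle, radius: float):
    """In-vessel path length of a ray reaching a point at distance ``a``
    from the axis, arriving at angle ``angle`` (radians in [0, pi]).

    Returns ``p = -a*cos(angle) + sqrt(radius^2 - a^2 sin^2(angle))``; the
    result lies in ``[0, 2*radius]``.
    """
    a = np.asarray(radial_position, dtype=float)
    th = np.asarray(angle, dtype=float)
    if np.any(a < 0) or np.any(a > radius):
        raise ValueError("radial_position must lie in [0, radius]")
    if np.any(th < 0) or np.any(th > np.pi):
        raise ValueError("angle must lie in [0, pi]")
    p = -a * np.cos(th) + np.sqrt(radius**2 - (a * np.sin(th)) ** 2)
    if p.ndim == 0:
        return float(p)
    return p


def local_mean_intensity(
    radial_position: float,
    c_x: float,
    optics: OpticalGeometry,
    time: float = 0.0,
) -> float:
    """Angle-averaged light intensity at a point, µmol m^-2 s^-1.

    Averages the Beer-Lambert attenuated intensity over arrival angles
    [0, pi] by a 64-point trapezoid rule.  Exactly I0 for ``c_x == 0`` or
    ``sigma_x == 0``.
    """
    if c_x < 0:
        raise ValueError("c_x must be non-negative")
    i0 = optics.i0(time)
    k = optics.sigma_x * G_PER_L_TO_G_PER_M3 * c_x
    if k == 0.0:
        return i0
    p = chord_path_length(radial_position, _THETA, optics.radius)
    return i0 * float(np.trapezoid(np.exp(-k * p), _THETA)) / np.pi


def _radial_quadrature(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights mapped to [0, radius]."""
    a = (_GL_NODES + 1.0) * 0.5 * radius
    w = _GL_WEIGHTS * 0.5 * radius
    return a, w


def mean_attenuation_profile(optics: OpticalGeometry, c_x) -> np.ndarray:
    """Angle-averaged attenuation factor at the radial quadrature nodes.

    Returns an array of shape ``(len(c_x), N_RADIAL)`` (or ``(N_RADIAL,)``
    for scalar ``c_x``) with values in (0, 1]; multiply by I0 to obtain the
    local mean intensity.
    """
    cx = np.atleast_1d(np.asarray(c_x, dtype=float))
    if np.any(cx < 0):
        raise ValueError("c_x must be non-negative")
    a, _ = _radial_quadrature(optics.radius)
    p = chord_path_length(a[:, None], _THETA[None, :], optics.radius)  # (R, T)
    k = optics.sigma_x * G_PER_L_TO_G_PER_M3 * cx  # (C,)
    atten = np.exp(-k[:, None, None] * p[None, :, :])  # (C, R, T)
    prof = np.trapezoid(atten, _THETA, axis=2) / np.pi  # (C, R)
    if np.isscalar(c_x) or np.asarray(c_x).ndim == 0:
        return prof[0]
    return prof


def light_limited_growth_rate(
    c_x: float,
    optics: OpticalGeometry,
    r_x_max: float,
    k_i: float,
    time: float = 0.0,
) -> float:
    """Volume-averaged light-limited specific growth rate (d^-1).

    Computes the cross-section average

        r = (2/r_R^2) * integral_0^r_R  r_x_max * I(a)/(I(a)+k_I) * a da

    by 32-point Gauss-Legendre quadrature, where ``I(a)`` is the
    angle-averaged local intensity.  Bounded by ``r_x_max``; strictly
    decreasing in ``c_x`` whenever ``sigma_x > 0``.
    """
    if min(c_x, r_x_max, k_i) < 0:
        raise ValueError("c_x, r_x_max and k_i must be non-negative")
    i0 = optics.i0(time)
    a, w = _radial_quadrature(optics.radius)
    intensity = i0 * mean_attenuation_profile(optics, c_x)  # (R,)
    if k_i == 0.0:
        monod = np.ones_like(intensity)
    else:
        monod = intensity / (intensity + k_i)
    return float(2.0 / optics.radius**2 * np.sum(w * a * r_x_max * monod))


class RadialLightModel:
    """Attenuation factors precomputed on a biomass grid.

    Speeds up repeated rate evaluations during ODE integration and
    parameter estimation: the angle-averaged Beer-Lambert factor is
    evaluated once on a grid of biomass concentrations, and the
    volume-averaged Monod factor is then obtained per candidate by a cheap
    reduction plus linear interpolation in ``c_X``.  Valid for a fixed
    ``sigma_x`` and radius; the incident intensity enters only as a scale.
    """

    def __init__(self, optics: OpticalGeometry, c_x_max: float, n_grid: int = 512):
        self.optics = optics
        self.grid = np.linspace(0.0, max(float(c_x_max), 1e-6), n_grid)
        self.attenuation = mean_attenuation_profile(optics, self.grid)  # (G, R)
        self._a, self._w = _radial_quadrature(optics.radius)

    def monod_table(self, i0: float, k_i) -> np.ndarray:
        """Volume-averaged Monod light factor on the biomass grid.

        Parameters
        ----------
        i0 : float
            Incident intensity for the current schedule segment.
        k_i : float or array of shape (S,)
            Light half-saturation constant(s), one per candidate.

        Returns
        -------
        ndarray of shape (S, G)
        """
        k = np.atleast_1d(np.asarray(k_i, dtype=float))[:, None, None]  # (S,1,1)
        intensity = i0 * self.attenuation[None, :, :]  # (1, G, R)
        with np.errstate(invalid="ignore"):
            monod = np.where(k == 0.0, 1.0, intensity / (intensity + k))
        r = self.optics.radius
        return 2.0 / r**2 * np.sum(self._w * self._a * monod, axis=2)  # (S, G)
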