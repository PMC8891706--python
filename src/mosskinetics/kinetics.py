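"""Specific rate laws: nitrate uptake, co-limited growth, product turnover.

Growth is limited either by nitrate or by light, combined with the minimum
law (threshold model):

    r_N(c_N)   = r_N_max * c_N / (c_N + k_N)          nitrate uptake (Pirt)
    r_X_N      = y_X_N * r_N                          nitrate-limited growth
    r_X_I      = volume-averaged Monod in light       (see ``lightfield``)
    r_X        = min(r_X_I, r_X_N)
    light-limited regime:  r_N = r_X / y_X_N          uptake follows growth

Product formation is growth-medium-associated (Monod in nitrate) and
first-order degradation applies:

    r_p   = r_p_max * c_N / (c_N + k_p)
    r_p_d = k_pd * c_P

The maximum uptake rate is not an independent parameter: it is derived as
``r_N_max = r_X_max / y_X_N`` so that the nitrate branch reproduces
``r_X_N = r_X_max * c_N/(c_N + k_N)`` and the yield coupling
``r_X = y_X_N * r_N`` holds in both regimes.

Units: rates per day; c_N and the half-saturation constants k_N, k_p in
mg NO3-/L; c_X in g DW/L; c_P in mg/L; y_X_N in g DW per g nitrate;
r_p_max in mg product per g DW per day; k_pd in L per g DW per day.
Maintenance (non-growth) nitrate uptake is taken as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace

from .lightfield import OpticalGeometry, light_limited_growth_rate

#: regime labels for the minimum law
NITRATE = "nitrate"
LIGHT = "light"


@dataclass(frozen=True)
class KineticParams:
    """Rate-law constants of the co-limitation growth/production model.

    Attributes
    ----------
    r_x_max : float
        Maximum specific growth rate (d^-1).
    k_n : float
        Nitrate half-saturation constant for growth (mg NO3-/L).
    k_i : float
        Light half-saturation constant (µmol m^-2 s^-1).
    y_x_n : float
        Biomass yield on nitrate (g DW per g nitrate).
    r_p_max : float
        Maximum specific product formation rate (mg per g DW per d).
    k_p : float
        Nitrate half-saturation constant for product synthesis (mg/L).
    k_pd : float
        Specific product degradation constant (L per g DW per d).
    """

    r_x_max: float
    k_n: float
    k_i: float
    y_x_n: float
    r_p_max: float = 0.0
    k_p: float = 0.0
    k_pd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_x_max", "k_n", "k_i", "y_x_n", "r_p_max", "k_p", "k_pd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.y_x_n <= 0:
            raise ValueError("y_x_n must be positive")

    @property
    def r_n_max(self) -> float:
        """Maximum specific nitrate uptake rate, g nitrate per g DW per d."""
        return self.r_x_max / self.y_x_n

    def replace(self, **kwargs) -> "KineticParams":
        return _dc_replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        return {
            "r_x_max": self.r_x_max,
            "k_n": self.k_n,
            "k_i": self.k_i,
            "y_x_n": self.y_x_n,
            "r_p_max": self.r_p_max,
            "k_p": self.k_p,
            "k_pd": self.k_pd,
        }


@dataclass(frozen=True)
class RateBundle:
    """Specific rates at one state, with the winning limitation branch.

    ``limiting_regime`` is ``"nitrate"`` when the nitrate branch of the
    minimum law set the growth rate (ties included) and ``"light"``
    otherwise.  The yield coupling ``r_x == y_x_n * r_n`` holds in both
    regimes.
    """

    r_x: float
    r_n: float
    r_p: float
    r_p_d: float
    limiting_regime: str


def nitrate_uptake_rate(c_n: float, params: KineticParams) -> float:
    """Monod-type specific nitrate uptake rate (g nitrate per g DW per d)."""
    if c_n < 0:
        raise ValueError("c_n must be non-negative")
    if c_n == 0.0:
        return 0.0
    return params.r_n_max * c_n / (c_n + params.k_n)


def protein_rates(c_n: float, c_p: float, params: KineticParams) -> tuple[float, float]:
    """Specific product formation and degradation rates (mg per g DW per d)."""
    if c_n < 0 or c_p < 0:
        raise ValueError("concentrations must be non-negative")
    if c_n == 0.0:
        r_p = 0.0
    else:
        r_p = params.r_p_max * c_n / (c_n + params.k_p)
    return r_p, params.k_pd * c_p


def effective_rates(
    c_n: float,
    c_x: float,
    c_p: float,
    params: KineticParams,
    optics: OpticalGeometry,
    time: float = 0.0,
) -> RateBundle:
    """Minimum-law effective rates at one reactor state.

    Evaluates the nitrate-limited growth rate ``y_x_n * r_N(c_N)`` and the
    volume-averaged light-limited rate, takes the minimum, and couples
    nitrate uptake back to growth through the yield in the light-limited
    regime.  Ties are labelled ``"nitrate"`` (no numerical effect).
    """
    if min(c_n, c_x, c_p) < 0:
        raise ValueError("concentrations must be non-negative")
    r_n_monod = nitrate_uptake_rate(c_n, params)
    r_x_nitrate = params.y_x_n * r_n_monod
    r_x_light = light_limited_growth_rate(
        c_x, optics, params.r_x_max, params.k_i, time
    )
    if r_x_light < r_x_nitrate:
        r_x = r_x_light
        r_n = r_x / params.y_x_n
        regime = LIGHT
    else:
        r_x = r_x_nitrate
        r_n = r_n_monod
        regime = NITRATE
    r_p, r_p_d = protein_rates(c_n, c_p, params)
    return RateBundle(r_x=r_x, r_n=r_n, r_p=r_p, r_p_d=r_p_d, limiting_regime=regime)


def doubling_time(r_x_max: float) -> float:
    """Biomass doubling time ln(2)/r for exponential growth at rate r (d)."""
    if r_x_max <= 0:
        raise ValueError("growth rate must be positive")
    return math.log(2.0) / r_x_max
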