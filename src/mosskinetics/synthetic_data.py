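"""Synthetic observation campaigns with the study's measurement structure.

Emulates how moss-bioreactor runs are actually sampled: roughly daily
sampling over 8-12 days, two or three replicate measurements per time
point, biomass dry weight in g/L, nitrate in mg/L and intracellular
product in mg/L.  Noise is multiplicative Gaussian per replicate,
``value * (1 + CV * z)`` truncated at zero, which mirrors the roughly
concentration-proportional scatter of dry-weight, reflectometric nitrate
and ELISA measurements.

The built-in fixtures carry the published parameter sets (parental batch,
producer-line batch, producer-line semi-continuous) together with the
operating schedules of the corresponding bioreactor runs, so every
downstream stage — simulation, fitting, reporting — is testable without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitting import ObservedDataset
from .kinetics import KineticParams
from .lightfield import OpticalGeometry
from .reactor import (
    BATCH,
    FED_BATCH,
    SEMI_CONTINUOUS_RATE,
    OperationSchedule,
    ReactorState,
    simulate,
)
from .steps import StepFunction

#: default initial conditions of a 5 L stirred-tank run: inoculation at
#: about 0.1 g DW/L in fresh medium containing 500 mg NO3-/L.
DEFAULT_INITIAL = dict(c_x=0.1, c_n=500.0, c_p=0.0)

#: nitrate concentration of the fresh (1x) medium, mg/L; the fed-batch
#: feed uses the 5x concentrate at 2500 mg/L.
FRESH_MEDIUM_NITRATE = 500.0
FEED_NITRATE_5X = 2500.0

VESSEL_RADIUS_CM = 8.75
INCIDENT_LIGHT = 350.0


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-level multiplicative measurement noise.

    ``cv`` is a single coefficient of variation or a per-variable dict
    (keys biomass/nitrate/product).  ``replicates`` replicate measurements
    are drawn per time point and variable.
    """

    cv: float | dict = 0.05
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        cvs = self.cv.values() if isinstance(self.cv, dict) else [self.cv]
        if any(c < 0 for c in cvs):
            raise ValueError("coefficients of variation must be non-negative")
        if self.replicates < 1:
            raise ValueError("at least one replicate is required")

    def cv_for(self, variable: str) -> float:
        if isinstance(self.cv, dict):
            return float(self.cv.get(variable, 0.0))
        return float(self.cv)


@dataclass(frozen=True)
class ScenarioFixture:
    """Named scenario: parameters, optics, schedule and sampling plan."""

    name: str
    params: KineticParams
    optics: OpticalGeometry
    schedule: OperationSchedule
    sampling_times: tuple[float, ...]
    observed: tuple[str, ...] = ("biomass", "nitrate", "product")


def _optics(sigma_x: float) -> OpticalGeometry:
    return OpticalGeometry.from_cm(
        incident_light=INCIDENT_LIGHT, sigma_x=sigma_x, radius_cm=VESSEL_RADIUS_CM
    )


def _initial(volume: float) -> ReactorState:
    return ReactorState(t=0.0, volume=volume, **DEFAULT_INITIAL)


#: published parameter columns (producer line B and its parental line);
#: the parental line carries no product kinetics (rates zeroed).
PARENTAL_BATCH_PARAMS = KineticParams(
    r_x_max=0.699, k_n=3.58, k_i=15.01, y_x_n=9.615,
    r_p_max=0.0, k_p=0.0, k_pd=0.0,
)
LINE_B_BATCH_PARAMS = KineticParams(
    r_x_max=0.699, k_n=4.41, k_i=15.29, y_x_n=7.042,
    r_p_max=0.327, k_p=1.010, k_pd=0.0801,
)
LINE_B_SEMI_PARAMS = KineticParams(
    r_x_max=0.647, k_n=3.91, k_i=16.86, y_x_n=5.050,
    r_p_max=0.236, k_p=1.545, k_pd=0.0801,
)

SIGMA_X_PARENTAL = 0.021
SIGMA_X_BATCH = 0.049
SIGMA_X_SEMI = 0.044


def builtin_fixtures() -> list[ScenarioFixture]:
    """The study's scenarios as ready-to-simulate fixtures.

    * ``parental-batch`` — parental line, biomass/nitrate only, 8 d batch.
    * ``lineB-batch`` — producer line, 8 d batch.
    * ``lineB-semicontinuous-D0.4`` — batch phase to day 6, then daily
      exchange of 2 L of 5 L (D = 0.4 d^-1) to day 11.
    * ``lineB-semicontinuous-D0.2`` — batch phase to day 7, then D = 0.2
      d^-1 to day 10.
    * ``lineB-fedbatch`` — 4 L batch to day 7, then 0.2 L/d of 5x medium
      (2500 mg NO3-/L) to day 12.
    """
    fixtures = []

    batch8 = OperationSchedule(mode=BATCH, initial=_initial(5.0), t_end=8.0)
    fixtures.append(
        ScenarioFixture(
            name="parental-batch",
            params=PARENTAL_BATCH_PARAMS,
            optics=_optics(SIGMA_X_PARENTAL),
            schedule=batch8,
            sampling_times=tuple(float(t) for t in range(9)),
            observed=("biomass", "nitrate"),
        )
    )
    fixtures.append(
        ScenarioFixture(
            name="lineB-batch",
            params=LINE_B_BATCH_PARAMS,
            optics=_optics(SIGMA_X_BATCH),
            schedule=batch8,
            sampling_times=tuple(float(t) for t in range(9)),
        )
    )
    fixtures.append(
        ScenarioFixture(
            name="lineB-semicontinuous-D0.4",
            params=LINE_B_SEMI_PARAMS,
            optics=_optics(SIGMA_X_SEMI),
            schedule=OperationSchedule(
                mode=SEMI_CONTINUOUS_RATE,
                initial=_initial(5.0),
                t_end=11.0,
                dilution=StepFunction(times=(0.0, 6.0), values=(0.0, 0.4)),
                feed_nitrate=FRESH_MEDIUM_NITRATE,
            ),
            sampling_times=tuple(float(t) for t in range(12)),
        )
    )
    fixtures.append(
        ScenarioFixture(
            name="lineB-semicontinuous-D0.2",
            params=LINE_B_SEMI_PARAMS,
            optics=_optics(SIGMA_X_SEMI),
            schedule=OperationSchedule(
                mode=SEMI_CONTINUOUS_RATE,
                initial=_initial(5.0),
                t_end=10.0,
                dilution=StepFunction(times=(0.0, 7.0), values=(0.0, 0.2)),
                feed_nitrate=FRESH_MEDIUM_NITRATE,
            ),
            sampling_times=tuple(float(t) for t in range(11)),
        )
    )
    fixtures.append(
        ScenarioFixture(
            name="lineB-fedbatch",
            params=LINE_B_BATCH_PARAMS,
            optics=_optics(SIGMA_X_BATCH),
            schedule=OperationSchedule(
                mode=FED_BATCH,
                initial=_initial(4.0),
                t_end=12.0,
                feed_flow=StepFunction(times=(0.0, 7.0), values=(0.0, 0.2)),
                feed_nitrate=FEED_NITRATE_5X,
            ),
            sampling_times=tuple(float(t) for t in range(13)),
        )
    )
    return fixtures


def get_fixture(name: str) -> ScenarioFixture:
    for f in builtin_fixtures():
        if f.name == name:
            return f
    names = [f.name for f in builtin_fixtures()]
    raise KeyError(f"unknown fixture {name!r}; available: {names}")


def generate(fixture: ScenarioFixture, noise: NoiseModel) -> ObservedDataset:
    """Simulate a fixture and sample noisy replicate observations.

    The exact trajectory is evaluated at the fixture's sampling times;
    each observed variable then receives ``noise.replicates`` independent
    multiplicative-Gaussian replicates per time point, truncated at zero.
    Deterministic for a given seed: replicates are drawn variable by
    variable in the fixture's ``observed`` order.
    """
    from .fitting import VARIABLE_COLUMNS  # local to avoid cycle at import time

    traj = simulate(
        fixture.params, fixture.optics, fixture.schedule,
        output_times=np.asarray(fixture.sampling_times, dtype=float),
    )
    rng = np.random.default_rng(noise.seed)
    rows = []
    for v in fixture.observed:
        exact = traj.frame[VARIABLE_COLUMNS[v]].to_numpy()
        cv = noise.cv_for(v)
        z = rng.standard_normal(size=(len(exact), noise.replicates))
        values = np.clip(exact[:, None] * (1.0 + cv * z), 0.0, None)
        for j, t in enumerate(fixture.sampling_times):
            for r in range(noise.replicates):
                rows.append(
                    {
                        "time_d": float(t),
                        "variable": v,
                        "value": float(values[j, r]),
                        "replicate_id": r,
                    }
                )
    data = pd.DataFrame(rows)
    return ObservedDataset(
        data=data, schedule=fixture.schedule, optics=fixture.optics, name=fixture.name
    )
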