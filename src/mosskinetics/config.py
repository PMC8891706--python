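"""Validated run configuration for the command-line pipeline.

A single YAML file describes a run: either a named built-in fixture or
explicit parameter/optics/schedule blocks, plus optional noise and fit
blocks.  Units follow the reporting conventions (radius in cm, nitrate in
mg/L, light in µmol m^-2 s^-1, times in days) and are converted at this
boundary; explicit unit-bearing field names guard against silent
1000-fold errors.  Every output file embeds the SHA-256 hash of the
canonical configuration for provenance.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .kinetics import KineticParams
from .lightfield import OpticalGeometry
from .reactor import (
    BATCH,
    FED_BATCH,
    MODES,
    SEMI_CONTINUOUS_EVENTS,
    SEMI_CONTINUOUS_RATE,
    ExchangeEvent,
    OperationSchedule,
    ReactorState,
)
from .steps import StepFunction
from .synthetic_data import NoiseModel, ScenarioFixture, get_fixture


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParamsConfig(_Model):
    """Kinetic parameters, in the printed units."""

    r_X_max: float = Field(description="maximum specific growth rate, 1/d")
    k_N: float = Field(description="nitrate half-saturation, mg/L")
    k_I: float = Field(description="light half-saturation, umol/(m^2 s)")
    y_X_N: float = Field(description="biomass yield on nitrate, g/g")
    r_p_max: float = Field(0.0, description="max specific production rate, mg/(g d)")
    k_p: float = Field(0.0, description="nitrate half-saturation for product, mg/L")
    k_pd: float = Field(0.0, description="specific degradation rate, L/(g d)")

    def build(self) -> KineticParams:
        return KineticParams(
            r_x_max=self.r_X_max, k_n=self.k_N, k_i=self.k_I, y_x_n=self.y_X_N,
            r_p_max=self.r_p_max, k_p=self.k_p, k_pd=self.k_pd,
        )


class LightStep(_Model):
    time_d: float
    intensity: float = Field(ge=0.0)


class OpticsConfig(_Model):
    sigma_X: float = Field(ge=0.0, description="cell absorption cross-section, m^2/g")
    radius_cm: float = Field(gt=0.0, description="vessel radius, cm")
    incident_light: float | list[LightStep] = Field(
        description="umol/(m^2 s); constant or piecewise steps"
    )

    def build(self) -> OpticalGeometry:
        light = self.incident_light
        if isinstance(light, list):
            step = StepFunction(
                times=tuple(s.time_d for s in light),
                values=tuple(s.intensity for s in light),
            )
        else:
            step = StepFunction.constant(float(light))
        return OpticalGeometry.from_cm(step, self.sigma_X, self.radius_cm)


class InitialConfig(_Model):
    biomass_gDW_per_L: float = Field(0.1, ge=0.0)
    nitrate_mg_per_L: float = Field(500.0, ge=0.0)
    product_mg_per_L: float = Field(0.0, ge=0.0)
    volume_L: float = Field(5.0, gt=0.0)


class FeedConfig(_Model):
    start_day: float = Field(ge=0.0)
    flow_L_per_d: float = Field(gt=0.0)
    nitrate_mg_per_L: float = Field(ge=0.0)


class DilutionConfig(_Model):
    start_day: float = Field(ge=0.0)
    rate_per_d: float = Field(gt=0.0)
    fresh_nitrate_mg_per_L: float = Field(ge=0.0)


class ExchangeConfig(_Model):
    time_d: float = Field(gt=0.0)
    fraction: float = Field(gt=0.0, lt=1.0)
    fresh_nitrate_mg_per_L: float = Field(ge=0.0)


class ScheduleConfig(_Model):
    mode: Literal[BATCH, FED_BATCH, SEMI_CONTINUOUS_RATE, SEMI_CONTINUOUS_EVENTS]
    t_end_d: float = Field(gt=0.0)
    initial: InitialConfig = InitialConfig()
    feed: Optional[FeedConfig] = None
    dilution: Optional[DilutionConfig] = None
    exchanges: list[ExchangeConfig] = []

    @model_validator(mode="after")
    def _mode_invariants(self):
        if self.mode == BATCH and (self.feed or self.dilution or self.exchanges):
            raise ValueError("batch mode admits no feed, dilution or exchanges")
        if self.mode == FED_BATCH and (self.dilution or self.exchanges or not self.feed):
            raise ValueError("fed_batch requires a feed block and admits no dilution/exchanges")
        if self.mode == SEMI_CONTINUOUS_RATE and (self.feed or self.exchanges or not self.dilution):
            raise ValueError("semi_continuous_rate requires a dilution block only")
        if self.mode == SEMI_CONTINUOUS_EVENTS and (self.feed or self.dilution or not self.exchanges):
            raise ValueError("semi_continuous_events requires exchange events only")
        return self

    def build(self) -> OperationSchedule:
        init = ReactorState(
            t=0.0,
            c_x=self.initial.biomass_gDW_per_L,
            c_n=self.initial.nitrate_mg_per_L,
            c_p=self.initial.product_mg_per_L,
            volume=self.initial.volume_L,
        )
        kwargs: dict = {}
        if self.feed is not None:
            times = (0.0, self.feed.start_day) if self.feed.start_day > 0 else (0.0,)
            values = (0.0, self.feed.flow_L_per_d) if self.feed.start_day > 0 else (
                self.feed.flow_L_per_d,
            )
            kwargs["feed_flow"] = StepFunction(times=times, values=values)
            kwargs["feed_nitrate"] = self.feed.nitrate_mg_per_L
        if self.dilution is not None:
            d = self.dilution
            times = (0.0, d.start_day) if d.start_day > 0 else (0.0,)
            values = (0.0, d.rate_per_d) if d.start_day > 0 else (d.rate_per_d,)
            kwargs["dilution"] = StepFunction(times=times, values=values)
            kwargs["feed_nitrate"] = d.fresh_nitrate_mg_per_L
        if self.exchanges:
            kwargs["exchanges"] = tuple(
                ExchangeEvent(e.time_d, e.fraction, e.fresh_nitrate_mg_per_L)
                for e in self.exchanges
            )
        return OperationSchedule(
            mode=self.mode, initial=init, t_end=self.t_end_d, **kwargs
        )


class NoiseConfig(_Model):
    cv: float | dict[str, float] = 0.05
    replicates: int = Field(2, ge=1)
    seed: int = 0

    def build(self) -> NoiseModel:
        return NoiseModel(cv=self.cv, replicates=self.replicates, seed=self.seed)


class FitConfig(_Model):
    bounds: dict[str, tuple[float, float]] = Field(
        description="free parameters with (low, high) bounds; names "
        "r_x_max, k_n, k_i, y_x_n, r_p_max, k_p, k_pd, sigma_x"
    )
    seed: int = 0
    popsize: int = Field(15, ge=15)
    maxiter: int = Field(500, ge=1)
    tol: float = Field(1e-8, gt=0.0)
    polish: bool = True
    scaling: Literal["max", "none"] = "max"
    observations: Optional[str] = Field(
        None, description="path to the long-format observation CSV"
    )

    def optimizer_settings(self) -> dict:
        return {
            "popsize": self.popsize,
            "maxiter": self.maxiter,
            "tol": self.tol,
            "polish": self.polish,
        }


class RunConfig(_Model):
    """Top-level run description: a fixture name or explicit blocks."""

    fixture: Optional[str] = None
    params: Optional[ParamsConfig] = None
    optics: Optional[OpticsConfig] = None
    schedule: Optional[ScheduleConfig] = None
    sampling_times_d: Optional[list[float]] = None
    noise: NoiseConfig = NoiseConfig()
    fit: Optional[FitConfig] = None
    out_dir: str = "."

    @model_validator(mode="after")
    def _fixture_or_blocks(self):
        if self.fixture is None:
            missing = [
                n for n in ("params", "optics", "schedule") if getattr(self, n) is None
            ]
            if missing:
                raise ValueError(
                    f"either give 'fixture' or provide blocks: missing {missing}"
                )
        return self

    def scenario(self) -> ScenarioFixture:
        """Resolve to a concrete scenario (fixture or explicit blocks)."""
        if self.fixture is not None:
            fx = get_fixture(self.fixture)
            if self.sampling_times_d is not None:
                fx = ScenarioFixture(
                    name=fx.name, params=fx.params, optics=fx.optics,
                    schedule=fx.schedule,
                    sampling_times=tuple(self.sampling_times_d),
                    observed=fx.observed,
                )
            return fx
        schedule = self.schedule.build()
        times = self.sampling_times_d
        if times is None:
            times = [float(t) for t in range(int(schedule.t_end) + 1)]
        params = self.params.build()
        observed = ("biomass", "nitrate") if params.r_p_max == 0 else (
            "biomass", "nitrate", "product"
        )
        return ScenarioFixture(
            name="custom",
            params=params,
            optics=self.optics.build(),
            schedule=schedule,
            sampling_times=tuple(times),
            observed=observed,
        )


def load_config(path) -> tuple[RunConfig, str]:
    """Load and validate a YAML config; returns (config, sha256 hash)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig.model_validate(raw)
    canonical = json.dumps(raw, sort_keys=True, default=str)
    digest = hashlib.sha256(canonical.encode()).hexdigest()
    return cfg, digest
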