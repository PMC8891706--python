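"""Macroscopic mass balances of the stirred-tank photobioreactor.

State variables are biomass c_X (g DW/L), nitrate c_N (mg NO3-/L),
intracellular product c_P (mg/L) and the working volume V (L).  The
balances are

    dc_X/dt = r_X c_X - D c_X
    dc_N/dt = -r_N c_X + D (c_N,f - c_N)        (c_N in mg/L, r_N in g/g/d)
    dc_P/dt = (r_p - r_p,d) c_X - D c_P
    dV/dt   = F

with D = 0 in batch, D = F/V in fed-batch (no broth removal, volume grows)
and D the configured exchange rate in semi-continuous operation at
constant volume.  The daily harvest-and-refill procedure used in the
laboratory is additionally available as a sequence of discrete
medium-exchange events; the continuous-D form is what the balances state
and is the default for fitting.

Integration is piecewise between schedule discontinuities (light steps,
feed starts, dilution-rate changes, exchange events) with an adaptive
explicit Runge-Kutta scheme (RK45, rtol 1e-8, atol 1e-10 by default).
At an exchange event replacing a fraction f of the broth the state jumps
to c_X (1-f), c_P (1-f) and c_N (1-f) + c_N,fresh f at unchanged volume,
and the removed biomass/product is accumulated in a harvest ledger so the
total amount of product formed (in-vessel plus harvested) is reportable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import KineticParams, RateBundle, effective_rates
from .lightfield import OpticalGeometry, RadialLightModel, mean_attenuation_profile, _radial_quadrature
from .steps import StepFunction

BATCH = "batch"
FED_BATCH = "fed_batch"
SEMI_CONTINUOUS_RATE = "semi_continuous_rate"
SEMI_CONTINUOUS_EVENTS = "semi_continuous_events"

MODES = (BATCH, FED_BATCH, SEMI_CONTINUOUS_RATE, SEMI_CONTINUOUS_EVENTS)

#: tolerance below which slightly negative integrator output is clamped to 0
NEGATIVE_CLAMP = 1e-9

_MG_PER_G = 1000.0


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last good state."""

    def __init__(self, message: str, last_state: "ReactorState | None" = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class ReactorState:
    """Reactor state at one instant."""

    t: float
    c_x: float
    c_n: float
    c_p: float
    volume: float

    def __post_init__(self) -> None:
        if min(self.c_x, self.c_n, self.c_p) < 0:
            raise ValueError("concentrations must be non-negative")
        if self.volume <= 0:
            raise ValueError("volume must be positive")


@dataclass(frozen=True)
class ExchangeEvent:
    """Discrete medium exchange: replace ``fraction`` of the broth with
    fresh medium containing ``fresh_nitrate`` mg NO3-/L (no biomass, no
    product)."""

    time: float
    fraction: float
    fresh_nitrate: float

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must lie in (0, 1)")
        if self.fresh_nitrate < 0:
            raise ValueError("fresh_nitrate must be non-negative")


@dataclass
class HarvestLedger:
    """Cumulative biomass (g DW) and product (mg) removed from the vessel."""

    biomass_g: float = 0.0
    product_mg: float = 0.0


@dataclass(frozen=True)
class OperationSchedule:
    """Operating mode, feeds, dilution/exchange plan and horizon.

    The light schedule lives in :class:`~mosskinetics.lightfield.OpticalGeometry`
    (it is an optical boundary condition, referenced here only through the
    optics passed alongside the schedule).

    Mode invariants: batch has no feed, dilution or exchanges; fed-batch
    has a feed but no configured dilution (D = F/V is implied) and no
    removal; semi-continuous keeps the volume constant, either with a
    continuous dilution rate or with discrete exchange events.
    """

    mode: str
    initial: ReactorState
    t_end: float
    feed_flow: StepFunction = field(default_factory=lambda: StepFunction.constant(0.0))
    feed_nitrate: float = 0.0
    dilution: StepFunction = field(default_factory=lambda: StepFunction.constant(0.0))
    exchanges: tuple[ExchangeEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.t_end <= self.initial.t:
            raise ValueError("t_end must exceed the initial time")
        if self.feed_nitrate < 0:
            raise ValueError("feed_nitrate must be non-negative")
        if self.mode == BATCH:
            if not (self.feed_flow.is_zero and self.dilution.is_zero and not self.exchanges):
                raise ValueError("batch mode admits no feed, dilution or exchanges")
        elif self.mode == FED_BATCH:
            if not self.dilution.is_zero or self.exchanges:
                raise ValueError("fed-batch admits no configured dilution or exchanges")
        elif self.mode == SEMI_CONTINUOUS_RATE:
            if not self.feed_flow.is_zero or self.exchanges:
                raise ValueError("semi_continuous_rate admits no feed flow or exchanges")
        else:  # SEMI_CONTINUOUS_EVENTS
            if not (self.feed_flow.is_zero and self.dilution.is_zero):
                raise ValueError("semi_continuous_events admits no feed flow or dilution")
            times = [e.time for e in self.exchanges]
            if sorted(times) != times or len(set(times)) != len(times):
                raise ValueError("exchange events must have distinct increasing times")
            if times and (times[0] <= self.initial.t or times[-1] > self.t_end):
                raise ValueError("exchange events must lie within (t0, t_end]")


def dilution_rate_from_exchange(
    volume_replaced: float, working_volume: float, interval_days: float = 1.0
) -> float:
    """Equivalent continuous dilution rate of a periodic medium exchange.

    Replacing ``volume_replaced`` litres of a ``working_volume``-litre
    culture every ``interval_days`` days corresponds to
    D = (volume_replaced / working_volume) / interval_days (d^-1).
    """
    if volume_replaced <= 0 or working_volume <= 0 or interval_days <= 0:
        raise ValueError("volumes and interval must be positive")
    if volume_replaced >= working_volume:
        raise ValueError("replaced volume must be smaller than the working volume")
    return (volume_replaced / working_volume) / interval_days


def apply_exchange_event(
    state: ReactorState,
    fraction: float,
    fresh_nitrate: float,
    ledger: HarvestLedger | None = None,
) -> ReactorState:
    """Jump map of a discrete medium exchange at constant volume.

    Removes a fraction of the (well-mixed) broth and refills with fresh
    medium; the removed biomass and product are credited to ``ledger`` if
    one is given.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if fresh_nitrate < 0:
        raise ValueError("fresh_nitrate must be non-negative")
    if ledger is not None:
        ledger.biomass_g += fraction * state.volume * state.c_x
        ledger.product_mg += fraction * state.volume * state.c_p
    return _dc_replace(
        state,
        c_x=state.c_x * (1.0 - fraction),
        c_p=state.c_p * (1.0 - fraction),
        c_n=state.c_n * (1.0 - fraction) + fresh_nitrate * fraction,
    )


def derivatives(
    state: ReactorState,
    params: KineticParams,
    optics: OpticalGeometry,
    schedule: OperationSchedule,
) -> tuple[float, float, float, float]:
    """Time derivatives (dc_X/dt, dc_N/dt, dc_P/dt, dV/dt) at one state."""
    if state.volume <= 0:
        raise IntegrationError("volume must be positive", state)
    rates = effective_rates(state.c_n, state.c_x, state.c_p, params, optics, state.t)
    f = schedule.feed_flow(state.t)
    if schedule.mode == FED_BATCH:
        d = f / state.volume
    elif schedule.mode == SEMI_CONTINUOUS_RATE:
        d = schedule.dilution(state.t)
    else:
        d = 0.0
    dc_x = rates.r_x * state.c_x - d * state.c_x
    dc_n = -_MG_PER_G * rates.r_n * state.c_x + d * (schedule.feed_nitrate - state.c_n)
    dc_p = (rates.r_p - rates.r_p_d) * state.c_x - d * state.c_p
    dv = f if schedule.mode == FED_BATCH else 0.0
    return dc_x, dc_n, dc_p, dv


# ---------------------------------------------------------------------------
# integration core (shared by simulate() and the fitting engine)
# ---------------------------------------------------------------------------


def _segment_breakpoints(schedule: OperationSchedule, optics: OpticalGeometry) -> list[float]:
    t0, t1 = schedule.initial.t, schedule.t_end
    pts = {t0, t1}
    pts.update(optics.incident_light.breakpoints_within(t0, t1))
    pts.update(schedule.feed_flow.breakpoints_within(t0, t1))
    pts.update(schedule.dilution.breakpoints_within(t0, t1))
    pts.update(e.time for e in schedule.exchanges if t0 < e.time < t1)
    return sorted(pts)


def _interp_rows(table: np.ndarray, grid: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Row-wise linear interpolation: table (S, G) sampled on grid at x (S,)."""
    xc = np.clip(x, grid[0], grid[-1])
    j = np.clip(np.searchsorted(grid, xc, side="right") - 1, 0, len(grid) - 2)
    w = (xc - grid[j]) / (grid[j + 1] - grid[j])
    rows = np.arange(table.shape[0]) if table.shape[0] > 1 else np.zeros(len(x), dtype=int)
    return table[rows, j] * (1.0 - w) + table[rows, j + 1] * w


class _ExactLight:
    """Per-call quadrature light factor (used by single-candidate runs)."""

    def __init__(self, optics: OpticalGeometry):
        self.optics = optics
        a, w = _radial_quadrature(optics.radius)
        self._a, self._w = a, w

    def factor(self, i0: float, k_i: np.ndarray, c_x: np.ndarray) -> np.ndarray:
        out = np.empty_like(c_x)
        r = self.optics.radius
        for s in range(len(c_x)):
            intensity = i0 * mean_attenuation_profile(self.optics, float(c_x[s]))
            if k_i[s] == 0.0:
                monod = np.ones_like(intensity)
            else:
                monod = intensity / (intensity + k_i[s])
            out[s] = 2.0 / r**2 * np.sum(self._w * self._a * monod)
        return out


def _integrate(
    p: dict[str, np.ndarray],
    optics: OpticalGeometry,
    schedule: OperationSchedule,
    t_eval: np.ndarray,
    rtol: float,
    atol: float,
    light_model: "RadialLightModel | None" = None,
    track_harvest: bool = False,
):
    """Integrate S candidate parameter sets in one stacked ODE system.

    Parameters are arrays of shape (S,) keyed by the ``KineticParams``
    field names.  Returns (out, ok, message) where ``out`` has shape
    (len(t_eval), S, ncols) with columns c_X, c_N, c_P, V (+ harvested
    biomass g, harvested product mg when ``track_harvest``).  Output times
    that coincide with an exchange event report the pre-exchange state.
    """
    S = len(p["r_x_max"])
    ncols = 6 if track_harvest else 4
    t_eval = np.asarray(t_eval, dtype=float)
    init = schedule.initial
    y = np.tile(
        np.array([init.c_x, init.c_n, init.c_p, init.volume] + [0.0] * (ncols - 4)),
        (S, 1),
    )
    out = np.full((len(t_eval), S, ncols), np.nan)
    recorded = t_eval <= init.t + 1e-12
    if recorded.any():
        out[recorded] = y[None, :, :]

    exact = _ExactLight(optics) if light_model is None else None
    events_by_time = {e.time: e for e in schedule.exchanges}
    knots = _segment_breakpoints(schedule, optics)
    mode = schedule.mode
    c_n_f = schedule.feed_nitrate
    r_x_max, k_n, k_i = p["r_x_max"], p["k_n"], p["k_i"]
    y_x_n, r_p_max, k_p, k_pd = p["y_x_n"], p["r_p_max"], p["k_p"], p["k_pd"]

    for t0, t1 in zip(knots[:-1], knots[1:]):
        if t1 - t0 <= 1e-12:
            continue
        mid = 0.5 * (t0 + t1)
        i0 = optics.incident_light(mid)
        f_rate = schedule.feed_flow(mid)
        d_rate = schedule.dilution(mid)
        if light_model is not None:
            monod_tab = light_model.monod_table(i0, k_i)
            grid = light_model.grid

        def rhs(t, yflat):
            Y = yflat.reshape(S, ncols)
            cx = np.maximum(Y[:, 0], 0.0)
            cn = np.maximum(Y[:, 1], 0.0)
            cp = np.maximum(Y[:, 2], 0.0)
            v = Y[:, 3]
            if light_model is not None:
                phi = _interp_rows(monod_tab, grid, cx)
            else:
                phi = exact.factor(i0, k_i, cx)
            r_light = r_x_max * phi
            with np.errstate(invalid="ignore", divide="ignore"):
                monod_n = np.where(cn > 0.0, cn / (cn + k_n), 0.0)
            r_x = np.minimum(r_light, r_x_max * monod_n)
            r_n = r_x / y_x_n
            with np.errstate(invalid="ignore", divide="ignore"):
                r_p = np.where(cn > 0.0, r_p_max * cn / (cn + k_p), 0.0)
            r_pd = k_pd * cp
            if mode == FED_BATCH:
                d = f_rate / v
            elif mode == SEMI_CONTINUOUS_RATE:
                d = d_rate
            else:
                d = 0.0
            dY = np.empty_like(Y)
            dY[:, 0] = r_x * cx - d * cx
            dY[:, 1] = -_MG_PER_G * r_n * cx + d * (c_n_f - cn)
            dY[:, 2] = (r_p - r_pd) * cx - d * cp
            dY[:, 3] = f_rate if mode == FED_BATCH else 0.0
            if ncols == 6:
                d_rem = d_rate if mode == SEMI_CONTINUOUS_RATE else 0.0
                dY[:, 4] = d_rem * cx * v
                dY[:, 5] = d_rem * cp * v
            return dY.reshape(-1)

        mask = (t_eval > t0 + 1e-12) & (t_eval <= t1 + 1e-12)
        ts = np.unique(np.concatenate([t_eval[mask], [t1]]))
        sol = solve_ivp(
            rhs, (t0, t1), y.reshape(-1), method="RK45", t_eval=ts, rtol=rtol, atol=atol
        )
        if not sol.success:
            return out, False, sol.message
        states = sol.y.T.reshape(len(ts), S, ncols)
        idx = np.searchsorted(ts, t_eval[mask])
        out[mask] = states[idx]
        y = states[-1].copy()
        event = events_by_time.get(t1)
        if event is not None:
            if ncols == 6:
                y[:, 4] += event.fraction * y[:, 3] * y[:, 0]
                y[:, 5] += event.fraction * y[:, 3] * y[:, 2]
            y[:, 0] *= 1.0 - event.fraction
            y[:, 2] *= 1.0 - event.fraction
            y[:, 1] = y[:, 1] * (1.0 - event.fraction) + event.fresh_nitrate * event.fraction
    return out, True, "ok"


@dataclass
class Trajectory:
    """Simulated reactor trajectory with rates and the limiting regime.

    ``frame`` has one row per output time with columns ``time_d``,
    ``biomass_gDW_per_L``, ``nitrate_mg_per_L``, ``product_mg_per_L``,
    ``volume_L``, ``growth_rate_per_d``, ``limiting_regime`` plus the
    remaining specific rates and the cumulative harvest columns.
    """

    frame: pd.DataFrame
    harvested_biomass_g: float = 0.0
    harvested_product_mg: float = 0.0

    EXPORT_COLUMNS = (
        "time_d",
        "biomass_gDW_per_L",
        "nitrate_mg_per_L",
        "product_mg_per_L",
        "volume_L",
        "growth_rate_per_d",
        "limiting_regime",
    )

    @property
    def times(self) -> np.ndarray:
        return self.frame["time_d"].to_numpy()

    def final_state(self) -> ReactorState:
        row = self.frame.iloc[-1]
        return ReactorState(
            t=row["time_d"],
            c_x=row["biomass_gDW_per_L"],
            c_n=row["nitrate_mg_per_L"],
            c_p=row["product_mg_per_L"],
            volume=row["volume_L"],
        )

    def total_product_mg(self) -> float:
        """Product formed over the run: in-vessel amount plus harvested."""
        row = self.frame.iloc[-1]
        return row["product_mg_per_L"] * row["volume_L"] + self.harvested_product_mg

    def values_at(self, variable_column: str, times) -> np.ndarray:
        """Values of one column at the requested output times (must be a
        subset of the trajectory's times)."""
        lookup = pd.Series(
            self.frame[variable_column].to_numpy(), index=np.round(self.times, 10)
        )
        return lookup.loc[np.round(np.asarray(times, dtype=float), 10)].to_numpy()

    def to_csv(self, path, header_comments: tuple[str, ...] = ()) -> None:
        """Write the standard trajectory CSV (RFC-4180, '.' decimals),
        optionally preceded by '#'-prefixed provenance comments."""
        with open(path, "w", newline="") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            self.frame.loc[:, list(self.EXPORT_COLUMNS)].to_csv(fh, index=False)


def simulate(
    params: KineticParams,
    optics: OpticalGeometry,
    schedule: OperationSchedule,
    output_times=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the mass balances and return a :class:`Trajectory`.

    ``output_times`` defaults to 201 evenly spaced points over the horizon.
    Small negative excursions (above -1e-9) are clamped to zero; anything
    below that magnitude raises :class:`IntegrationError`.
    """
    if output_times is None:
        output_times = np.linspace(schedule.initial.t, schedule.t_end, 201)
    t_eval = np.asarray(output_times, dtype=float)
    if np.any(np.diff(t_eval) <= 0):
        raise ValueError("output_times must be strictly increasing")
    if t_eval[0] < schedule.initial.t - 1e-12 or t_eval[-1] > schedule.t_end + 1e-12:
        raise ValueError("output_times must lie within [t0, t_end]")

    arrays = {k: np.array([v]) for k, v in params.as_dict().items()}
    out, ok, message = _integrate(
        arrays, optics, schedule, t_eval, rtol, atol, light_model=None, track_harvest=True
    )
    states = out[:, 0, :]
    if not ok:
        good = ~np.isnan(states[:, 0])
        last = None
        if good.any():
            i = np.max(np.nonzero(good))
            last = ReactorState(
                t=t_eval[i],
                c_x=max(states[i, 0], 0.0),
                c_n=max(states[i, 1], 0.0),
                c_p=max(states[i, 2], 0.0),
                volume=states[i, 3],
            )
        raise IntegrationError(f"ODE solver failed: {message}", last)

    conc = states[:, :3]
    if np.any(conc < -NEGATIVE_CLAMP):
        raise IntegrationError(
            f"negative concentrations beyond tolerance (min {conc.min():.3e})"
        )
    conc = np.clip(conc, 0.0, None)

    rates = [
        effective_rates(conc[i, 1], conc[i, 0], conc[i, 2], params, optics, t_eval[i])
        for i in range(len(t_eval))
    ]
    frame = pd.DataFrame(
        {
            "time_d": t_eval,
            "biomass_gDW_per_L": conc[:, 0],
            "nitrate_mg_per_L": conc[:, 1],
            "product_mg_per_L": conc[:, 2],
            "volume_L": states[:, 3],
            "growth_rate_per_d": [r.r_x for r in rates],
            "nitrate_uptake_g_per_gDW_d": [r.r_n for r in rates],
            "product_formation_mg_per_gDW_d": [r.r_p for r in rates],
            "product_degradation_mg_per_gDW_d": [r.r_p_d for r in rates],
            "limiting_regime": [r.limiting_regime for r in rates],
            "harvested_biomass_g": states[:, 4],
            "harvested_product_mg": states[:, 5],
        }
    )
    return Trajectory(
        frame=frame,
        harvested_biomass_g=float(states[-1, 4]),
        harvested_product_mg=float(states[-1, 5]),
    )
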