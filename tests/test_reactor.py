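"""Mass balances, operating modes, events and integrator accuracy."""

import numpy as np
import pytest

from mosskinetics import (
    ExchangeEvent,
    HarvestLedger,
    KineticParams,
    OperationSchedule,
    OpticalGeometry,
    ReactorState,
    StepFunction,
    apply_exchange_event,
    derivatives,
    dilution_rate_from_exchange,
    effective_rates,
    simulate,
)
from mosskinetics.reactor import BATCH, FED_BATCH, SEMI_CONTINUOUS_EVENTS, SEMI_CONTINUOUS_RATE

LINE_B = KineticParams(
    r_x_max=0.699, k_n=4.41, k_i=15.29, y_x_n=7.042,
    r_p_max=0.327, k_p=1.010, k_pd=0.0801,
)
OPTICS = OpticalGeometry.from_cm(350.0, 0.049, 8.75)


def batch_schedule(t_end=8.0, c_n0=500.0, c_x0=0.1, volume=5.0):
    return OperationSchedule(
        mode=BATCH,
        initial=ReactorState(t=0.0, c_x=c_x0, c_n=c_n0, c_p=0.0, volume=volume),
        t_end=t_end,
    )


class TestScheduleInvariants:
    def test_batch_rejects_feed_and_dilution(self):
        init = ReactorState(0, 0.1, 500, 0, 5)
        with pytest.raises(ValueError):
            OperationSchedule(
                mode=BATCH, initial=init, t_end=8,
                dilution=StepFunction.constant(0.4),
            )
        with pytest.raises(ValueError):
            OperationSchedule(
                mode=BATCH, initial=init, t_end=8,
                feed_flow=StepFunction.constant(0.2),
            )

    def test_semi_continuous_rejects_feed_flow(self):
        init = ReactorState(0, 0.1, 500, 0, 5)
        with pytest.raises(ValueError):
            OperationSchedule(
                mode=SEMI_CONTINUOUS_RATE, initial=init, t_end=8,
                dilution=StepFunction.constant(0.4),
                feed_flow=StepFunction.constant(0.2),
            )

    def test_exchange_events_must_be_ordered(self):
        init = ReactorState(0, 0.1, 500, 0, 5)
        with pytest.raises(ValueError):
            OperationSchedule(
                mode=SEMI_CONTINUOUS_EVENTS, initial=init, t_end=8,
                exchanges=(
                    ExchangeEvent(5.0, 0.4, 500.0),
                    ExchangeEvent(3.0, 0.4, 500.0),
                ),
            )


class TestDerivatives:
    def test_batch_growth_only(self):
        state = ReactorState(t=0.0, c_x=1.0, c_n=400.0, c_p=0.5, volume=5.0)
        rates = effective_rates(400.0, 1.0, 0.5, LINE_B, OPTICS)
        dc_x, dc_n, dc_p, dv = derivatives(state, LINE_B, OPTICS, batch_schedule())
        assert dc_x == pytest.approx(rates.r_x)
        assert dc_n == pytest.approx(-1000.0 * rates.r_n)
        assert dc_p == pytest.approx(rates.r_p - rates.r_p_d)
        assert dv == 0.0

    def test_semi_continuous_dilution_at_zero_growth(self):
        # depleted nitrate means r_X = 0; dilution alone drives dc_X/dt
        sched = OperationSchedule(
            mode=SEMI_CONTINUOUS_RATE,
            initial=ReactorState(0, 0.1, 500, 0, 5),
            t_end=11.0,
            dilution=StepFunction.constant(0.4),
            feed_nitrate=500.0,
        )
        state = ReactorState(t=7.0, c_x=1.0, c_n=0.0, c_p=0.0, volume=5.0)
        dc_x, dc_n, _, dv = derivatives(state, LINE_B, OPTICS, sched)
        assert dc_x == pytest.approx(-0.4)
        assert dc_n == pytest.approx(0.4 * 500.0)
        assert dv == 0.0

    def test_fed_batch_dilution_is_flow_over_volume(self):
        sched = OperationSchedule(
            mode=FED_BATCH,
            initial=ReactorState(0, 0.1, 500, 0, 4),
            t_end=12.0,
            feed_flow=StepFunction.constant(0.2),
            feed_nitrate=2500.0,
        )
        state = ReactorState(t=8.0, c_x=1.0, c_n=0.0, c_p=2.0, volume=4.0)
        d = 0.2 / 4.0
        dc_x, dc_n, dc_p, dv = derivatives(state, LINE_B, OPTICS, sched)
        assert dc_x == pytest.approx(-d * 1.0)
        assert dc_n == pytest.approx(d * 2500.0)
        assert dc_p == pytest.approx(-LINE_B.k_pd * 2.0 * 1.0 - d * 2.0)
        assert dv == pytest.approx(0.2)


class TestSimulate:
    def test_exponential_limit_under_saturating_light_and_nitrate(self):
        """With k_I = 0 and abundant nitrate, growth is exponential at
        nearly r_X_max over the first day."""
        params = LINE_B.replace(k_i=0.0)
        sched = batch_schedule(t_end=1.0, c_n0=5000.0)
        traj = simulate(params, OPTICS, sched, output_times=np.linspace(0, 1, 11))
        expected = 0.1 * np.exp(params.r_x_max * traj.times)
        assert np.allclose(traj.frame["biomass_gDW_per_L"], expected, rtol=0.01)

    def test_batch_yield_conservation_law(self):
        """c_X(t) - c_X(0) = y_X_N (c_N(0) - c_N(t)) / 1000 at all times,
        because uptake is coupled to growth through the yield in both
        limitation regimes."""
        traj = simulate(LINE_B, OPTICS, batch_schedule(t_end=12.0))
        f = traj.frame
        lhs = f["biomass_gDW_per_L"] - 0.1
        rhs = LINE_B.y_x_n * (500.0 - f["nitrate_mg_per_L"]) / 1000.0
        assert np.max(np.abs(lhs - rhs)) < 1e-6

    def test_batch_nitrate_depletion_stops_growth(self):
        traj = simulate(LINE_B, OPTICS, batch_schedule(t_end=12.0))
        final = traj.frame.iloc[-1]
        assert final["nitrate_mg_per_L"] < 5.0
        assert final["growth_rate_per_d"] < 1e-3
        assert final["limiting_regime"] == "nitrate"

    def test_washout_when_dilution_exceeds_max_growth(self):
        sched = OperationSchedule(
            mode=SEMI_CONTINUOUS_RATE,
            initial=ReactorState(0, 0.1, 500, 0, 5),
            t_end=11.0,
            dilution=StepFunction(times=(0.0, 6.0), values=(0.0, 1.0)),
            feed_nitrate=500.0,
        )
        traj = simulate(LINE_B, OPTICS, sched, output_times=np.arange(0, 11.5, 0.5))
        cx = traj.frame["biomass_gDW_per_L"].to_numpy()
        after = traj.times >= 6.0
        assert np.all(np.diff(cx[after]) < 0)

    def test_fed_batch_volume_bookkeeping(self):
        sched = OperationSchedule(
            mode=FED_BATCH,
            initial=ReactorState(0, 0.1, 500, 0, 4),
            t_end=12.0,
            feed_flow=StepFunction(times=(0.0, 7.0), values=(0.0, 0.2)),
            feed_nitrate=2500.0,
        )
        traj = simulate(LINE_B, OPTICS, sched, output_times=np.arange(13.0))
        expected = 4.0 + np.array(
            [sched.feed_flow.integral(0.0, t) for t in traj.times]
        )
        assert np.allclose(traj.frame["volume_L"], expected, atol=1e-9)

    def test_product_monotone_without_degradation_or_dilution(self):
        params = LINE_B.replace(k_pd=0.0)
        traj = simulate(params, OPTICS, batch_schedule(t_end=12.0))
        cp = traj.frame["product_mg_per_L"].to_numpy()
        assert np.all(np.diff(cp) >= -1e-12)

    def test_grid_refinement_convergence(self):
        base = simulate(LINE_B, OPTICS, batch_schedule(), rtol=1e-8, atol=1e-10)
        fine = simulate(LINE_B, OPTICS, batch_schedule(), rtol=5e-9, atol=5e-11)
        for col in ("biomass_gDW_per_L", "nitrate_mg_per_L", "product_mg_per_L"):
            a = base.frame[col].to_numpy()
            b = fine.frame[col].to_numpy()
            scale = np.max(np.abs(b)) or 1.0
            assert np.max(np.abs(a - b)) / scale < 1e-6

    def test_output_times_validation(self):
        with pytest.raises(ValueError):
            simulate(LINE_B, OPTICS, batch_schedule(), output_times=[0.0, 9.0])
        with pytest.raises(ValueError):
            simulate(LINE_B, OPTICS, batch_schedule(), output_times=[0.5, 0.5])


class TestExchangeEvents:
    def test_biomass_removal_and_ledger(self):
        ledger = HarvestLedger()
        state = ReactorState(t=6.0, c_x=2.0, c_n=10.0, c_p=1.0, volume=5.0)
        new = apply_exchange_event(state, 0.4, 500.0, ledger)
        assert new.c_x == pytest.approx(1.2)
        assert new.volume == 5.0
        assert ledger.biomass_g == pytest.approx(0.4 * 5.0 * 2.0)
        assert ledger.product_mg == pytest.approx(0.4 * 5.0 * 1.0)

    def test_nitrate_mixing(self):
        state = ReactorState(t=6.0, c_x=2.0, c_n=10.0, c_p=1.0, volume=5.0)
        new = apply_exchange_event(state, 0.2, 500.0)
        assert new.c_n == pytest.approx(10.0 * 0.8 + 500.0 * 0.2)  # 108 mg/L

    def test_two_half_exchanges_quarter_the_product(self):
        state = ReactorState(t=6.0, c_x=2.0, c_n=10.0, c_p=1.0, volume=5.0)
        once = apply_exchange_event(state, 0.5, 0.0)
        twice = apply_exchange_event(once, 0.5, 0.0)
        assert twice.c_p == pytest.approx(0.25)

    def test_invalid_fraction_rejected(self):
        state = ReactorState(t=6.0, c_x=2.0, c_n=10.0, c_p=1.0, volume=5.0)
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                apply_exchange_event(state, bad, 500.0)

    def test_event_mode_simulation_tracks_harvest(self):
        events = tuple(
            ExchangeEvent(t, 0.4, 500.0) for t in (6.0, 7.0, 8.0, 9.0, 10.0)
        )
        sched = OperationSchedule(
            mode=SEMI_CONTINUOUS_EVENTS,
            initial=ReactorState(0, 0.1, 500, 0, 5),
            t_end=11.0,
            exchanges=events,
        )
        traj = simulate(LINE_B, OPTICS, sched, output_times=np.arange(0, 11.5, 0.5))
        assert np.allclose(traj.frame["volume_L"], 5.0)
        assert traj.harvested_biomass_g > 0
        assert traj.total_product_mg() > traj.final_state().c_p * 5.0
        # sampling at an event time reports the pre-exchange state:
        # biomass just after day 6 is lower than at day 6
        f = traj.frame
        at6 = f.loc[np.isclose(f.time_d, 6.0), "biomass_gDW_per_L"].iloc[0]
        at6_5 = f.loc[np.isclose(f.time_d, 6.5), "biomass_gDW_per_L"].iloc[0]
        assert at6_5 < at6


def test_daily_exchange_dilution_rate_arithmetic():
    assert dilution_rate_from_exchange(2.0, 5.0) == pytest.approx(0.4)
    assert dilution_rate_from_exchange(1.0, 5.0) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        dilution_rate_from_exchange(5.0, 5.0)
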