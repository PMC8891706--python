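"""Global least-squares parameter estimation and goodness of fit.

The estimation problem is the classical trajectory fit: minimise the
pooled sum of squared residuals between observed concentrations and the
simulated model over a box of kinetic parameters,

    min_P  sum_ij ( Y_ij - f(X_i, P) )^2 ,

solved with differential evolution (seeded, population >= 15 per free
dimension) followed by an optional local gradient-free (Nelder-Mead)
polish.  Because the observed variables span 2-3 orders of magnitude
(nitrate in hundreds of mg/L, product in tenths of mg/L), residuals are
scaled per variable by the maximum absolute observed value before squaring
by default; the raw unweighted objective is available with
``scaling="none"``.

Goodness of fit is reported per observed variable as the coefficient of
determination R^2 = 1 - SS_res/SS_tot on the unscaled data, using
replicate means as observations.

During the evolutionary search the population is integrated as one
stacked ODE system using tabulated light factors (fast path); the final
objective and R^2 are recomputed with the exact quadrature light field at
the default integrator tolerances, so reported numbers match
:func:`mosskinetics.reactor.simulate` to machine precision.
"""

from __future__ import annotations

import inspect
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .kinetics import KineticParams
from .lightfield import OpticalGeometry, RadialLightModel
from .reactor import (
    FED_BATCH,
    IntegrationError,
    OperationSchedule,
    Trajectory,
    _integrate,
    simulate,
)

VARIABLES = ("biomass", "nitrate", "product")

#: trajectory column per observed variable
VARIABLE_COLUMNS = {
    "biomass": "biomass_gDW_per_L",
    "nitrate": "nitrate_mg_per_L",
    "product": "product_mg_per_L",
}

_STATE_INDEX = {"biomass": 0, "nitrate": 1, "product": 2}

#: kinetic parameters that may be freed; sigma_x frees the optical
#: cross-section (slower, non-vectorised search path)
FREE_PARAMETER_NAMES = (
    "r_x_max",
    "k_n",
    "k_i",
    "y_x_n",
    "r_p_max",
    "k_p",
    "k_pd",
    "sigma_x",
)

#: finite objective returned when the integrator fails at a candidate
FAILURE_PENALTY = 1e12

DEFAULT_OPTIMIZER_SETTINGS = {
    "popsize": 15,
    "maxiter": 500,
    "tol": 1e-8,
    "mutation": (0.5, 1.0),
    "recombination": 0.7,
    "init": "latinhypercube",
    "polish": True,
    "polish_maxiter": 400,
    "search_rtol": 1e-6,
    "search_atol": 1e-8,
}


@dataclass
class ObservedDataset:
    """Long-format observations bound to an operating schedule.

    ``data`` columns: ``time_d``, ``variable`` (biomass|nitrate|product),
    ``value``, optional ``replicate_id`` and ``sd``.  Values carry the
    reporting units (g DW/L, mg NO3-/L, mg/L).
    """

    data: pd.DataFrame
    schedule: OperationSchedule
    optics: OpticalGeometry
    name: str = ""

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = {"time_d", "variable", "value"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"observation table lacks columns: {sorted(missing)}")
        if len(df) == 0:
            raise ValueError("observation table is empty")
        bad = set(df["variable"]) - set(VARIABLES)
        if bad:
            raise ValueError(
                f"unknown variables {sorted(bad)}; admissible names are {list(VARIABLES)}"
            )
        if "replicate_id" not in df.columns:
            df["replicate_id"] = 0
        t = df["time_d"].to_numpy(dtype=float)
        if t.min() < self.schedule.initial.t - 1e-12 or t.max() > self.schedule.t_end + 1e-12:
            raise ValueError("observation times must lie within the schedule horizon")
        self.data = df

    @property
    def observed_variables(self) -> tuple[str, ...]:
        present = set(self.data["variable"])
        return tuple(v for v in VARIABLES if v in present)

    @property
    def times(self) -> np.ndarray:
        """Sorted unique observation times."""
        return np.unique(self.data["time_d"].to_numpy(dtype=float))

    def scales(self) -> dict[str, float]:
        """Per-variable max |value| (1.0 where the maximum is zero)."""
        out = {}
        for v in self.observed_variables:
            m = float(self.data.loc[self.data["variable"] == v, "value"].abs().max())
            out[v] = m if m > 0 else 1.0
        return out

    def replicate_means(self) -> pd.DataFrame:
        """Mean observed value per (variable, time)."""
        return (
            self.data.groupby(["variable", "time_d"], as_index=False)["value"].mean()
        )

    def to_csv(self, path, header_comments: tuple[str, ...] = ()) -> None:
        cols = ["time_d", "variable", "value", "replicate_id"]
        if "sd" in self.data.columns:
            cols.append("sd")
        with open(path, "w", newline="") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            self.data.loc[:, cols].to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path, schedule, optics, name: str = "") -> "ObservedDataset":
        df = pd.read_csv(path, comment="#")
        return cls(data=df, schedule=schedule, optics=optics, name=name)


@dataclass
class FitResult:
    """Outcome of a parameter-estimation run."""

    params: KineticParams
    optics: OpticalGeometry
    free: tuple[str, ...]
    fixed: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    objective: float
    r_squared: dict[str, float | None]
    seed: int
    popsize: int
    n_generations: int
    n_evaluations: int
    converged: bool
    message: str
    scaling: str = "max"

    def to_dict(self) -> dict:
        return {
            "parameters": self.params.as_dict() | {"sigma_x": self.optics.sigma_x},
            "free": list(self.free),
            "fixed": self.fixed,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "objective": self.objective,
            "r_squared": self.r_squared,
            "seed": self.seed,
            "popsize": self.popsize,
            "n_generations": self.n_generations,
            "n_evaluations": self.n_evaluations,
            "converged": self.converged,
            "message": self.message,
            "scaling": self.scaling,
        }

    def to_json(self, path=None, **extra) -> str:
        payload = self.to_dict() | extra
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _as_dataset_list(datasets) -> list[ObservedDataset]:
    if isinstance(datasets, ObservedDataset):
        datasets = [datasets]
    datasets = list(datasets)
    if not datasets:
        raise ValueError("at least one dataset is required")
    return datasets


def _candidate(base: KineticParams, optics: OpticalGeometry, values: dict[str, float]):
    """Apply free-parameter values to the base parameter set / optics."""
    kin = {k: v for k, v in values.items() if k != "sigma_x"}
    params = base.replace(**kin) if kin else base
    if "sigma_x" in values:
        optics = optics.replace_sigma(values["sigma_x"])
    return params, optics


def _dataset_residual_layout(dataset: ObservedDataset):
    """Precompute index arrays mapping observations onto model outputs."""
    times = dataset.times
    time_index = {round(t, 12): i for i, t in enumerate(times)}
    layout = []
    for v in dataset.observed_variables:
        sub = dataset.data[dataset.data["variable"] == v]
        idx = np.array([time_index[round(t, 12)] for t in sub["time_d"]], dtype=int)
        layout.append((v, idx, sub["value"].to_numpy(dtype=float)))
    return times, layout


def objective(
    candidate_params: KineticParams,
    datasets,
    weights=None,
    *,
    optics_override: OpticalGeometry | None = None,
    scaling: str = "max",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Pooled weighted sum of squared residuals for one candidate.

    Simulates each dataset's schedule, evaluates the model at the
    observation times and pools squared residuals over variables and
    replicates; per-variable residuals are divided by the dataset-variable
    maximum absolute observation when ``scaling == "max"``.  Returns a
    large finite penalty instead of raising when the integrator fails.
    """
    datasets = _as_dataset_list(datasets)
    if weights is None:
        weights = [1.0] * len(datasets)
    total = 0.0
    for ds, w in zip(datasets, weights):
        optics = optics_override if optics_override is not None else ds.optics
        times, layout = _dataset_residual_layout(ds)
        try:
            traj = simulate(
                candidate_params, optics, ds.schedule, output_times=times, rtol=rtol, atol=atol
            )
        except IntegrationError:
            return FAILURE_PENALTY
        scales = ds.scales() if scaling == "max" else {v: 1.0 for v in VARIABLES}
        for v, idx, obs in layout:
            model = traj.frame[VARIABLE_COLUMNS[v]].to_numpy()[idx]
            total += w * float(np.sum(((obs - model) / scales[v]) ** 2))
    return total


def r_squared(trajectory: Trajectory, dataset: ObservedDataset) -> dict[str, float | None]:
    """Coefficient of determination per observed variable.

    Uses replicate means as observations: R^2 = 1 - SS_res/SS_tot.
    Variables with zero variance across time points are reported as
    ``None`` (undefined), never as 1.
    """
    means = dataset.replicate_means()
    out: dict[str, float | None] = {}
    for v in dataset.observed_variables:
        sub = means[means["variable"] == v]
        if len(sub) < 2:
            raise ValueError(f"variable {v!r} needs at least 2 observations")
        y = sub["value"].to_numpy(dtype=float)
        yhat = trajectory.values_at(VARIABLE_COLUMNS[v], sub["time_d"].to_numpy())
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0.0:
            out[v] = None
            continue
        out[v] = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    return out


class _SearchEngine:
    """Vectorised objective used inside differential evolution.

    Evaluates a whole candidate population per call by stacking the
    population into one ODE system, with tabulated light factors.  Falls
    back to per-candidate evaluation if a stacked integration fails, so a
    single pathological candidate only penalises itself.
    """

    def __init__(self, datasets, free, base, optics_list, bounds, weights, scaling, settings):
        self.datasets = datasets
        self.free = free
        self.base = base
        self.optics_list = optics_list
        self.weights = weights
        self.scaling = scaling
        self.rtol = settings["search_rtol"]
        self.atol = settings["search_atol"]
        self.n_calls = 0
        self._layouts = [_dataset_residual_layout(ds) for ds in datasets]
        self._scales = [
            ds.scales() if scaling == "max" else {v: 1.0 for v in VARIABLES}
            for ds in datasets
        ]
        self._light = []
        y_hi = bounds.get("y_x_n", (base.y_x_n, base.y_x_n))[1]
        for ds, optics in zip(datasets, optics_list):
            self._light.append(
                RadialLightModel(optics, c_x_max=self._biomass_bound(ds, y_hi))
            )

    @staticmethod
    def _biomass_bound(dataset: ObservedDataset, y_hi: float) -> float:
        """Upper bound on reachable biomass for grid sizing (generous)."""
        sched = dataset.schedule
        init = sched.initial
        nitrate = init.c_n
        nitrate += sched.feed_nitrate * sched.dilution.integral(init.t, sched.t_end)
        if sched.mode == FED_BATCH:
            nitrate += (
                sched.feed_nitrate
                * sched.feed_flow.integral(init.t, sched.t_end)
                / init.volume
            )
        for e in sched.exchanges:
            nitrate += e.fraction * e.fresh_nitrate
        return 1.2 * (init.c_x + y_hi * nitrate / 1000.0) + 1.0

    def _arrays(self, x2d: np.ndarray) -> dict[str, np.ndarray]:
        S = x2d.shape[1]
        arrays = {k: np.full(S, v) for k, v in self.base.as_dict().items()}
        for i, name in enumerate(self.free):
            arrays[name] = x2d[i]
        return arrays

    def population_energies(self, x2d: np.ndarray) -> np.ndarray:
        """Objective for a population ``x2d`` of shape (n_free, S)."""
        x2d = np.asarray(x2d, dtype=float)
        S = x2d.shape[1]
        self.n_calls += S
        arrays = self._arrays(x2d)
        energies = np.zeros(S)
        for ds, optics, light, (times, layout), scales, w in zip(
            self.datasets, self.optics_list, self._light, self._layouts, self._scales,
            self.weights,
        ):
            out, ok, _ = _integrate(
                arrays, optics, ds.schedule, times, self.rtol, self.atol,
                light_model=light,
            )
            if not ok:
                for s in range(S):
                    energies[s] += self._single(arrays, s, ds, optics, light,
                                                times, layout, scales, w)
                continue
            for v, idx, obs in layout:
                model = np.clip(out[:, :, _STATE_INDEX[v]], 0.0, None)[idx]  # (n_obs, S)
                energies += w * np.sum(((obs[:, None] - model) / scales[v]) ** 2, axis=0)
        return energies

    def _single(self, arrays, s, ds, optics, light, times, layout, scales, w) -> float:
        one = {k: v[s : s + 1] for k, v in arrays.items()}
        out, ok, _ = _integrate(
            one, optics, ds.schedule, times, self.rtol, self.atol, light_model=light
        )
        if not ok:
            return FAILURE_PENALTY
        total = 0.0
        for v, idx, obs in layout:
            model = np.clip(out[:, 0, _STATE_INDEX[v]], 0.0, None)[idx]
            total += w * float(np.sum(((obs - model) / scales[v]) ** 2))
        return total

    def __call__(self, x: np.ndarray) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            return float(self.population_energies(x[:, None])[0])
        return self.population_energies(x)


def _seed_de_kwarg(seed: int) -> dict:
    """scipy renamed differential_evolution's ``seed`` to ``rng``."""
    params = inspect.signature(differential_evolution).parameters
    return {"rng": seed} if "rng" in params else {"seed": seed}


def fit(
    datasets,
    bounds: dict[str, tuple[float, float]],
    fixed_params: KineticParams,
    seed: int,
    optimizer_settings: dict | None = None,
    *,
    weights=None,
    scaling: str = "max",
) -> FitResult:
    """Estimate free parameters by bounded global least squares.

    Parameters
    ----------
    datasets : ObservedDataset or sequence thereof
        Observations to fit (jointly, with shared parameters, when several
        are given).
    bounds : dict
        ``{name: (low, high)}`` for each free parameter; names from
        :data:`FREE_PARAMETER_NAMES`.  Collapsed bounds (low == high) pin a
        parameter at that value.
    fixed_params : KineticParams
        Values of all parameters not freed (and the search starting
        template).
    seed : int
        Seed for the differential-evolution population; the whole fit is
        deterministic given (seed, settings, data).
    optimizer_settings : dict, optional
        Overrides of :data:`DEFAULT_OPTIMIZER_SETTINGS`.

    Returns
    -------
    FitResult
        Estimates, objective (exact recomputation), per-variable R^2 and
        optimizer diagnostics.  Non-convergence flags the result instead of
        raising.
    """
    datasets = _as_dataset_list(datasets)
    if not bounds:
        raise ValueError("no free parameters: bounds is empty")
    unknown = set(bounds) - set(FREE_PARAMETER_NAMES)
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    for name, (lo, hi) in bounds.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError(f"bounds for {name!r} must be finite and ordered")
    if seed is None:
        raise ValueError("a seed is required for reproducible fits")

    settings = DEFAULT_OPTIMIZER_SETTINGS | (optimizer_settings or {})
    free = tuple(bounds.keys())
    optics_list = [ds.optics for ds in datasets]
    if weights is None:
        weights = [1.0] * len(datasets)

    vectorized = "sigma_x" not in free
    de_bounds = [tuple(bounds[n]) for n in free]
    # degenerate (collapsed) bounds break latinhypercube sampling of some
    # scipy versions; widen infinitesimally and clamp after.
    de_bounds = [
        (lo, hi) if hi > lo else (lo, lo + max(1e-12, abs(lo) * 1e-12))
        for lo, hi in de_bounds
    ]

    if vectorized:
        engine = _SearchEngine(
            datasets, free, fixed_params, optics_list, bounds, weights, scaling, settings
        )
        func = engine
        de_kwargs = {"vectorized": True, "updating": "deferred"}
    else:
        def func(x):
            values = dict(zip(free, np.atleast_1d(x)))
            params, optics = _candidate(fixed_params, optics_list[0], values)
            return objective(
                params, datasets, weights,
                optics_override=optics if "sigma_x" in values else None,
                scaling=scaling,
                rtol=settings["search_rtol"], atol=settings["search_atol"],
            )
        engine = None
        de_kwargs = {}

    result = differential_evolution(
        func,
        de_bounds,
        strategy="best1bin",
        popsize=settings["popsize"],
        maxiter=settings["maxiter"],
        tol=settings["tol"],
        mutation=settings["mutation"],
        recombination=settings["recombination"],
        init=settings["init"],
        polish=False,
        **de_kwargs,
        **_seed_de_kwarg(seed),
    )
    x_best = np.asarray(result.x, dtype=float)
    n_evals = engine.n_calls if engine is not None else result.nfev

    if settings["polish"]:
        scalar = (lambda x: func(x)) if engine is None else (
            lambda x: float(engine.population_energies(np.asarray(x)[:, None])[0])
        )
        local = minimize(
            scalar,
            x_best,
            method="Nelder-Mead",
            bounds=de_bounds,
            options={"maxiter": settings["polish_maxiter"], "xatol": 1e-10, "fatol": 1e-12},
        )
        if local.fun <= result.fun:
            x_best = np.asarray(local.x, dtype=float)
        n_evals += local.nfev

    x_best = np.clip(x_best, [b[0] for b in de_bounds], [b[1] for b in de_bounds])
    # re-clamp onto the user's (possibly collapsed) bounds
    x_best = np.clip(
        x_best, [bounds[n][0] for n in free], [bounds[n][1] for n in free]
    )
    values = dict(zip(free, x_best))
    params, optics = _candidate(fixed_params, optics_list[0], values)

    final_objective = objective(
        params, datasets, weights,
        optics_override=optics if "sigma_x" in values else None,
        scaling=scaling,
    )
    r2: dict[str, float | None] = {}
    for ds in datasets:
        ds_optics = optics if "sigma_x" in values else ds.optics
        traj = simulate(params, ds_optics, ds.schedule, output_times=ds.times)
        ds_r2 = r_squared(traj, ds)
        if len(datasets) == 1:
            r2 = ds_r2
        else:
            r2.update({f"{ds.name or 'dataset'}:{k}": v for k, v in ds_r2.items()})

    fixed = {
        k: v for k, v in (fixed_params.as_dict() | {"sigma_x": optics_list[0].sigma_x}).items()
        if k not in free
    }
    return FitResult(
        params=params,
        optics=optics if "sigma_x" in values else optics_list[0],
        free=free,
        fixed=fixed,
        bounds={k: tuple(v) for k, v in bounds.items()},
        objective=final_objective,
        r_squared=r2,
        seed=int(seed),
        popsize=settings["popsize"],
        n_generations=int(result.nit),
        n_evaluations=int(n_evals),
        converged=bool(result.success),
        message=str(result.message),
        scaling=scaling,
    )


def default_bounds(params: KineticParams, free) -> dict[str, tuple[float, float]]:
    """A decade around each reference value: [x/10, 10x] per free parameter."""
    values = params.as_dict()
    out = {}
    for name in free:
        x = values[name]
        if x <= 0:
            raise ValueError(f"cannot derive default bounds for {name!r} = {x}")
        out[name] = (x / 10.0, x * 10.0)
    return out


class MossBioreactorModel(BaseEstimator, RegressorMixin):
    """Scikit-learn style front end to the kinetic trajectory fit.

    The design matrix ``X`` is a DataFrame (or record array) with columns
    ``time_d`` and ``variable`` (optionally ``replicate_id``); ``y`` holds
    the observed values.  :meth:`fit` estimates the free kinetic
    parameters for the configured operating schedule, :meth:`predict`
    returns model concentrations at the requested (time, variable) pairs,
    and ``score`` is the usual R^2 of :class:`~sklearn.base.RegressorMixin`.

    Parameters
    ----------
    schedule : OperationSchedule
    optics : OpticalGeometry
    fixed_params : KineticParams
        Values for parameters that are not freed, and the template the
        default bounds are derived from.
    bounds : dict, optional
        ``{name: (low, high)}``; defaults to a decade around
        ``fixed_params`` for ``r_x_max``, ``k_n``, ``y_x_n`` and, when the
        template has product kinetics, ``r_p_max``, ``k_p``, ``k_pd``.
    seed : int
    optimizer_settings : dict, optional
    scaling : {"max", "none"}
    """

    def __init__(
        self,
        schedule: OperationSchedule = None,
        optics: OpticalGeometry = None,
        fixed_params: KineticParams = None,
        bounds: dict | None = None,
        seed: int = 0,
        optimizer_settings: dict | None = None,
        scaling: str = "max",
    ):
        self.schedule = schedule
        self.optics = optics
        self.fixed_params = fixed_params
        self.bounds = bounds
        self.seed = seed
        self.optimizer_settings = optimizer_settings
        self.scaling = scaling

    def _as_frame(self, X) -> pd.DataFrame:
        df = pd.DataFrame(X)
        if "time_d" not in df.columns or "variable" not in df.columns:
            raise ValueError("X must provide 'time_d' and 'variable' columns")
        return df

    def fit(self, X, y):
        for attr in ("schedule", "optics", "fixed_params"):
            if getattr(self, attr) is None:
                raise ValueError(f"{attr} must be set before fitting")
        df = self._as_frame(X).copy()
        df["value"] = np.asarray(y, dtype=float)
        dataset = ObservedDataset(
            data=df, schedule=self.schedule, optics=self.optics, name="X"
        )
        bounds = self.bounds
        if bounds is None:
            free = ["r_x_max", "k_n", "y_x_n"]
            if self.fixed_params.r_p_max > 0:
                free += ["r_p_max", "k_p", "k_pd"]
            bounds = default_bounds(self.fixed_params, free)
        self.result_ = fit(
            dataset,
            bounds=bounds,
            fixed_params=self.fixed_params,
            seed=self.seed,
            optimizer_settings=self.optimizer_settings,
            scaling=self.scaling,
        )
        self.params_ = self.result_.params
        self.optics_ = self.result_.optics
        self.objective_ = self.result_.objective
        self.r_squared_ = self.result_.r_squared
        self.n_features_in_ = df.shape[1] - 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        df = self._as_frame(X)
        times = np.unique(df["time_d"].to_numpy(dtype=float))
        traj = simulate(self.params_, self.optics_, self.schedule, output_times=times)
        out = np.empty(len(df))
        for v in df["variable"].unique():
            if v not in VARIABLES:
                raise ValueError(
                    f"unknown variable {v!r}; admissible names are {list(VARIABLES)}"
                )
            mask = (df["variable"] == v).to_numpy()
            out[mask] = traj.values_at(
                VARIABLE_COLUMNS[v], df.loc[mask, "time_d"].to_numpy(dtype=float)
            )
        return out

    def simulate(self, output_times=None) -> Trajectory:
        """Trajectory of the fitted model over the configured schedule."""
        check_is_fitted(self, "params_")
        return simulate(self.params_, self.optics_, self.schedule, output_times)
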