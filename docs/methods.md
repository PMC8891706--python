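# Methods

## Model

`mosskinetics` describes a moss (Physcomitrella) protonema suspension in
a stirred, homogeneously side-illuminated cylindrical photobioreactor as
a well-mixed, unstructured, non-segregated system with four macroscopic
state variables: biomass dry weight c_X (g/L), nitrate c_N (mg/L),
intracellular recombinant product c_P (mg/L) and working volume V (L).

Growth is co-limited by nitrate and light through the minimum law
(threshold model): each resource defines a Monod-type ceiling on the
specific growth rate and the smaller one applies. Nitrate uptake is
modelled Pirt-style — an uptake rate r_N with Monod kinetics and a yield
y_X,N coupling it to growth. The maximum uptake rate is not an
independent parameter; it is derived as r_N,max = r_X,max / y_X,N so
that the nitrate branch reproduces r_X,N = r_X,max·c_N/(c_N+k_N) and the
identity r_X = y_X,N·r_N holds in *both* regimes (in the light-limited
regime uptake is explicitly slaved to growth). That identity implies the
batch conservation law

    c_X(t) − c_X(0) = y_X,N · (c_N(0) − c_N(t)) · 10⁻³

(the factor bridging mg and g), which the integrator reproduces to
tolerance and the test suite asserts. Maintenance (non-growth) nitrate
uptake is zero. Product formation is Monod in nitrate (protein synthesis
needs the nitrogen source) and degradation is first order in c_P with a
biomass-proportional volumetric term. Temperature, pH and CO₂ are held
constant by the controller and are not modelled; phytohormone effects
are deliberately outside the model's scope.

## Light field

The vessel is an infinite cylinder (2-D cross-section); the wall is
uniformly illuminated from all sides and the top/bottom faces are
ignored. Light reaching an interior point at radius a along a chord at
angle θ is attenuated by Beer-Lambert absorption with coefficient
σ_X·c_X; scattering, wavelength resolution and photoinhibition dynamics
are not modelled. The angle-averaged local intensity and the
volume-averaged growth rate are

    Ī(a)  = (1/π) ∫₀^π I₀ exp(−σ_X c_X p(a,θ)) dθ
    r̄_X,I = (2/r_R²) ∫₀^{r_R} r_X,max · Ī(a)/(Ī(a)+k_I) · a da

with p(a,θ) = −a cos θ + √(r_R² − a² sin²θ). The Monod factor is applied
*locally* and then volume-averaged (rate-then-volume averaging), the
physically standard choice for a population spanning a strongly
non-uniform light field; by Jensen's inequality it yields a slightly
lower overall rate than averaging the intensity first.

Units: σ_X is m² per g DW and c_X is converted from g/L to g/m³
(×1000) before forming σ_X·c_X·p, which makes the published
cross-sections (0.02–0.05 m²/g) produce realistic attenuation — at
2 g DW/L and σ_X = 0.049 m²/g the axis intensity is ~0.07 µmol m⁻² s⁻¹
out of 350.

Numerics: 64-point trapezoid over θ (the integrand has vanishing
endpoint derivatives, so the rule superconverges — agreement with an
8193-point reference and with a 10⁶-ray stratified Monte-Carlo oracle is
at machine precision and well inside 0.1%), and 32-point Gauss-Legendre
over the radius with the cylindrical weight a. During parameter search
the volume-averaged Monod factor is tabulated on a 512-point biomass
grid per optics/intensity level and linearly interpolated (relative
error ~10⁻⁵); `simulate()` and all reported numbers use the exact
quadrature.

## Operating modes and events

Batch (D = 0, F = 0), fed-batch (D = F/V, volume grows, nothing
removed), and semi-continuous at constant volume in two equivalent
descriptions: a continuous dilution rate D (what the balance equations
state; the default for fitting) or discrete daily harvest-and-refill
events c → c(1−f), c_N → c_N(1−f) + f·c_N,fresh (what the laboratory
actually does). Removed biomass and product are accumulated in a harvest
ledger so the total product formed (in-vessel plus harvested) is
reportable. Daily replacement of 2 L (1 L) of a 5 L culture corresponds
to D = 0.4 (0.2) d⁻¹.

Integration is piecewise between schedule discontinuities (light steps,
feed starts, dilution changes, exchange events) with adaptive RK45 at
rtol 10⁻⁸ / atol 10⁻¹⁰ (10⁻⁶/10⁻⁸ inside the evolutionary search).
Trajectory values in [−10⁻⁹, 0) are clamped to zero; anything lower
raises. Outputs requested exactly at an event time report the
pre-exchange state (the sample is taken at harvest). When an exchange
and a light step coincide the exchange is applied first (arbitrary,
documented). Washout: with D > r_X,max the biomass declines towards
zero, as the simulator reproduces.

## Default scenario conditions

The built-in fixtures carry the published parameter columns (parental
batch; producer-line batch; producer-line semi-continuous, the latter
re-used for both D = 0.4 and D = 0.2 validation-style schedules) and the
corresponding schedules: 8-day 5 L batches; semi-continuous phases
starting day 6 (D = 0.4, to day 11) or day 7 (D = 0.2, to day 10);
fed-batch with 4 L batch phase to day 7 then 0.2 L/d of 5×-concentrated
medium (2500 mg NO₃⁻/L) to day 12. Initial conditions are
c_X = 0.1 g DW/L (typical inoculation density), c_N = 500 mg/L (the 1×
medium, one fifth of the measured 5× feed), c_P = 0. Incident light is
constant at 350 µmol m⁻² s⁻¹; the 160→350 start-up step used in some
runs is available through the piecewise light schedule. The parental
fixture zeroes all product kinetics and observes biomass and nitrate
only. Under these conditions the simulated batch reaches ~3.2 g DW/L by
day 8 and depletes nitrate shortly after (day ~8.9) — growth cessation
coincides with nitrate exhaustion, and biomass maxima across modes
(~3.6 batch, ~4.7 fed-batch, ~1.9 semi-continuous) match the reported
magnitudes.

## Synthetic data generator

`generate()` samples the exact trajectory at the campaign's times
(daily by default) and applies independent multiplicative Gaussian noise
value·(1 + CV·z) per replicate, truncated at zero; defaults are CV = 5%
and 2 replicates, mirroring duplicate dry-weight / reflectometric
nitrate / ELISA measurements. Everything is seeded (NumPy Generator;
replicates drawn variable by variable in a fixed order), so campaigns
are bit-reproducible. What the generator does *not* emulate: the late
drop in product concentration seen in real fed-batch runs when the
medium browns (the model has no mechanism for it — the corresponding
published fed-batch protein fit also failed, and no fed-batch parameter
column exists), pellet formation and the associated transfer
limitations, sampling-volume effects, or additive error floors near
zero. Passing recovery tests therefore demonstrate estimator correctness
under the model's own assumptions, not robustness to real-data model
error.

## Parameter estimation

The objective is the pooled sum of squared residuals between replicate
observations and the simulated trajectory at the observation times
(dense solver output, not interpolation between coarse steps). Because
the variables span orders of magnitude, residuals are divided per
dataset-variable by the maximum absolute observation before squaring;
the raw unweighted objective remains available (`scaling="none"`).
Integrator failure at a candidate returns a large finite penalty
(10¹²) instead of raising. Several datasets can be fitted jointly with
shared parameters.

Search: scipy differential evolution, best1bin, population 15 per free
dimension, tolerance 10⁻⁸, up to 500 generations, seeded and therefore
bit-reproducible; evaluated population-wise by stacking all candidates
into one ODE system (`vectorized`/deferred updating). A bounded
Nelder-Mead polish (gradient-free, consistent with the noisy adaptive
integration) refines the best member; the final objective and per-variable
R² are recomputed on the exact light path. Default recovery protocol
fixes the optics (σ_X and k_I) to avoid the σ_X/k_I confounding when
light never limits; default recovery bounds are a decade around the
reference value. Freeing σ_X switches to a per-candidate (non-stacked)
search path. Collapsed bounds pin a parameter.

Identifiability under the default campaign (daily sampling 0–8 d, 5%
CV): r_X,max, y_X,N and r_p,max are recovered to a few percent and k_pd
to roughly ±20–40%; k_N and k_p are effectively unidentifiable because
nitrate stays far above both half-saturation constants for almost the
whole window (growth is light-limited except in the final hours) — the
fit surface is a flat ridge along which k_p and r_p,max trade off, and
the box bounds act as the only regulariser. These two constants should
be reported with their bounds, not trusted; identifying them requires
sampling through the depletion transient. R² is undefined (reported as
missing, never 1) for a variable with zero variance across time points.

## Known limitations

Unstructured and non-segregated: no chloronema/caulonema composition,
no tissue-age effects, no phytohormone terms. No gas-phase balance, no
scattering or photoinhibition, reflective walls ignored. Fresh-weight
reporting requires a user-supplied FW:DW ratio (none is shipped).
Confidence intervals (profile likelihood, bootstrap) and model selection
are out of scope.
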