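# Methods

## Scope

`lignivis` implements the analysis chain behind in-line monitoring of lignin
methylolation (hydroxymethylation): a second-order kinetic model of the
formaldehyde–phenolic reaction, UV-based quantification of lignosulphonate
and phenolic hydroxyl content, and a PCA-based calibration that turns an
in-line visible-spectroscopy score into a phenolic-concentration predictor.
Because no instrument data are distributed, a first-class synthetic
generator reproduces the statistical structure of each input, and every
stage is validated in closed loop against it.

## Kinetic model

Methylolation is modelled as an elementary second-order reaction between
free formaldehyde F and the *reactive* part of the type I+II phenolic
hydroxyl pool:

    -d[F]/dt    = k1·[POH]_r·[F] + k2·[F]²
    -d[POH]_r/dt = k1·[POH]_r·[F]

with `[POH]_r(0) = [POH]₀·(1 − f_nonreactive)`. The non-reactive fraction
(blocked ring positions; predominantly syringyl units in hardwood
lignosulphonate) is chemically inert and constant, so the observable total
is `[POH] = [POH]_r + f_nonreactive·[POH]₀`. The `k2·[F]²` term lumps
formaldehyde-only side reactions (Cannizzaro-type self-disproportionation)
and is zero when formaldehyde and phenolic consumption balance.
Temperature is metadata: each parameter set belongs to one isothermal run
and no Arrhenius relation is fitted (the off-line assay delay makes
cross-temperature rate comparisons unreliable).

Units are mol/L and hours throughout; unit conversion happens only at the
I/O boundary.

### Solution and integration

With `k2 = 0` the model has the classical closed form for the extent
`x(t)` of A + B → C with unequal initial concentrations,

    x(t) = a·b·(e^{(a−b)k₁t} − 1) / (a·e^{(a−b)k₁t} − b),

written with `expm1` for small-argument accuracy and falling back to the
equal-concentration hyperbolic form `1/(b−x) − 1/b = k₁t` when
`|a − b| ≤ 10⁻¹²·max(a,b)`. With `k2 > 0` the coupled system is integrated
with LSODA at rtol 10⁻⁸ / atol 10⁻⁹; the closed form is always preferred
when available because it removes step-size risk. The t = 0 sample is the
initial condition itself, never an integrator output. Tests compare both
paths against an independent fixed-step Euler integration whose step
(5·10⁻⁶ h) keeps its own truncation error below the 10⁻⁶ mol/L agreement
tolerance.

### Parameter estimation

`fit_kinetics` minimises the joint unweighted sum of squared residuals of
the simulated versus observed F and POH series (per-series weights and a
single-series mode are exposed; both series are used by default because
both assays carry independent information about the extent). A fixed
multi-start grid (k1 ∈ {0.1, 0.5, 1, 2, 5}, k2 ∈ {0, 0.1},
f ∈ {0.5, 0.7, 0.9}) feeds a bounded trust-region least-squares solver;
the best SSE wins with ties broken by the smallest k1, so the estimate is
deterministic for given data. If the no-reaction model (k1 = 0) fits as
well as the optimum the rate is unidentifiable (flat data put the
optimizer on an SSE ridge along which the reactive pool vanishes); the
boundary solution is returned and flagged degenerate.

On noiseless hourly data the fit recovers generating parameters to three
or more decimals. With 0.005 mol/L Gaussian assay error on six hourly
points per series, the k1 estimate is unbiased with a relative standard
deviation near 0.11 — an information limit of the sampling design, not of
the optimizer; tests assert exactly this behaviour.

## UV quantification

Lignosulphonate content comes from plain Beer–Lambert inversion of the
absorbance at 232.5 nm (ε = 24.5 L g⁻¹ cm⁻¹) through a two-step dilution
scheme (default: 0.5 g to 1000 mL, 0.5 mL aliquot to 3.0 mL, 1 cm quartz
cuvette — the path length is the standard cuvette value).

Phenolic hydroxyls are typed by differential ionization spectroscopy:
alkaline-minus-reference (pH 6) absorbance, normalised by mass
concentration and path, gives a Δε spectrum with two maxima near 300 and
360 nm. Types I and II ionize at pH 12; the weakly acidic types III and IV
require 0.2 M NaOH, so the pH-12 difference encodes [OH]I+II and the NaOH
difference the total, with III+IV by subtraction (floored at zero with a
warning). Maxima are located by local quadratic interpolation of the grid
argmax within ±20 nm of the nominal centers. Contents are a linear
combination of the two maxima heights; the combination coefficients are a
required configuration object because no authoritative values ship with
the package — the defaults (0.250 and 0.425 % per L g⁻¹ cm⁻¹) are
implementation defaults of realistic magnitude, used identically by the
synthetic generator, so the quantification loop is self-consistent but the
absolute coefficient values carry no literature weight. The %→mol/L
conversion uses a per-hydroxyl formula mass of 17.007 g/mol.

## Chemometric monitoring

The in-line spectra matrix X (times × wavelengths) is restricted to
600–800 nm (the shorter-wavelength half of the 342–825 nm range is an
order of magnitude noisier), mean-centered per wavelength, and decomposed
by SVD into scores and orthonormal loadings (X = T·Pᵀ + E). Each loading
is oriented so its largest-magnitude entry is positive; the sign is
otherwise arbitrary and the downstream calibration is sign-invariant.
Three components are computed by default (the reaction, a spare for
drift, and one more).

Which component tracks the reaction depends on conditions, so it is chosen
automatically as the one (among the first three) whose score correlates
most strongly in absolute value with the modelled [POH] decay, with a
manual override. Acquisitions within a window around each sample
withdrawal (default 2 min after the event) are masked, and the first 15
min are excluded from the regression (the off-line reference is dominated
by analysis delay early on; both defaults configurable). The calibration
regresses modelled [POH] — the fitted kinetic model evaluated at every
retained acquisition time — on the selected score by ordinary least
squares, reporting slope, intercept and R²; regressing in this direction
makes the calibration directly predict concentration, and R² equals that
of the transposed regression for simple linear fits.

## Synthetic data

The generator is the package's study-conditions definition, not a test
dial.

* **In-line spectra** — Beer–Lambert mixtures of three latent Gaussian
  chromophore profiles: reactant-linked (driven by [POH], main band
  700 nm), product-linked (driven by extent x, main band 650 nm), and a
  weak medium-drift component (760 nm, 0.005 AU, driven by a sinusoid of
  period 8 h — non-monotone on purpose, so drift is distinguishable from
  the monotone reaction signal). No chemical assignment of the visible
  bands is claimed. On top: flat sinusoidal baseline wander (0.005 AU,
  8 h), iid noise with sd 0.002 AU above 600 nm and 0.02 AU below,
  and 0.05 AU spikes lasting 2 min at each hourly sampling event.
  Acquisition: two spectra per minute over 5 h on the 342–825 nm grid at
  0.24 nm (2013 points), or 2.4 nm in coarse mode for fast tests.
* **Off-line assays** — hourly [F] and [POH] samples re-simulated at
  t + delay (default 0.25 h — the assay takes at least 15 min and the
  reaction keeps running in the flask), plus iid Gaussian error
  (default 0.005 mol/L), clipped at 0.
* **Ionization spectra** — a pH-6/pH-12/NaOH triple whose alkaline-minus-
  reference differences are two-Gaussian curves (centers 300/360 nm on the
  0.5 nm grid, σ = 12 nm). Band amplitudes are solved from the 2×2
  inter-band overlap system so the maxima heights encode the target
  contents exactly, making the noise-free quantification round trip
  accurate to ~10⁻⁹.

All randomness derives from an explicit seed with per-stage substreams
(SeedSequence keyed on the stage name); identical seed and configuration
are bit-reproducible.

What the generator does **not** emulate: real chromophore spectra and
their temperature dependence, probe-geometry and radiative-transfer
effects, scattering from agglomerates, pH drift, heteroscedastic or
correlated assay error, and the true shape of withdrawal disturbances
(the rectangular 2-min spike is a documented placeholder). Passing tests
therefore demonstrate the correctness and self-consistency of the
analysis chain under the assumed data structure, not instrument-level
validity.

## Pipeline

`run_pipeline` executes simulate → fit-kinetics → monitor → calibrate from
a validated config (unknown keys rejected; explicit seed required), writes
every intermediate, and emits a self-describing JSON report (config echo,
package version, file digests). Because the simulated scenario declares
its off-line delay, the pipeline assigns each assay to its true delayed
time before fitting (`correct_offline_delay`, default on); without this
the fitted k1 is biased high by the delay — the same artefact that makes
real cross-temperature rate estimates unreliable.

Problem sizes used by the test suite and the acceptance script: coarse
202-point wavelength grid, 601 spectra, 6 off-line points, 100-replicate
noise studies — the chain's behaviour is scale-free in these dimensions,
and the fine grid is exercised by shape tests.

## Known limitations

* The ionization coefficients are closed-loop defaults; quantifying real
  spectra requires user-supplied, literature-calibrated coefficients.
* The kinetic model ignores Tollens/condensation chemistry beyond the
  single k2·[F]² term and assumes a fixed reactive/non-reactive partition.
* With hourly sampling, k1 carries ~11% relative uncertainty at
  0.005 mol/L assay noise; monitoring R² for feedstocks with a small
  reactive phenolic pool (hardwood at 50–60 °C) can fall below 0.95 even
  when the softwood scenario comfortably exceeds it.
* No partial-least-squares regression; the calibration is a single-score
  linear map.
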