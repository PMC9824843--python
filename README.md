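# lignivis

Kinetics and in-line visible-spectroscopy monitoring of lignin
methylolation (hydroxymethylation with formaldehyde).

Lignosulphonates — the dominant industrial lignin stream — need
methylolation with formaldehyde before they can replace phenol in
phenol–formaldehyde wood adhesives, but the reaction is conventionally
followed by slow, destructive off-line assays. `lignivis` implements the
full analysis chain for monitoring this reaction in-line with a visible
spectrometer probe:

* **kinetics** — a second-order kinetic model of the
  formaldehyde–phenolic reaction,
  `−d[F]/dt = k1·[POH]_r·[F] + k2·[F]²`, where only a fraction
  `1 − f_nonreactive` of the type I+II phenolic hydroxyls is available to
  react and `k2·[F]²` lumps formaldehyde-only side reactions; closed-form
  and ODE simulation, reaction extent `x = [F]₀ − [F]`, and deterministic
  multi-start least-squares estimation of (k1, k2, f) from off-line assay
  series.
* **phenolics** — UV quantification: lignosulphonate content from the
  absorbance at 232.5 nm (ε = 24.5 L g⁻¹ cm⁻¹, Beer–Lambert inversion
  through the dilution scheme), and phenolic hydroxyl typing from
  differential ionization spectra (pH 12 vs pH 6 for readily ionized
  types I+II, 0.2 M NaOH for the total).
* **chemometrics** — PCA of the mean-centered spectra matrix
  (X = T·Pᵀ + E), 600–800 nm region selection, masking of
  sample-withdrawal disturbances, automatic selection of the
  reaction-tracking component, and least-squares calibration of its score
  against the modelled [POH] decay with R².
* **synthetic** — seeded generators for every input: Beer–Lambert
  spectral mixtures with baseline drift, wavelength-dependent noise and
  sampling spikes; delayed, noisy hourly assays; ionization-spectra
  triples.
* **pipeline / CLI** — `lignivis run` executes
  simulate → fit-kinetics → monitor → calibrate reproducibly from a
  JSON/YAML config.

## Worked example

Run the softwood-lignosulphonate 60 °C scenario end to end:

```sh
echo '{"scenario": "SLS_60", "seed": 1}' > cfg.json
lignivis run cfg.json
```

prints (abridged):

```
{
  "k1": 1.5103390829079915,
  "k2": 0.0,
  "f_nonreactive": 0.7080122627458197,
  "sse": 0.0001888289476180952,
  "n_points": 6
}
{
  "component_index": 1,
  "slope": 0.10542143437455483,
  "intercept": 0.28119657699737927,
  "r_squared": 0.9764071475057743,
  "n_points": 550,
  "region_nm": [600.0, 800.0]
}
```

The first block is the kinetic fit to the six simulated hourly off-line
assays: the rate constant (L mol⁻¹ h⁻¹) and non-reactive phenolic
fraction land near the scenario's generating values (k1 = 1.53, f = 0.71);
the residual scatter reflects the 0.005 mol/L assay noise. The second
block is the in-line calibration: the first principal-component score of
the 600–800 nm spectra, after masking sampling spikes and the first
15 min, predicts [POH] (mol/L) as `slope·score + intercept` with
R² = 0.976 over 550 retained acquisitions — the in-line monitor tracks
the off-line chemistry.

The same stages are available programmatically:

```python
import numpy as np
from lignivis import simulate_trajectory, fit_kinetics
from lignivis.presets import SLS_60

traj = simulate_trajectory(SLS_60.params, SLS_60.init, np.linspace(0, 5, 301))
print(SLS_60.init.F0 - traj.F[-1])   # 0.1023 mol/L formaldehyde consumed in 5 h
```

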