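"""Synthetic spectro-kinetic data with the structure the analysis assumes.

Generates every input the monitoring pipeline consumes, so all stages are
testable without instrument data:

* in-line visible spectra as Beer-Lambert mixtures of latent chromophore
  profiles driven by the kinetic model, plus baseline drift,
  wavelength-dependent noise (elevated below 600 nm) and transient spikes
  at sample-withdrawal times;
* hourly off-line assay series of free formaldehyde and phenolic OH with
  measurement noise and an analysis delay during which the reaction keeps
  progressing;
* differential ionization UV spectra (pH 6 / pH 12 / 0.2 M NaOH) whose
  two-band difference maxima invert exactly through the quantification
  stage.

All randomness flows from explicit seeds; identical seed and configuration
give bit-identical output.

The latent chromophore model is deliberately neutral: one profile tied to
the unreacted phenolic species, one to the methylolated product, and one
slow autonomous drift standing in for medium changes.  No chemical
assignment of the visible bands is claimed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chemometrics import SpectraTimeSeries
from .kinetics import (
    InitialConditions,
    KineticParams,
    OfflineSeries,
    ReactionTrajectory,
    simulate_trajectory,
)
from .phenolics import (
    DEFAULT_COEFFICIENTS,
    IonizationCoefficients,
    PhenolicOHContent,
)

__all__ = [
    "GaussianBand",
    "Chromophore",
    "ChromophoreSet",
    "NoiseModel",
    "instrument_grid",
    "default_chromophores",
    "generate_inline_spectra",
    "generate_offline_series",
    "generate_ionization_spectra",
]

# Instrument wavelength range (nm) and native resolution of the in-line probe.
GRID_LO_NM = 342.0
GRID_HI_NM = 825.0
GRID_STEP_NM = 0.24
COARSE_STEP_NM = 2.4

# Default acquisition schedule: two spectra per minute for five hours.
DEFAULT_DURATION_H = 5.0
DEFAULT_RATE_PER_MIN = 2.0

# Period (h) of the autonomous drift driver in ChromophoreSet.
DRIFT_PERIOD_H = 8.0


def instrument_grid(coarse: bool = False) -> np.ndarray:
    """The probe's wavelength grid: 342-825 nm at 0.24 nm (or 2.4 nm) steps."""
    step = COARSE_STEP_NM if coarse else GRID_STEP_NM
    n = int(math.floor((GRID_HI_NM - GRID_LO_NM) / step)) + 1
    return GRID_LO_NM + step * np.arange(n)


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian absorption band: center (nm), width sigma (nm), amplitude."""

    center: float
    width: float
    amplitude: float

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        return self.amplitude * np.exp(
            -0.5 * ((wl - self.center) / self.width) ** 2
        )


@dataclass(frozen=True)
class Chromophore:
    """A latent spectral component and the process variable that drives it.

    ``driver`` selects the concentration time course: "poh" follows the
    total phenolic concentration, "extent" follows the reaction extent x,
    and "drift" follows a slow autonomous sinusoid (period
    ``DRIFT_PERIOD_H``, no kinetic meaning).  ``scale`` multiplies the
    driver.
    """

    bands: tuple[GaussianBand, ...]
    driver: str
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.driver not in ("poh", "extent", "drift"):
            raise ValueError(f"unknown driver {self.driver!r}")

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        out = np.zeros(len(wavelengths))
        for band in self.bands:
            out += band.profile(wavelengths)
        if np.any(out < 0):
            raise ValueError("chromophore extinction profile must be non-negative")
        return out


@dataclass(frozen=True)
class ChromophoreSet:
    components: tuple[Chromophore, ...]

    def concentrations(
        self, trajectory: ReactionTrajectory, duration: float
    ) -> np.ndarray:
        """Concentration drivers, shape (n_times, n_components)."""
        cols = []
        for c in self.components:
            if c.driver == "poh":
                cols.append(c.scale * trajectory.POH)
            elif c.driver == "extent":
                cols.append(c.scale * trajectory.x)
            else:  # drift: slow non-monotone wander, decoupled from kinetics
                cols.append(
                    c.scale
                    * np.sin(2.0 * np.pi * trajectory.times / DRIFT_PERIOD_H)
                )
        return np.column_stack(cols)


def default_chromophores() -> ChromophoreSet:
    """Neutral three-component latent model behind the visible spectra.

    A reactant-linked band near 700 nm, a product-linked band near 650 nm
    and a weak broad drift component; amplitudes give an absorbance swing
    of roughly 0.2 AU in the 600-800 nm window over a typical run, well
    above the 0.002 AU noise floor there.
    """
    return ChromophoreSet(
        components=(
            Chromophore(
                bands=(
                    GaussianBand(center=700.0, width=60.0, amplitude=2.0),
                    GaussianBand(center=450.0, width=50.0, amplitude=1.2),
                ),
                driver="poh",
            ),
            Chromophore(
                bands=(
                    GaussianBand(center=650.0, width=40.0, amplitude=1.5),
                    GaussianBand(center=500.0, width=60.0, amplitude=0.8),
                ),
                driver="extent",
            ),
            # medium drift of the same order as the baseline wander (AU)
            Chromophore(
                bands=(GaussianBand(center=760.0, width=100.0, amplitude=0.005),),
                driver="drift",
            ),
        )
    )


@dataclass(frozen=True)
class NoiseModel:
    """Measurement imperfections of the in-line probe and off-line assays.

    ``noise_sd_above_600`` / ``noise_sd_below_600`` — iid absorbance noise
    (AU); the short-wavelength half of the visible range is an order of
    magnitude noisier.  ``drift_amplitude`` / ``drift_period_h`` — slow
    sinusoidal baseline wander (AU).  ``spike_amplitude`` /
    ``spike_duration_min`` — transient absorbance offset while a sample is
    withdrawn.  ``offline_sd`` — iid error of the off-line assays (mol/L).
    ``offline_delay_h`` — time between withdrawal and quench during which
    the reaction keeps running (at least 15 min in practice).
    """

    noise_sd_above_600: float = 0.002
    noise_sd_below_600: float = 0.02
    drift_amplitude: float = 0.005
    drift_period_h: float = 8.0
    spike_amplitude: float = 0.05
    spike_duration_min: float = 2.0
    offline_sd: float = 0.005
    offline_delay_h: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "noise_sd_above_600",
            "noise_sd_below_600",
            "drift_amplitude",
            "spike_amplitude",
            "offline_sd",
            "offline_delay_h",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def quiet(self) -> "NoiseModel":
        """A copy with every imperfection switched off (delay included)."""
        return NoiseModel(
            noise_sd_above_600=0.0,
            noise_sd_below_600=0.0,
            drift_amplitude=0.0,
            spike_amplitude=0.0,
            offline_sd=0.0,
            offline_delay_h=0.0,
            seed=self.seed,
        )


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Independent substream per generator stage, derived from one seed."""
    ss = np.random.SeedSequence([seed, int.from_bytes(stream.encode(), "big")])
    return np.random.default_rng(ss)


def generate_inline_spectra(
    params: KineticParams,
    init: InitialConditions,
    chromophores: ChromophoreSet | None = None,
    noise: NoiseModel | None = None,
    duration_h: float = DEFAULT_DURATION_H,
    rate_per_min: float = DEFAULT_RATE_PER_MIN,
    coarse: bool = False,
    sampling_events: np.ndarray | None = None,
) -> SpectraTimeSeries:
    """Simulate the in-line visible spectra of one methylolation run.

    Absorbance is the Beer-Lambert mixture of the chromophore profiles
    weighted by their kinetic concentration drivers, plus baseline drift,
    withdrawal spikes at the sampling events (hourly by default) and iid
    noise with the wavelength-dependent standard deviation of the noise
    model.  The default schedule acquires two spectra per minute for five
    hours (601 spectra including t = 0).
    """
    if chromophores is None:
        chromophores = default_chromophores()
    if noise is None:
        noise = NoiseModel()
    wl = instrument_grid(coarse=coarse)
    n_times = int(round(duration_h * 60.0 * rate_per_min)) + 1
    times = np.linspace(0.0, duration_h, n_times)
    if sampling_events is None:
        sampling_events = np.arange(1.0, math.floor(duration_h) + 0.5, 1.0)
    sampling_events = np.asarray(sampling_events, dtype=float)

    traj = simulate_trajectory(params, init, times)
    conc = chromophores.concentrations(traj, duration_h)  # (n_times, n_comp)
    profiles = np.stack(
        [c.profile(wl) for c in chromophores.components]
    )  # (n_comp, n_wl)
    A = conc @ profiles

    if noise.drift_amplitude > 0:
        A += noise.drift_amplitude * np.sin(
            2.0 * np.pi * times / noise.drift_period_h
        )[:, None]

    if noise.spike_amplitude > 0 and len(sampling_events):
        spike_h = noise.spike_duration_min / 60.0
        in_spike = np.zeros(n_times, dtype=bool)
        for ev in sampling_events:
            in_spike |= (times >= ev) & (times <= ev + spike_h)
        A[in_spike] += noise.spike_amplitude

    if noise.noise_sd_above_600 > 0 or noise.noise_sd_below_600 > 0:
        rng = _rng(noise.seed, "inline")
        sd = np.where(wl < 600.0, noise.noise_sd_below_600, noise.noise_sd_above_600)
        A = A + rng.standard_normal(A.shape) * sd

    return SpectraTimeSeries(
        times=times,
        wavelengths=wl,
        absorbance=A,
        sampling_events=sampling_events,
    )


def generate_offline_series(
    trajectory: ReactionTrajectory,
    interval_h: float = 1.0,
    noise: NoiseModel | None = None,
) -> OfflineSeries:
    """Emulate the hourly off-line assays of [F] and [POH].

    A sample nominally taken at t is only quenched and measured after the
    analysis delay, during which the reaction continues in the flask: the
    reported value is the true concentration at ``t + delay`` plus iid
    Gaussian error, clipped at 0.  Concentrations at the delayed times are
    re-simulated exactly from the trajectory's own parameters rather than
    interpolated.
    """
    if noise is None:
        noise = NoiseModel()
    t_nominal = np.arange(0.0, trajectory.times[-1] + 1e-9, interval_h)
    t_actual = t_nominal + noise.offline_delay_h
    sim_times = np.unique(np.concatenate([[0.0], t_actual]))
    traj = simulate_trajectory(trajectory.params, trajectory.init, sim_times)
    ix = np.searchsorted(sim_times, t_actual)
    F = traj.F[ix].copy()
    POH = traj.POH[ix].copy()
    if noise.offline_sd > 0:
        rng = _rng(noise.seed, "offline")
        F = F + rng.standard_normal(len(F)) * noise.offline_sd
        POH = POH + rng.standard_normal(len(POH)) * noise.offline_sd
    return OfflineSeries(
        times=t_nominal, F=np.clip(F, 0.0, None), POH=np.clip(POH, 0.0, None)
    )


# Ionization-spectra geometry: 190-400 nm grid with both band centers on
# grid points, narrow bands so the 300/360 cross-talk is ~4e-6 relative.
ION_GRID_STEP_NM = 0.5
ION_BAND_WIDTH_NM = 12.0
ION_BAND_RATIO = 0.6  # height of the 360 nm band relative to the 300 nm band


def _ionization_heights(
    content_pct: float, coefficients: IonizationCoefficients
) -> tuple[float, float]:
    """Band heights (L g^-1 cm^-1) encoding a given OH content.

    Splits the content across the two bands at the fixed height ratio so
    that ``a300*h300 + a360*h360`` returns the content exactly.
    """
    denom = coefficients.a300 + coefficients.a360 * ION_BAND_RATIO
    h300 = content_pct / denom
    return h300, ION_BAND_RATIO * h300


def generate_ionization_spectra(
    content: PhenolicOHContent,
    coefficients: IonizationCoefficients = DEFAULT_COEFFICIENTS,
    mass_conc: float = 0.08,
    path: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """UV spectra triple (pH6 reference, pH12, 0.2 M NaOH) on 190-400 nm.

    The alkaline-minus-reference difference is a two-Gaussian curve with
    maxima at 300 and 360 nm whose heights encode the phenolic contents
    through the coefficient set: the pH-12 spectrum encodes the type I+II
    content, the NaOH spectrum the total.  Band amplitudes are solved from
    the (tiny) inter-band overlap so the maxima heights are exact, making
    the quantification round trip close to machine precision at zero noise.

    Returns ``(wavelengths, {"pH6": A, "pH12": A, "NaOH02M": A})`` in
    absorbance units for the given mass concentration (g/L) and path (cm).
    """
    n = int(round((400.0 - 190.0) / ION_GRID_STEP_NM)) + 1
    wl = 190.0 + ION_GRID_STEP_NM * np.arange(n)

    g300 = np.exp(-0.5 * ((wl - 300.0) / ION_BAND_WIDTH_NM) ** 2)
    g360 = np.exp(-0.5 * ((wl - 360.0) / ION_BAND_WIDTH_NM) ** 2)
    cross = math.exp(-0.5 * (60.0 / ION_BAND_WIDTH_NM) ** 2)

    def difference(content_pct: float) -> np.ndarray:
        h300, h360 = _ionization_heights(content_pct, coefficients)
        # amplitudes such that the summed curve hits h300/h360 at the centers
        det = 1.0 - cross * cross
        a300 = (h300 - cross * h360) / det
        a360 = (h360 - cross * h300) / det
        return a300 * g300 + a360 * g360

    # Non-ionizing background common to all three solutions: aromatic tail
    # decaying into the near-UV.  It cancels in the difference.
    background = 5.0 * np.exp(-(wl - 190.0) / 45.0) * mass_conc * path

    spectra = {
        "pH6": background.copy(),
        "pH12": background + difference(content.oh_I_II) * mass_conc * path,
        "NaOH02M": background + difference(content.oh_total) * mass_conc * path,
    }
    if noise_sd > 0:
        rng = _rng(seed, "ionization")
        for key in spectra:
            spectra[key] = spectra[key] + rng.standard_normal(n) * noise_sd
    return wl, spectra
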