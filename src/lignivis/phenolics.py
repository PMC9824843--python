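"""UV quantification of lignosulphonate and phenolic hydroxyl content.

Two assays are implemented:

* Lignosulphonate (LS) content from the absorbance at 232.5 nm of a doubly
  diluted aqueous solution, using an extinction coefficient of
  24.5 L g^-1 cm^-1 and plain Beer-Lambert inversion through the dilution
  scheme.

* Phenolic hydroxyl typing by differential ionization UV spectroscopy.
  Phenolic OH groups ionize to phenolates with a red-shifted absorption,
  producing difference spectra (alkaline minus pH-6 reference) with two
  maxima near 300 and 360 nm.  Readily ionized groups (types I and II)
  respond already at pH 12; the weakly acidic types III and IV require
  0.2 M NaOH.  Contents are obtained as a linear combination of the two
  difference-maximum absorptivities; the combination coefficients are a
  configuration object (see :class:`IonizationCoefficients`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DilutionScheme",
    "IonizationSpectrum",
    "IonizationCoefficients",
    "PhenolicOHContent",
    "DEFAULT_COEFFICIENTS",
    "HLS_DILUTION_SCHEME",
    "OH_FORMULA_MASS",
    "ls_content_from_absorbance",
    "ionization_difference",
    "phenolic_oh_content",
    "offline_poh_sample",
]

# Formula mass of one hydroxyl group, g/mol; converts a mass-percent OH
# content into molar phenolic concentration.
OH_FORMULA_MASS = 17.007

# Extinction coefficient of lignosulphonate at 232.5 nm, L g^-1 cm^-1.
LS_EPSILON_232 = 24.5


@dataclass(frozen=True)
class DilutionScheme:
    """Two-step dilution from weighed sample to cuvette.

    ``sample_mass`` g dissolved to ``primary_volume`` L; ``aliquot_volume`` L
    of that solution diluted to ``final_volume`` L in the cuvette of
    ``path_length`` cm.
    """

    sample_mass: float
    primary_volume: float
    aliquot_volume: float
    final_volume: float
    path_length: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "sample_mass",
            "primary_volume",
            "aliquot_volume",
            "final_volume",
            "path_length",
        ):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        if self.aliquot_volume > self.final_volume:
            raise ValueError("aliquot_volume must not exceed final_volume")

    @property
    def dilution_factor(self) -> float:
        return self.final_volume / self.aliquot_volume


# 0.5 g sample to 1000 mL, then 0.5 mL aliquot diluted to 3.0 mL, 1 cm cuvette.
HLS_DILUTION_SCHEME = DilutionScheme(
    sample_mass=0.5,
    primary_volume=1.0,
    aliquot_volume=0.5e-3,
    final_volume=3.0e-3,
    path_length=1.0,
)


@dataclass(frozen=True)
class IonizationSpectrum:
    """Differential absorptivity spectrum: alkaline minus pH-6 reference.

    ``delta_absorptivity`` is per unit mass concentration and path length,
    L g^-1 cm^-1, on the 190-400 nm grid.  ``maxima`` maps the nominal band
    positions (300, 360) to refined (wavelength, height) pairs, or None
    when no maximum was detectable within the search window.
    """

    wavelengths: np.ndarray
    delta_absorptivity: np.ndarray
    maxima: dict[float, tuple[float, float] | None]

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl[0] < 190 - 1e-9 or wl[-1] > 400 + 1e-9:
            raise ValueError("ionization spectra live on 190-400 nm")
        if not np.all(np.isfinite(self.delta_absorptivity)):
            raise ValueError("delta_absorptivity must be finite")


@dataclass(frozen=True)
class PhenolicOHContent:
    """Phenolic hydroxyl contents as mass % on a dry-LS basis."""

    oh_I_II: float
    oh_III_IV: float

    def __post_init__(self) -> None:
        if self.oh_I_II < 0 or self.oh_III_IV < 0:
            raise ValueError("phenolic contents must be non-negative")

    @property
    def oh_total(self) -> float:
        return self.oh_I_II + self.oh_III_IV


@dataclass(frozen=True)
class IonizationCoefficients:
    """Linear map from difference-maximum absorptivities to OH content.

    A content in mass % is ``a300 * deps300 + a360 * deps360`` where
    ``deps300``/``deps360`` are the heights (L g^-1 cm^-1) of the two
    ionization-difference maxima.  The pH-12 spectrum yields the type I+II
    content, the 0.2 M NaOH spectrum the total content.

    The shipped :data:`DEFAULT_COEFFICIENTS` are implementation defaults
    chosen to be of a realistic order of magnitude for lignosulphonates;
    they are used consistently by the synthetic generator and the
    quantifier, so the quantification loop is self-consistent but the
    absolute values carry no literature authority.
    """

    a300: float
    a360: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a300) and math.isfinite(self.a360)):
            raise ValueError("coefficients must be finite")

    def content_from_maxima(self, deps300: float, deps360: float) -> float:
        return self.a300 * deps300 + self.a360 * deps360


DEFAULT_COEFFICIENTS = IonizationCoefficients(a300=0.250, a360=0.425)


def ls_content_from_absorbance(
    A232: float,
    scheme: DilutionScheme,
    epsilon: float = LS_EPSILON_232,
) -> float:
    """Lignosulphonate content (mass %) from the absorbance at 232.5 nm.

    Beer-Lambert gives the cuvette concentration ``A / (epsilon * l)``;
    multiplying back through the aliquot dilution and the primary volume
    yields the LS mass in the weighed sample, reported as a percentage.
    """
    if A232 < 0:
        raise ValueError(f"absorbance must be >= 0, got {A232}")
    if not (math.isfinite(epsilon) and epsilon > 0):
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    conc_cuvette = A232 / (epsilon * scheme.path_length)  # g/L
    conc_primary = conc_cuvette * scheme.dilution_factor
    ls_mass = conc_primary * scheme.primary_volume
    return 100.0 * ls_mass / scheme.sample_mass


def _refine_maximum(
    wl: np.ndarray, y: np.ndarray, center: float, window: float = 20.0
) -> tuple[float, float] | None:
    """Locate a local maximum near ``center`` by quadratic interpolation.

    Searches the grid argmax within +/- ``window`` nm of ``center`` and fits
    a parabola through it and its neighbours.  Returns None when the argmax
    sits on the window edge with no interior peak (no detectable maximum) or
    the spectrum is flat there.
    """
    sel = np.flatnonzero(np.abs(wl - center) <= window)
    if len(sel) < 3:
        return None
    ys = y[sel]
    k = int(np.argmax(ys))
    if k == 0 or k == len(sel) - 1:
        return None
    i = sel[k]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not locally concave: flat or noise-dominated
        return None
    delta = 0.5 * (y0 - y2) / denom
    step = wl[i + 1] - wl[i]
    peak_wl = wl[i] + delta * step
    peak_h = y1 - 0.25 * (y0 - y2) * delta
    return float(peak_wl), float(peak_h)


def ionization_difference(
    alkaline: np.ndarray,
    reference_pH6: np.ndarray,
    wavelengths: np.ndarray,
    mass_conc: float,
    path: float = 1.0,
) -> IonizationSpectrum:
    """Differential absorptivity spectrum and its two band maxima.

    Subtracts the pH-6 reference absorbance from the alkaline absorbance
    pointwise and normalises by mass concentration (g/L) and path length
    (cm).  Any absorbance common to both solutions (non-ionizing
    chromophores, baseline) cancels.  The maxima nearest 300 and 360 nm are
    located by local quadratic interpolation; an undetectable maximum is
    recorded as None and flagged with a warning.
    """
    wl = np.asarray(wavelengths, dtype=float)
    alk = np.asarray(alkaline, dtype=float)
    ref = np.asarray(reference_pH6, dtype=float)
    if alk.shape != wl.shape or ref.shape != wl.shape:
        raise ValueError("alkaline, reference and wavelength grids must match")
    if not (math.isfinite(mass_conc) and mass_conc > 0):
        raise ValueError(f"mass_conc must be positive, got {mass_conc}")
    if path <= 0:
        raise ValueError(f"path must be positive, got {path}")

    deps = (alk - ref) / (mass_conc * path)
    maxima: dict[float, tuple[float, float] | None] = {}
    for center in (300.0, 360.0):
        m = _refine_maximum(wl, deps, center)
        if m is None:
            warnings.warn(
                f"no detectable ionization maximum within 20 nm of {center:g} nm",
                stacklevel=2,
            )
        maxima[center] = m
    return IonizationSpectrum(wavelengths=wl, delta_absorptivity=deps, maxima=maxima)


def phenolic_oh_content(
    delta_eps_300_pH12: float,
    delta_eps_360_pH12: float,
    delta_eps_300_NaOH: float,
    delta_eps_360_NaOH: float,
    coefficients: IonizationCoefficients = DEFAULT_COEFFICIENTS,
) -> PhenolicOHContent:
    """Phenolic hydroxyl contents from the four difference-maximum heights.

    The pH-12 maxima yield the readily ionized type I+II content; the
    0.2 M NaOH maxima yield the total content; types III+IV follow by
    difference, floored at 0 with a warning if the difference is negative.
    """
    if coefficients is None:
        raise ValueError("an IonizationCoefficients set is required")
    oh_I_II = coefficients.content_from_maxima(delta_eps_300_pH12, delta_eps_360_pH12)
    oh_total = coefficients.content_from_maxima(delta_eps_300_NaOH, delta_eps_360_NaOH)
    oh_III_IV = oh_total - oh_I_II
    if oh_III_IV < 0:
        warnings.warn(
            f"total OH content ({oh_total:.4g}) below type I+II content "
            f"({oh_I_II:.4g}); flooring III+IV at 0",
            stacklevel=2,
        )
        oh_III_IV = 0.0
    oh_I_II = max(oh_I_II, 0.0)
    return PhenolicOHContent(oh_I_II=oh_I_II, oh_III_IV=oh_III_IV)


def offline_poh_sample(
    reaction_mass: float,
    flask_volume: float,
    measured: PhenolicOHContent,
    ls_conc_in_medium: float,
) -> float:
    """Reaction-medium [POH] (mol/L) from an off-line hourly assay.

    An hourly sample of ``reaction_mass`` g of reaction medium diluted to
    ``flask_volume`` L is assayed for type I+II phenolic content (mass % on
    LS).  Because the content is expressed per LS mass, the medium molar
    concentration needs only the LS concentration in the medium (g/L) and a
    per-hydroxyl formula mass of 17.007 g/mol; the sampling masses and
    volumes are validated for interface completeness.
    """
    for name, v in (
        ("reaction_mass", reaction_mass),
        ("flask_volume", flask_volume),
        ("ls_conc_in_medium", ls_conc_in_medium),
    ):
        if not (math.isfinite(v) and v > 0):
            raise ValueError(f"{name} must be positive and finite, got {v!r}")
    return ls_conc_in_medium * (measured.oh_I_II / 100.0) / OH_FORMULA_MASS
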