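"""PCA-based in-line monitoring of the methylolation reaction.

The in-line visible spectra form a data matrix X (times x wavelengths).
After restriction to a low-noise spectral region (600-800 nm by default) and
mean-centering, X is decomposed as X = T P^T + E (scores T, orthonormal
loadings P).  One principal component tracks the reaction: its score series
is selected by correlation with the modelled phenolic decay and calibrated
against it by ordinary least squares, giving an in-line predictor of [POH]
with an R-squared quality figure.  Momentary disturbances caused by sample
withdrawal, and an initial window where the off-line reference is
unreliable, are excluded from the calibration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .kinetics import ReactionTrajectory

__all__ = [
    "SpectraTimeSeries",
    "PCAModel",
    "MonitoringCalibration",
    "select_region",
    "mean_center",
    "fit_pca",
    "mask_disturbances",
    "select_monitoring_pc",
    "calibrate_scores",
    "predict_poh",
]


@dataclass(frozen=True)
class SpectraTimeSeries:
    """Absorbance matrix over acquisition times (h) and a wavelength grid (nm)."""

    times: np.ndarray
    wavelengths: np.ndarray
    absorbance: np.ndarray
    sampling_events: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        wl = np.asarray(self.wavelengths, dtype=float)
        A = np.asarray(self.absorbance, dtype=float)
        if A.shape != (len(t), len(wl)):
            raise ValueError(
                f"absorbance shape {A.shape} does not match "
                f"{len(t)} times x {len(wl)} wavelengths"
            )
        if len(t) and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValueError("times must be strictly increasing and start >= 0")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(A)):
            raise ValueError("absorbance must be finite")

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def n_wavelengths(self) -> int:
        return len(self.wavelengths)


@dataclass(frozen=True)
class PCAModel:
    """Principal-component model of a mean-centered spectra matrix.

    ``loadings`` has orthonormal columns (one per component), ``scores`` are
    the projections of the centered spectra, and
    ``explained_variance_fraction`` gives each component's share of the
    total centered variance.  Components are ordered by decreasing
    variance; each loading is oriented so its largest-magnitude entry is
    positive (the sign is otherwise arbitrary).
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Mean + scores @ loadings.T: the rank-n_components approximation."""
        return self.mean_spectrum + self.scores @ self.loadings.T


@dataclass(frozen=True)
class MonitoringCalibration:
    """Linear map from a PC score to [POH] (mol/L) with quality diagnostics."""

    component_index: int  # 1-based
    slope: float
    intercept: float
    r_squared: float
    excluded_initial_window: float
    n_points: int
    region: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "component_index": self.component_index,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "excluded_initial_window_h": self.excluded_initial_window,
            "n_points": self.n_points,
            "region_nm": list(self.region) if self.region else None,
        }


def select_region(
    spectra: SpectraTimeSeries, lo: float = 600.0, hi: float = 800.0
) -> SpectraTimeSeries:
    """Restrict the series to wavelengths in [lo, hi] nm (inclusive).

    The default 600-800 nm window keeps the low-noise part of the visible
    range; shorter wavelengths carry most of the measurement noise.
    """
    if lo >= hi:
        raise ValueError(f"need lo < hi, got ({lo}, {hi})")
    keep = (spectra.wavelengths >= lo) & (spectra.wavelengths <= hi)
    if not keep.any():
        raise ValueError(
            f"region [{lo}, {hi}] nm does not overlap the grid "
            f"[{spectra.wavelengths[0]}, {spectra.wavelengths[-1]}]"
        )
    return SpectraTimeSeries(
        times=spectra.times,
        wavelengths=spectra.wavelengths[keep],
        absorbance=spectra.absorbance[:, keep],
        sampling_events=spectra.sampling_events,
    )


def mean_center(spectra: SpectraTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Subtract each wavelength's time-average; returns (centered, mean)."""
    A = spectra.absorbance
    if A.shape[0] < 2:
        raise ValueError("mean-centering needs at least 2 spectra")
    mean = A.mean(axis=0)
    return A - mean, mean


def fit_pca(
    centered: np.ndarray,
    n_components: int = 3,
    mean_spectrum: np.ndarray | None = None,
) -> PCAModel:
    """Principal components of a mean-centered matrix by SVD.

    Zero-variance trailing components of rank-deficient input are kept with
    zero scores and flagged with a warning.
    """
    centered = np.asarray(centered, dtype=float)
    n, p = centered.shape
    if n_components > min(n, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_times, n_wavelengths)="
            f"{min(n, p)}"
        )
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    rank_tol = s[0] * max(n, p) * np.finfo(float).eps if s.size else 0.0
    if np.count_nonzero(s > rank_tol) < n_components:
        warnings.warn(
            "input is rank-deficient: trailing components have zero variance",
            stacklevel=2,
        )
    loadings = Vt[:n_components].T
    scores = U[:, :n_components] * s[:n_components]
    # orient each loading so its largest-magnitude entry is positive
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
            scores[:, k] = -scores[:, k]
    total_var = float(np.sum(s**2))
    ev = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    if mean_spectrum is None:
        mean_spectrum = np.zeros(p)
    return PCAModel(
        mean_spectrum=np.asarray(mean_spectrum, dtype=float),
        loadings=loadings,
        scores=scores,
        explained_variance_fraction=ev,
    )


def mask_disturbances(
    spectra: SpectraTimeSeries,
    sampling_events: np.ndarray | None = None,
    pre_window_min: float = 0.0,
    post_window_min: float = 2.0,
) -> np.ndarray:
    """Boolean mask over acquisition times; True = retained.

    Sample withdrawal from the reactor disturbs the probe for a short time,
    so acquisitions within [event - pre, event + post] are excluded.
    Overlapping windows merge naturally.
    """
    if pre_window_min < 0 or post_window_min < 0:
        raise ValueError("exclusion windows must be >= 0")
    if sampling_events is None:
        sampling_events = spectra.sampling_events
    mask = np.ones(spectra.n_times, dtype=bool)
    if sampling_events is None:
        return mask
    pre_h = pre_window_min / 60.0
    post_h = post_window_min / 60.0
    t = spectra.times
    for ev in np.atleast_1d(np.asarray(sampling_events, dtype=float)):
        mask &= ~((t >= ev - pre_h) & (t <= ev + post_h))
    return mask


def _interp_reference(
    reference: ReactionTrajectory, times: np.ndarray
) -> np.ndarray:
    return reference.poh_at(times)


def select_monitoring_pc(
    model: PCAModel,
    reference: ReactionTrajectory,
    times: np.ndarray,
    mask: np.ndarray | None = None,
    n_candidates: int = 3,
    override: int | None = None,
) -> int:
    """Index (1-based) of the component tracking the reaction.

    Among the first ``n_candidates`` components, returns the one whose score
    series correlates most strongly (in absolute value) with the modelled
    [POH] decay interpolated onto the retained acquisition times.  Which
    component carries the reaction varies with conditions (drift can claim
    the first), hence the data-driven rule; ``override`` forces a manual
    choice.
    """
    if override is not None:
        if not 1 <= override <= model.n_components:
            raise ValueError(f"override {override} outside 1..{model.n_components}")
        return override
    if mask is None:
        mask = np.ones(len(times), dtype=bool)
    t_ret = np.asarray(times, dtype=float)[mask]
    if len(t_ret) < 3:
        raise ValueError("need at least 3 retained time points")
    ref = _interp_reference(reference, t_ret)
    if np.std(ref) <= 1e-12 * max(1.0, float(np.abs(ref).max())):
        raise ValueError("reference [POH] is constant: correlation undefined")
    n_candidates = min(n_candidates, model.n_components)
    best_idx, best_corr = 1, -1.0
    for k in range(n_candidates):
        score = model.scores[mask, k]
        if np.std(score) == 0:
            continue
        c = abs(float(np.corrcoef(score, ref)[0, 1]))
        if c > best_corr + 1e-12:
            best_idx, best_corr = k + 1, c
    return best_idx


def calibrate_scores(
    model: PCAModel,
    component: int,
    reference: ReactionTrajectory,
    times: np.ndarray,
    excluded_initial_window: float = 0.25,
    mask: np.ndarray | None = None,
    region: tuple[float, float] | None = None,
) -> MonitoringCalibration:
    """Least-squares calibration of a PC score against the modelled [POH].

    Regresses the reference [POH] (interpolated from the kinetic model onto
    the retained acquisition times) on the selected component's score,
    after dropping the initial window (default 15 min, where the off-line
    reference is dominated by analysis delay) and any disturbance-masked
    times.  Returns slope, intercept and R^2 = 1 - SS_res/SS_tot.
    """
    times = np.asarray(times, dtype=float)
    if mask is None:
        mask = np.ones(len(times), dtype=bool)
    keep = mask & (times >= excluded_initial_window)
    if np.count_nonzero(keep) < 3:
        raise ValueError("need at least 3 retained points after exclusions")
    if not 1 <= component <= model.n_components:
        raise ValueError(f"component {component} outside 1..{model.n_components}")

    score = model.scores[keep, component - 1]
    ref = _interp_reference(reference, times[keep])
    if np.std(score) == 0:
        raise ValueError("selected score is constant: calibration degenerate")

    slope, intercept = np.polyfit(score, ref, 1)
    fitted = slope * score + intercept
    ss_res = float(np.sum((ref - fitted) ** 2))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return MonitoringCalibration(
        component_index=component,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        excluded_initial_window=excluded_initial_window,
        n_points=int(np.count_nonzero(keep)),
        region=region,
    )


def predict_poh(
    calibration: MonitoringCalibration, score: np.ndarray | float
) -> np.ndarray | float:
    """In-line [POH] prediction (mol/L) from a score value; clipped at 0."""
    pred = calibration.slope * np.asarray(score, dtype=float) + calibration.intercept
    if np.any(pred < 0):
        warnings.warn("predicted [POH] below 0 clipped", stacklevel=2)
        pred = np.clip(pred, 0.0, None)
    if np.ndim(score) == 0:
        return float(pred)
    return pred
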