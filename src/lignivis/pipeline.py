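"""End-to-end orchestration: simulate -> fit kinetics -> monitor -> calibrate.

A :class:`RunConfig` names a study scenario (one of the preset
lignosulphonate runs or fully custom parameters), the spectral region,
exclusion windows, noise model and seed.  :func:`run_pipeline` executes the
stages in order, writes every intermediate to the output directory and
returns a :class:`RunReport` that echoes the configuration, so a completed
run can be re-executed and re-validated from its report alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .chemometrics import (
    MonitoringCalibration,
    calibrate_scores,
    fit_pca,
    mask_disturbances,
    mean_center,
    select_monitoring_pc,
    select_region,
)
from .io import write_calibration_json, write_fit_json, write_offline, write_spectra
from .kinetics import (
    FitResult,
    InitialConditions,
    KineticParams,
    fit_kinetics,
    simulate_trajectory,
)
from .presets import HLS_50, HLS_60, SLS_60, StudyConditions
from .synthetic import (
    NoiseModel,
    generate_inline_spectra,
    generate_offline_series,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "SCENARIOS"]

logger = logging.getLogger("lignivis")

SCENARIOS: dict[str, StudyConditions] = {
    "SLS_60": SLS_60,
    "HLS_50": HLS_50,
    "HLS_60": HLS_60,
}

_KNOWN_KEYS = {
    "scenario",
    "seed",
    "duration_h",
    "region_nm",
    "excluded_initial_window_h",
    "spike_window_min",
    "coarse_grid",
    "noise",
    "fit_model",
    "fit_use_series",
    "correct_offline_delay",
    "output_dir",
    "params",
    "init",
}

_KNOWN_NOISE_KEYS = {
    "noise_sd_above_600",
    "noise_sd_below_600",
    "drift_amplitude",
    "drift_period_h",
    "spike_amplitude",
    "spike_duration_min",
    "offline_sd",
    "offline_delay_h",
}


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    scenario: str
    seed: int
    duration_h: float = 5.0
    region_nm: tuple[float, float] = (600.0, 800.0)
    excluded_initial_window_h: float = 0.25
    spike_window_min: float = 2.0
    coarse_grid: bool = True
    noise: dict = field(default_factory=dict)
    fit_model: str | None = None  # default: secondary term iff scenario has k2>0
    fit_use_series: str = "both"
    # assign each off-line measurement to its true (delayed) time before
    # fitting; the analysis delay is part of the declared scenario
    correct_offline_delay: bool = True
    output_dir: str | None = None
    params: dict | None = None  # custom scenario: KineticParams fields
    init: dict | None = None  # custom scenario: InitialConditions fields

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in d:
            raise ConfigError("config must set an explicit seed")
        if "scenario" not in d:
            raise ConfigError("config must name a scenario")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.scenario not in SCENARIOS and self.scenario != "custom":
            raise ConfigError(
                f"unknown scenario {self.scenario!r}; "
                f"choose from {sorted(SCENARIOS)} or 'custom'"
            )
        if self.scenario == "custom" and (self.params is None or self.init is None):
            raise ConfigError("custom scenario requires 'params' and 'init'")
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")
        unknown = set(self.noise) - _KNOWN_NOISE_KEYS
        if unknown:
            raise ConfigError(f"unknown noise keys: {sorted(unknown)}")
        lo, hi = self.region_nm
        if lo >= hi:
            raise ConfigError(f"region_nm must satisfy lo < hi, got {self.region_nm}")
        if self.fit_model not in (None, "single", "with_secondary"):
            raise ConfigError(f"unknown fit_model {self.fit_model!r}")
        if self.fit_use_series not in ("both", "F", "POH"):
            raise ConfigError(f"unknown fit_use_series {self.fit_use_series!r}")

    def conditions(self) -> StudyConditions:
        if self.scenario == "custom":
            return StudyConditions(
                name="custom",
                params=KineticParams(**self.params),
                init=InitialConditions(**self.init),
            )
        return SCENARIOS[self.scenario]

    def noise_model(self) -> NoiseModel:
        return NoiseModel(seed=self.seed, **self.noise)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["region_nm"] = list(self.region_nm)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """Self-describing result of one pipeline run."""

    config: dict
    config_digest: str
    version: str
    fitted_params: dict
    calibration: dict
    diagnostics: dict
    outputs: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def write(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full monitoring workflow for one configured run.

    Stages, in order: simulate the in-line spectra and off-line assay
    series for the configured scenario; fit the kinetic model to the
    off-line data; simulate the modelled [POH] decay from the fitted
    parameters; restrict the spectra to the configured region,
    mean-center, run PCA; mask withdrawal disturbances; select the
    reaction-tracking component; calibrate its score against the modelled
    decay.  Identical configuration reproduces identical outputs.
    """
    config.validate()
    cond = config.conditions()
    noise = config.noise_model()
    t0 = time.perf_counter()
    logger.info(
        "run %s: seed=%d digest=%s", config.scenario, config.seed, config.digest()
    )

    outdir = Path(config.output_dir) if config.output_dir else None
    outputs: dict[str, str] = {}

    def _stage(name):
        logger.info("stage %-12s t=%.2fs", name, time.perf_counter() - t0)

    try:
        _stage("simulate")
        spectra = generate_inline_spectra(
            cond.params,
            cond.init,
            noise=noise,
            duration_h=config.duration_h,
            coarse=config.coarse_grid,
        )
        truth = simulate_trajectory(cond.params, cond.init, spectra.times)
        offline = generate_offline_series(truth, noise=noise)
    except Exception as e:
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e

    try:
        _stage("fit-kinetics")
        model = config.fit_model or (
            "with_secondary" if cond.params.k2 > 0 else "single"
        )
        fit_input = offline
        if config.correct_offline_delay and noise.offline_delay_h > 0:
            from .kinetics import OfflineSeries

            fit_input = OfflineSeries(
                times=offline.times + noise.offline_delay_h,
                F=offline.F,
                POH=offline.POH,
            )
        fit = fit_kinetics(
            fit_input, cond.init, model=model, use_series=config.fit_use_series
        )
    except Exception as e:
        raise RuntimeError(f"stage 'fit-kinetics' failed: {e}") from e

    try:
        _stage("monitor")
        modeled = simulate_trajectory(fit.params, cond.init, spectra.times)
        region = select_region(spectra, *config.region_nm)
        centered, mean_spec = mean_center(region)
        pca = fit_pca(centered, n_components=3, mean_spectrum=mean_spec)
        mask = mask_disturbances(
            region, post_window_min=config.spike_window_min
        )
    except Exception as e:
        raise RuntimeError(f"stage 'monitor' failed: {e}") from e

    try:
        _stage("calibrate")
        pc = select_monitoring_pc(pca, modeled, region.times, mask)
        calibration = calibrate_scores(
            pca,
            pc,
            modeled,
            region.times,
            excluded_initial_window=config.excluded_initial_window_h,
            mask=mask,
            region=config.region_nm,
        )
    except Exception as e:
        raise RuntimeError(f"stage 'calibrate' failed: {e}") from e

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        write_spectra(spectra, outdir / "inline_spectra.csv")
        write_offline(offline, outdir / "offline_series.csv")
        write_fit_json(fit, outdir / "fitted_params.json")
        write_calibration_json(calibration, outdir / "calibration.json")
        outputs = {
            p.name: _file_digest(p)
            for p in sorted(outdir.glob("*.csv")) + sorted(outdir.glob("*.json"))
            if p.name != "report.json"  # the report digests its inputs only
        }

    _stage("done")
    report = RunReport(
        config=config.to_dict(),
        config_digest=config.digest(),
        version=__version__,
        fitted_params=fit.to_dict(),
        calibration=calibration.to_dict(),
        diagnostics={
            "n_spectra": int(spectra.n_times),
            "n_wavelengths_region": int(region.n_wavelengths),
            "n_masked": int(np.count_nonzero(~mask)),
            "explained_variance_fraction": [
                float(v) for v in pca.explained_variance_fraction
            ],
            "selected_component": int(pc),
        },
        outputs=outputs,
    )
    if outdir is not None:
        report.write(outdir / "report.json")
    return report
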