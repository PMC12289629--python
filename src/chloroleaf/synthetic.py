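"""Synthetic leaf readings and calibration datasets with planted truth.

No public dataset of raw RGBC leaf readings exists for this class of
instrument, so every stage of the pipeline is exercised on synthetic
data whose generating process is known exactly:

* raw channels are drawn uniformly within ranges spanning the counts
  observed on real wheat/maize leaves (R' 24-32, G' 22-30, B' 17-22,
  C 70-90 counts/uW/cm2), so each color channel is always below the
  clear channel;
* reference chlorophyll contents are computed FROM the production
  five-feature models on the drawn reading, plus independent Gaussian
  noise — making those models the planted ground truth that
  calibration routines must recover;
* replicate scatter is emulated as additive per-channel noise of a
  configurable scale, clipped at zero.

Uniform (rather than Gaussian) channel sampling is the
assumption-minimal choice given only observed ranges.  Rows whose
noisy contents fall outside the plausibility window are resampled, so
a default-config dataset is fully "ok" by construction.  Everything is
deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .colorspace import SensorReading, extract_features
from .errors import ConfigError
from .models import (
    DEFAULT_WINDOW,
    PlausibilityWindow,
    default_models,
    predict,
)
from .calibration import CalibrationDataset, CalibrationRow

__all__ = [
    "GeneratorConfig",
    "generate_readings",
    "generate_calibration_dataset",
    "generate_replicates",
]

#: (low, high) raw-count ranges per channel, spanning leaf observations.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "r_raw": (24.0, 32.0),
    "g_raw": (22.0, 30.0),
    "b_raw": (17.0, 22.0),
    "c_raw": (70.0, 90.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-data generator.

    Parameters
    ----------
    n_samples : int
        Number of leaf samples to generate.
    crop : str
        ``"wheat"``, ``"maize"`` or ``"mixed"`` (alternating labels).
    ranges : dict
        Per-channel ``(low, high)`` raw-count ranges.
    noise_sd : float
        SD of the Gaussian noise added to each generated chlorophyll
        content, mg/g.  The default 0.05 mg/g sits below the scatter
        of the real calibration residuals, keeping planted-model
        recovery well conditioned while still exercising noise paths.
    replicate_jitter : float
        Scale (SD) of per-channel replicate noise, counts.
    seed : int
        PRNG seed; identical seeds give identical datasets.
    """

    n_samples: int = 100
    crop: str = "mixed"
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    noise_sd: float = 0.05
    replicate_jitter: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise ConfigError(f"n_samples must be >= 0, got {self.n_samples}")
        if self.crop not in ("wheat", "maize", "mixed"):
            raise ConfigError(f"crop must be wheat/maize/mixed, got {self.crop!r}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.replicate_jitter < 0:
            raise ConfigError(f"replicate_jitter must be >= 0, got {self.replicate_jitter}")
        if set(self.ranges) != set(DEFAULT_RANGES):
            raise ConfigError(f"ranges must cover exactly {sorted(DEFAULT_RANGES)}")
        for name, (lo, hi) in self.ranges.items():
            if not lo < hi or lo < 0:
                raise ConfigError(f"degenerate or negative range for {name}: ({lo}, {hi})")


def _draw_reading(rng: np.random.Generator, ranges: dict[str, tuple[float, float]]) -> SensorReading:
    vals = {name: rng.uniform(lo, hi) for name, (lo, hi) in ranges.items()}
    # color channels must not exceed the clear (broadband) channel
    c = vals["c_raw"]
    return SensorReading(
        r_raw=min(vals["r_raw"], c),
        g_raw=min(vals["g_raw"], c),
        b_raw=min(vals["b_raw"], c),
        c_raw=c,
    )


def generate_readings(config: GeneratorConfig) -> list[SensorReading]:
    """Draw ``n_samples`` sensor readings uniformly within the ranges."""
    rng = np.random.default_rng(config.seed)
    return [_draw_reading(rng, config.ranges) for _ in range(config.n_samples)]


def generate_calibration_dataset(
    config: GeneratorConfig,
    window: PlausibilityWindow = DEFAULT_WINDOW,
    max_resample: int = 1000,
) -> CalibrationDataset:
    """Generate a calibration dataset with the production models as truth.

    Each row: a drawn reading, its extracted features, and reference
    contents computed from the production CL-a/CL-b/TCL models plus
    ``N(0, noise_sd)`` noise.  Rows whose noisy contents fall outside
    the plausibility window (or at/below zero) are redrawn, so the
    dataset is valid calibration input by construction.
    """
    rng = np.random.default_rng(config.seed)
    cla_model, clb_model, tcl_model = default_models()
    rows: list[CalibrationRow] = []
    crops = ("wheat", "maize")
    for i in range(config.n_samples):
        crop = config.crop if config.crop != "mixed" else crops[i % 2]
        for _ in range(max_resample):
            reading = _draw_reading(rng, config.ranges)
            feats = extract_features(reading)
            noise = rng.normal(0.0, config.noise_sd, size=3) if config.noise_sd > 0 else np.zeros(3)
            cla = predict(cla_model, feats) + noise[0]
            clb = predict(clb_model, feats) + noise[1]
            tcl = predict(tcl_model, feats) + noise[2]
            plausible = (
                cla > 0
                and clb > 0
                and window.min_content < tcl <= window.max_total
            )
            if plausible:
                rows.append(
                    CalibrationRow(
                        sample_id=f"syn{i:04d}",
                        features=feats,
                        cla=cla,
                        clb=clb,
                        tcl=tcl,
                        crop=crop,
                    )
                )
                break
        else:
            raise ConfigError(
                "could not draw a plausible sample; check ranges/noise_sd"
            )
    return CalibrationDataset(tuple(rows))


def generate_replicates(
    base: SensorReading, n: int, jitter: float, seed: int = 0
) -> list[SensorReading]:
    """Emulate repeated measurements of the same leaf point.

    Adds independent Gaussian noise of SD ``jitter`` to each channel,
    clipped at zero.  ``jitter=0`` returns ``n`` identical copies.
    """
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    if jitter < 0:
        raise ConfigError(f"jitter must be >= 0, got {jitter}")
    if jitter == 0:
        return [base] * n
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        noise = rng.normal(0.0, jitter, size=4)
        channels = np.maximum(np.array(base.channels()) + noise, 0.0)
        out.append(SensorReading(*channels))
    return out
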