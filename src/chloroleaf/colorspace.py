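"""Color-feature extraction from four-channel RGB-sensor readings.

A handheld leaf detector built around an RGBC photodiode sensor reports
four raw channel intensities per measurement: red (R'), green (G'),
blue (B'), and an unfiltered clear channel (C), all in counts/uW/cm2.
This module turns one such reading into the canonical 20-element color
feature vector used throughout the package:

* the 4 raw channels, carried through unchanged;
* 3 normalized color indices ``R = R'/C * 255`` (likewise G, B), which
  cancel overall illumination intensity;
* hue, saturation and value from the standard hexcone RGB->HSV
  transform (H in degrees [0, 360), S and V in [0, 1]);
* 10 ratio/product combinations of the normalized indices
  (R/B, R/G, G/R, G/B, B/R, B/G, R*G, R*B, G*B, R*G*B).

Normalized indices are kept at full floating precision; no integer
quantization is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import EmptyInputError, InvalidReadingError, UndefinedFeatureError

__all__ = [
    "SensorReading",
    "ColorFeatures",
    "FEATURE_NAMES",
    "normalize_channels",
    "to_hsv",
    "derived_indices",
    "extract_features",
    "average_replicates",
]

#: Canonical ordering of the 20 color features: 4 raw channels,
#: 3 normalized indices, 3 HSV coordinates, 10 combinations.
FEATURE_NAMES: tuple[str, ...] = (
    "r_raw",
    "g_raw",
    "b_raw",
    "c_raw",
    "r",
    "g",
    "b",
    "h",
    "s",
    "v",
    "r_over_b",
    "r_over_g",
    "g_over_r",
    "g_over_b",
    "b_over_r",
    "b_over_g",
    "r_times_g",
    "r_times_b",
    "g_times_b",
    "r_times_g_times_b",
)

#: Names of the 10 ratio/product indices, in canonical order.
DERIVED_INDEX_NAMES: tuple[str, ...] = FEATURE_NAMES[10:]


@dataclass(frozen=True)
class SensorReading:
    """One raw four-channel measurement from the RGBC sensor.

    Parameters
    ----------
    r_raw, g_raw, b_raw, c_raw : float
        Channel intensities in counts/uW/cm2.  All must be finite and
        non-negative; ``c_raw > 0`` is additionally required wherever
        normalization takes place.
    """

    r_raw: float
    g_raw: float
    b_raw: float
    c_raw: float

    def __post_init__(self) -> None:
        for name in ("r_raw", "g_raw", "b_raw", "c_raw"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise InvalidReadingError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise InvalidReadingError(f"{name} must be >= 0, got {value!r}")

    def channels(self) -> tuple[float, float, float, float]:
        return (self.r_raw, self.g_raw, self.b_raw, self.c_raw)


@dataclass(frozen=True)
class ColorFeatures:
    """The canonical 20-element color feature vector of one sample."""

    r_raw: float
    g_raw: float
    b_raw: float
    c_raw: float
    r: float
    g: float
    b: float
    h: float
    s: float
    v: float
    r_over_b: float
    r_over_g: float
    g_over_r: float
    g_over_b: float
    b_over_r: float
    b_over_g: float
    r_times_g: float
    r_times_b: float
    g_times_b: float
    r_times_g_times_b: float

    def as_dict(self) -> dict[str, float]:
        """Features as an ordered name -> value mapping."""
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in FEATURE_NAMES)

    def __len__(self) -> int:
        return len(FEATURE_NAMES)


def normalize_channels(reading: SensorReading) -> tuple[float, float, float]:
    """Normalize raw channels against the clear channel on a 0-255 scale.

    Implements ``R = R'/C * 255`` (and likewise for G, B): dividing by
    the broadband clear intensity cancels the overall illumination
    level, and the 255 factor puts the index on the familiar 8-bit
    color scale.  No rounding is applied.

    Returns
    -------
    (r, g, b) : tuple of float
        Normalized color indices.  Each lies in [0, 255] whenever the
        corresponding raw channel does not exceed ``c_raw``.

    Raises
    ------
    InvalidReadingError
        If ``c_raw <= 0``.
    """
    if reading.c_raw <= 0:
        raise InvalidReadingError(
            f"clear channel must be > 0 for normalization, got {reading.c_raw!r}"
        )
    scale = 255.0 / reading.c_raw
    return (reading.r_raw * scale, reading.g_raw * scale, reading.b_raw * scale)


def to_hsv(r: float, g: float, b: float) -> tuple[float, float, float]:
    """Convert normalized color indices to hue/saturation/value.

    Standard hexcone conversion: ``v = max/255``, ``s = (max-min)/max``
    (0 when max is 0), and hue from the dominant-channel sector
    formula, wrapped into [0, 360) degrees.  Achromatic inputs
    (max == min) take ``h = 0`` by convention.

    Raises
    ------
    InvalidReadingError
        If any input is negative.
    """
    if r < 0 or g < 0 or b < 0:
        raise InvalidReadingError("normalized indices must be >= 0 for HSV conversion")
    mx = max(r, g, b)
    mn = min(r, g, b)
    delta = mx - mn

    v = mx / 255.0
    s = 0.0 if mx == 0 else delta / mx

    if delta == 0:
        h = 0.0
    elif mx == r:
        h = 60.0 * (((g - b) / delta) % 6.0)
    elif mx == g:
        h = 60.0 * ((b - r) / delta + 2.0)
    else:  # mx == b
        h = 60.0 * ((r - g) / delta + 4.0)
    h %= 360.0
    return (h, s, v)


def derived_indices(r: float, g: float, b: float) -> dict[str, float]:
    """Compute the 10 ratio/product indices of the normalized channels.

    Returns the indices keyed by canonical name (R/B, R/G, G/R, G/B,
    B/R, B/G, R*G, R*B, G*B, R*G*B), in canonical order.

    Raises
    ------
    UndefinedFeatureError
        If a ratio has a zero denominator; the error names the feature.
        Real leaf readings never have a zero channel, so a zero here
        signals a defective measurement rather than data to propagate.
    InvalidReadingError
        If any input is negative.
    """
    if r < 0 or g < 0 or b < 0:
        raise InvalidReadingError("normalized indices must be >= 0 for derived indices")

    ratios = {
        "r_over_b": (r, b),
        "r_over_g": (r, g),
        "g_over_r": (g, r),
        "g_over_b": (g, b),
        "b_over_r": (b, r),
        "b_over_g": (b, g),
    }
    out: dict[str, float] = {}
    for name, (num, den) in ratios.items():
        if den == 0:
            raise UndefinedFeatureError(name)
        out[name] = num / den
    out["r_times_g"] = r * g
    out["r_times_b"] = r * b
    out["g_times_b"] = g * b
    out["r_times_g_times_b"] = r * g * b
    return out


def extract_features(reading: SensorReading) -> ColorFeatures:
    """Compute the full 20-feature vector for one sensor reading.

    Composes :func:`normalize_channels`, :func:`to_hsv` and
    :func:`derived_indices`; deterministic (identical input gives
    bitwise-identical output).

    Raises
    ------
    InvalidReadingError, UndefinedFeatureError
        Propagated from the underlying steps.
    """
    r, g, b = normalize_channels(reading)
    h, s, v = to_hsv(r, g, b)
    combos = derived_indices(r, g, b)
    return ColorFeatures(
        r_raw=reading.r_raw,
        g_raw=reading.g_raw,
        b_raw=reading.b_raw,
        c_raw=reading.c_raw,
        r=r,
        g=g,
        b=b,
        h=h,
        s=s,
        v=v,
        **combos,
    )


def average_replicates(readings: Sequence[SensorReading] | Iterable[SensorReading]) -> SensorReading:
    """Channel-wise arithmetic mean of replicate readings.

    Field protocol takes replicate measurements per sample (triplicate
    in routine use) and works with their mean.  Averaging happens on
    the raw channels, before any feature is computed, matching how
    replicate summaries are reported at channel level.

    Raises
    ------
    EmptyInputError
        If the sequence is empty.
    """
    readings = list(readings)
    if not readings:
        raise EmptyInputError("cannot average an empty list of readings")
    n = len(readings)
    sums = [0.0, 0.0, 0.0, 0.0]
    for rd in readings:
        for i, value in enumerate(rd.channels()):
            sums[i] += value
    return SensorReading(*(total / n for total in sums))
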