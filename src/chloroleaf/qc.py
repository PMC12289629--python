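"""Instrument QC: repeatability and stability statistics.

Two QC protocols characterize the sensor head:

* **Repeatability** — the same leaf point is measured many times in a
  row (10 in the reference protocol); per-sample, per-channel mean,
  standard deviation and coefficient of variation (CV) quantify
  shot-to-shot scatter.
* **Stability** — a fixed set of color cards is re-measured at several
  times of day; the CV of the per-time channel means quantifies drift.

The CV convention throughout is **population** standard deviation
(divide by n, not n-1) over the mean, in percent.  This choice is
deliberate: it is the convention that regenerates the instrument's
published stability figures from the underlying timepoint means, and
for small replicate counts it is the convention the field's instrument
reports use.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .colorspace import SensorReading
from .errors import (
    EmptyInputError,
    InsufficientReplicatesError,
    UndefinedCVError,
)

__all__ = [
    "QCRow",
    "QCReport",
    "CHANNELS",
    "cv_percent",
    "cv_from_summary",
    "repeatability_report",
    "stability_report",
]

#: Raw channel names in report order.
CHANNELS: tuple[str, ...] = ("r_raw", "g_raw", "b_raw", "c_raw")


@dataclass(frozen=True)
class QCRow:
    """Statistics of one group x channel cell."""

    group: str
    channel: str
    mean: float
    sd: float
    cv_percent: float


@dataclass(frozen=True)
class QCReport:
    """Per-group per-channel statistics plus the overall mean CV.

    ``overall_cv_percent`` is the plain arithmetic mean of every
    group x channel CV in the report.
    """

    rows: tuple[QCRow, ...]
    overall_cv_percent: float
    kind: str = "repeatability"  # "repeatability" | "stability"

    def cell(self, group: str, channel: str) -> QCRow:
        for row in self.rows:
            if row.group == group and row.channel == channel:
                return row
        raise KeyError((group, channel))

    def summary_lines(self) -> list[str]:
        lines = [f"{self.kind} report ({len(self.rows)} cells)"]
        for row in self.rows:
            lines.append(
                f"  {row.group:>12s} {row.channel:>6s}: "
                f"mean={row.mean:.1f} sd={row.sd:.3f} cv={row.cv_percent:.3f}%"
            )
        lines.append(f"  overall mean CV: {self.overall_cv_percent:.3f}%")
        return lines


def cv_percent(values: Sequence[float] | Iterable[float]) -> float:
    """Coefficient of variation in percent: 100 * population SD / mean.

    Raises
    ------
    EmptyInputError
        On an empty sequence.
    UndefinedCVError
        If the mean is zero.
    """
    values = list(values)
    if not values:
        raise EmptyInputError("CV of an empty sequence is undefined")
    mean = statistics.fmean(values)
    if mean == 0:
        raise UndefinedCVError("CV undefined for zero mean")
    sd = statistics.pstdev(values)
    return 100.0 * sd / mean


def cv_from_summary(mean: float, sd: float) -> float:
    """CV in percent from a printed mean +/- SD summary.

    Provided for checking tabulated summaries; the report builders
    always compute CVs from the raw replicates instead, because SDs
    rounded for print cannot reliably regenerate the underlying CV.
    """
    if mean == 0:
        raise UndefinedCVError("CV undefined for zero mean")
    if sd < 0:
        raise UndefinedCVError("SD must be >= 0")
    return 100.0 * sd / mean


def repeatability_report(
    replicates: Mapping[str, Sequence[SensorReading]],
) -> QCReport:
    """Repeatability statistics from per-sample replicate readings.

    Parameters
    ----------
    replicates : mapping of sample id -> list of SensorReading
        At least 2 replicates per sample.

    Returns
    -------
    QCReport
        One row per sample x channel (mean, population SD, CV) and the
        overall mean CV across all cells.

    Raises
    ------
    InsufficientReplicatesError
        If any sample has fewer than 2 replicates.
    EmptyInputError
        If the mapping is empty.
    """
    if not replicates:
        raise EmptyInputError("no samples supplied")
    rows: list[QCRow] = []
    for sample_id, readings in replicates.items():
        readings = list(readings)
        if len(readings) < 2:
            raise InsufficientReplicatesError(
                f"sample {sample_id!r} has {len(readings)} replicate(s); need >= 2"
            )
        for idx, channel in enumerate(CHANNELS):
            series = [rd.channels()[idx] for rd in readings]
            mean = statistics.fmean(series)
            sd = statistics.pstdev(series)
            if mean == 0:
                raise UndefinedCVError(
                    f"zero mean for {sample_id!r}/{channel}: CV undefined"
                )
            rows.append(
                QCRow(str(sample_id), channel, mean, sd, 100.0 * sd / mean)
            )
    overall = statistics.fmean(row.cv_percent for row in rows)
    return QCReport(tuple(rows), overall, kind="repeatability")


def stability_report(
    timepoint_means: Mapping[str, Mapping[str, float] | Sequence[float]],
) -> QCReport:
    """Stability statistics across timepoint means.

    Parameters
    ----------
    timepoint_means : mapping of timepoint label -> channel means
        Channel means per timepoint, either keyed by channel name or
        as a sequence in ``CHANNELS`` order.  At least 2 timepoints.

    Returns
    -------
    QCReport
        One row per channel: mean/SD/CV of that channel's timepoint
        means (population SD), grouped under label ``all_times``.

    Raises
    ------
    InsufficientReplicatesError
        With fewer than 2 timepoints.
    """
    if len(timepoint_means) < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 timepoints, got {len(timepoint_means)}"
        )
    normalized: dict[str, dict[str, float]] = {}
    for time, means in timepoint_means.items():
        if isinstance(means, Mapping):
            normalized[str(time)] = {ch: float(means[ch]) for ch in CHANNELS}
        else:
            means = list(means)
            if len(means) != len(CHANNELS):
                raise EmptyInputError(
                    f"timepoint {time!r}: expected {len(CHANNELS)} channel means"
                )
            normalized[str(time)] = dict(zip(CHANNELS, map(float, means)))

    rows: list[QCRow] = []
    for channel in CHANNELS:
        series = [normalized[t][channel] for t in normalized]
        mean = statistics.fmean(series)
        sd = statistics.pstdev(series)
        if mean == 0:
            raise UndefinedCVError(f"zero mean for channel {channel}: CV undefined")
        rows.append(QCRow("all_times", channel, mean, sd, 100.0 * sd / mean))
    overall = statistics.fmean(row.cv_percent for row in rows)
    return QCReport(tuple(rows), overall, kind="stability")
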