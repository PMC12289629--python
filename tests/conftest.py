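"""Shared fixtures: the instrument's published QC summaries and the
sample readings used as worked examples throughout the tests."""

from __future__ import annotations

import pytest

from chloroleaf import SensorReading

# Per-channel means of one wheat leaf measured 10 times on the same
# point (replicate summary row 1 of the repeatability protocol).
SAMPLE1_MEANS = SensorReading(r_raw=27.9, g_raw=27.0, b_raw=18.8, c_raw=80.9)

# Stability protocol: per-channel means of a color-card set measured at
# four times of day (order: R', G', B', C in counts/uW/cm2).
STABILITY_TIMEPOINT_MEANS = {
    "08:00": {"r_raw": 69.2, "g_raw": 39.0, "b_raw": 36.2, "c_raw": 155.6},
    "12:00": {"r_raw": 71.0, "g_raw": 40.0, "b_raw": 37.0, "c_raw": 159.0},
    "16:00": {"r_raw": 70.0, "g_raw": 39.0, "b_raw": 37.0, "c_raw": 157.0},
    "20:00": {"r_raw": 70.0, "g_raw": 39.0, "b_raw": 37.0, "c_raw": 157.0},
}

# Published per-channel CVs (percent) of those stability means.
STABILITY_CVS = {"r_raw": 0.911, "g_raw": 1.103, "b_raw": 0.941, "c_raw": 0.771}

# Repeatability summary: 6 leaves x 4 channels of (mean, sd, cv%) cells
# as printed in the instrument's repeatability table.
REPEATABILITY_CELLS = [
    # sample 1 (wheat)
    (27.9, 0.0, 0.000), (27.0, 0.1, 0.341), (18.8, 0.1, 0.382), (80.9, 0.5, 0.666),
    # sample 2
    (29.0, 0.0, 0.000), (29.0, 0.0, 0.000), (19.2, 0.4, 2.083), (85.0, 0.0, 0.000),
    # sample 3
    (25.8, 0.0, 0.000), (23.8, 0.0, 0.000), (18.0, 0.0, 0.000), (74.0, 0.0, 0.000),
    # sample 4 (maize)
    (29.9, 0.3, 1.003), (26.5, 0.5, 1.889), (19.0, 0.0, 0.000), (82.1, 0.5, 0.656),
    # sample 5
    (30.9, 0.3, 0.971), (27.9, 0.3, 1.075), (20.9, 0.3, 1.435), (86.3, 0.6, 0.742),
    # sample 6
    (30.0, 0.0, 0.000), (26.1, 0.3, 1.149), (20.0, 0.0, 0.000), (78.0, 0.0, 0.000),
]

# Mean chlorophyll contents (mg/g) of the wheat modeling material.
WHEAT_MEAN_CONTENTS = {"cla": 2.140, "clb": 0.571, "tcl": 2.711}


@pytest.fixture
def sample1_reading() -> SensorReading:
    return SAMPLE1_MEANS


@pytest.fixture
def stability_means() -> dict:
    return STABILITY_TIMEPOINT_MEANS


@pytest.fixture
def five_features() -> list[str]:
    return ["b", "b_raw", "h", "s", "v"]
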