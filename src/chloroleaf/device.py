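"""Software-level emulator of the handheld detector's run loop.

The instrument's firmware is a simple state machine: power-on
initialization, a welcome screen, then a ready loop; pressing the
detection head triggers a measurement, whose result lands either on
the result display or, if the computed contents are implausible, on a
detection-error screen.  From a result the user can flip between the
three content pages (CL-a, CL-b, TCL), transmit the result, or start
a new measurement; from an error the device returns to ready.

Timing (the welcome-screen second, the ~2 s measurement) is modeled as
zero-cost ``tick`` events, and transmission as writing the current
estimate to a sink callback — both are hardware-bound details with no
computational content.  Illegal events for a state are logged and
ignored; the emulator never crashes on input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable

from .colorspace import SensorReading, extract_features
from .errors import ChloroleafError
from .models import (
    DEFAULT_WINDOW,
    ChlorophyllEstimate,
    LinearModel,
    PlausibilityWindow,
    default_models,
    predict_all,
)

__all__ = ["DeviceState", "DeviceEmulator", "step", "STATES", "EVENTS", "PAGES"]

logger = logging.getLogger(__name__)

STATES = ("INIT", "WELCOME", "READY", "MEASURING", "RESULT", "ERROR", "TRANSMITTED")
EVENTS = ("power_on", "tick", "press_detect", "press_flip", "press_transmit", "reading")
PAGES = ("cla", "clb", "tcl")


@dataclass(frozen=True)
class DeviceState:
    """Immutable snapshot of the emulated device."""

    state: str = "INIT"
    estimate: ChlorophyllEstimate | None = None
    page: str = "cla"


def _next_page(page: str) -> str:
    return PAGES[(PAGES.index(page) + 1) % len(PAGES)]


def step(
    state: DeviceState,
    event: str,
    reading: SensorReading | None = None,
    models: tuple[LinearModel, LinearModel, LinearModel] | None = None,
    window: PlausibilityWindow = DEFAULT_WINDOW,
    transmit_sink: Callable[[ChlorophyllEstimate], None] | None = None,
) -> DeviceState:
    """Advance the device by one event; deterministic, total.

    The only transitions taken are:
    INIT->WELCOME->READY->MEASURING->{RESULT|ERROR};
    RESULT->{READY, TRANSMITTED, RESULT (page flip)}; ERROR->READY.
    An event that is illegal in the current state is a logged no-op.
    """
    if event not in EVENTS:
        logger.warning("unknown event %r ignored in state %s", event, state.state)
        return state

    s = state.state
    if s == "INIT" and event == "power_on":
        return DeviceState(state="WELCOME")
    if s == "WELCOME" and event == "tick":
        return replace(state, state="READY")
    if s == "READY" and event == "press_detect":
        return replace(state, state="MEASURING")
    if s == "MEASURING" and event == "reading":
        if reading is None:
            logger.warning("reading event without a reading payload; ignored")
            return state
        try:
            estimate = predict_all(extract_features(reading), models=models, window=window)
        except ChloroleafError as exc:
            logger.warning("measurement failed (%s); detection error", exc)
            return DeviceState(state="ERROR")
        if estimate.status != "ok":
            return DeviceState(state="ERROR")
        return DeviceState(state="RESULT", estimate=estimate, page="cla")
    if s == "RESULT":
        if event == "press_flip":
            return replace(state, page=_next_page(state.page))
        if event == "press_transmit":
            if transmit_sink is not None and state.estimate is not None:
                transmit_sink(state.estimate)
            return replace(state, state="TRANSMITTED")
        if event == "press_detect":
            return replace(state, state="READY")
    if s == "ERROR" and event in ("tick", "press_detect"):
        return DeviceState(state="READY")

    logger.warning("event %r is illegal in state %s; ignored", event, s)
    return state


class DeviceEmulator:
    """Stateful convenience wrapper around :func:`step`."""

    def __init__(
        self,
        models: tuple[LinearModel, LinearModel, LinearModel] | None = None,
        window: PlausibilityWindow = DEFAULT_WINDOW,
        transmit_sink: Callable[[ChlorophyllEstimate], None] | None = None,
    ):
        self.models = models if models is not None else default_models()
        self.window = window
        self.transmit_sink = transmit_sink
        self.state = DeviceState()
        self.history: list[str] = [self.state.state]

    def send(self, event: str, reading: SensorReading | None = None) -> DeviceState:
        self.state = step(
            self.state,
            event,
            reading=reading,
            models=self.models,
            window=self.window,
            transmit_sink=self.transmit_sink,
        )
        if self.history[-1] != self.state.state:
            self.history.append(self.state.state)
        return self.state

    def display(self) -> str:
        """What the screen would show in the current state."""
        s = self.state
        if s.state == "WELCOME":
            return "welcome"
        if s.state == "READY":
            return "press the detection head to measure"
        if s.state == "ERROR":
            return "detection error"
        if s.state in ("RESULT", "TRANSMITTED") and s.estimate is not None:
            suffix = " (transmitted)" if s.state == "TRANSMITTED" else ""
            return s.estimate.display(s.page) + suffix
        return s.state.lower()
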