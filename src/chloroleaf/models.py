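"""Calibrated linear prediction models for leaf chlorophyll content.

The detector predicts chlorophyll-a (CL-a), chlorophyll-b (CL-b) and
total chlorophyll (TCL), all in mg per g fresh leaf, from five color
features: the normalized blue index B, the raw blue channel B', and
the HSV coordinates H, S, V.  The production models are multiple
linear regressions calibrated on pooled wheat and maize leaves:

    CL-a = -30.623 + 1.143*B - 0.225*B' + 0.008*H + 85.096*S - 170.899*V
    CL-b = -13.164 + 0.467*B - 0.052*B' + 0.005*H + 35.536*S -  72.08*V
    TCL  = -43.787 + 1.609*B - 0.276*B' + 0.013*H + 120.632*S - 242.979*V

Note the two "blue" symbols: B is the normalized index (feature name
``b``), B' the raw sensor channel (feature name ``b_raw``).  The TCL
coefficients equal the CL-a + CL-b sums up to 0.001 print rounding on
the B and B' terms, so TCL tracks CL-a + CL-b closely but not exactly.

The on-device workflow guards results against implausible output: a
negative content or a total above a configurable ceiling flags the
measurement as a detection error instead of reporting a number.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import IO, Mapping

from .colorspace import FEATURE_NAMES, ColorFeatures
from .errors import ModelMismatchError, ParameterError

__all__ = [
    "LinearModel",
    "ChlorophyllEstimate",
    "PlausibilityWindow",
    "DEFAULT_WINDOW",
    "TARGETS",
    "default_models",
    "predict",
    "predict_all",
    "read_model",
    "write_model",
]

#: Valid prediction targets, in display order.
TARGETS: tuple[str, ...] = ("chlorophyll_a", "chlorophyll_b", "total_chlorophyll")

_DEFAULT_MODEL_RESOURCE = "default_models.json"


@dataclass(frozen=True)
class LinearModel:
    """An affine prediction model over named color features.

    Parameters
    ----------
    target : str
        One of ``chlorophyll_a``, ``chlorophyll_b``, ``total_chlorophyll``.
    intercept : float
        Constant term, mg/g.
    coefficients : mapping of str to float
        Weight per feature, mg/g per feature unit.  Every key must be
        one of the canonical 20 feature names.
    feature_order : tuple of str
        Evaluation order; must cover exactly the coefficient keys.
    metadata : str
        Free-form provenance text.
    """

    target: str
    intercept: float
    coefficients: Mapping[str, float]
    feature_order: tuple[str, ...] = ()
    metadata: str = ""

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ParameterError(f"unknown target {self.target!r}; expected one of {TARGETS}")
        coefs = dict(self.coefficients)
        object.__setattr__(self, "coefficients", coefs)
        unknown = set(coefs) - set(FEATURE_NAMES)
        if unknown:
            raise ParameterError(f"unknown feature names in coefficients: {sorted(unknown)}")
        order = tuple(self.feature_order) or tuple(
            name for name in FEATURE_NAMES if name in coefs
        )
        if len(set(order)) != len(order):
            raise ParameterError("feature_order contains duplicates")
        if set(order) != set(coefs):
            raise ParameterError("feature_order must cover exactly the coefficient keys")
        object.__setattr__(self, "feature_order", order)


@dataclass(frozen=True)
class PlausibilityWindow:
    """Acceptance window for predicted contents (mg/g).

    A prediction outside the window flags the whole measurement as a
    detection error.  The default ceiling of 6.0 mg/g on total
    chlorophyll brackets the contents observed in wheat and maize
    calibration material (maximum 4.859 mg/g) with headroom; negative
    contents are physically impossible and always rejected.
    """

    min_content: float = 0.0
    max_total: float = 6.0


DEFAULT_WINDOW = PlausibilityWindow()


@dataclass(frozen=True)
class ChlorophyllEstimate:
    """One measurement result: the three contents plus a status flag."""

    cla: float
    clb: float
    tcl: float
    status: str = "ok"  # "ok" | "detection_error"

    def display(self, page: str = "tcl", decimals: int = 3) -> str:
        """Human-readable rendering of one display page (3 dp)."""
        labels = {"cla": "CL-a", "clb": "CL-b", "tcl": "TCL"}
        if page not in labels:
            raise ParameterError(f"unknown display page {page!r}")
        if self.status != "ok":
            return "detection error"
        return f"{labels[page]}: {getattr(self, page):.{decimals}f} mg/g"


def predict(model: LinearModel, features: ColorFeatures | Mapping[str, float]) -> float:
    """Evaluate ``intercept + sum(coef * feature)`` in mg/g.

    Raises
    ------
    ModelMismatchError
        If a feature named by the model is absent from the input.
    """
    if isinstance(features, ColorFeatures):
        lookup = features.as_dict()
    else:
        lookup = dict(features)
    total = model.intercept
    for name in model.feature_order:
        if name not in lookup:
            raise ModelMismatchError(
                f"model for {model.target} requires feature {name!r}, absent from input"
            )
        value = lookup[name]
        if not math.isfinite(value):
            raise ModelMismatchError(f"feature {name!r} is not finite: {value!r}")
        total += model.coefficients[name] * value
    return total


def predict_all(
    features: ColorFeatures | Mapping[str, float],
    models: tuple[LinearModel, LinearModel, LinearModel] | None = None,
    window: PlausibilityWindow = DEFAULT_WINDOW,
) -> ChlorophyllEstimate:
    """Evaluate the three content models and apply the plausibility guard.

    Abnormality is reported through the ``status`` field, never as an
    exception: the device displays a detection error and returns to
    the ready state.
    """
    if models is None:
        models = default_models()
    cla_model, clb_model, tcl_model = models
    cla = predict(cla_model, features)
    clb = predict(clb_model, features)
    tcl = predict(tcl_model, features)
    abnormal = (
        cla < window.min_content
        or clb < window.min_content
        or tcl < window.min_content
        or tcl > window.max_total
    )
    status = "detection_error" if abnormal else "ok"
    return ChlorophyllEstimate(cla=cla, clb=clb, tcl=tcl, status=status)


def _model_from_doc(doc: Mapping) -> LinearModel:
    return LinearModel(
        target=doc["target"],
        intercept=float(doc["intercept"]),
        coefficients={k: float(v) for k, v in doc["coefficients"].items()},
        feature_order=tuple(doc.get("feature_order") or ()),
        metadata=doc.get("metadata", ""),
    )


def _model_to_doc(model: LinearModel) -> dict:
    return {
        "target": model.target,
        "intercept": model.intercept,
        "coefficients": dict(model.coefficients),
        "feature_order": list(model.feature_order),
        "metadata": model.metadata,
    }


def read_model(source: str | Path | IO[str]) -> LinearModel:
    """Read one model document (JSON) from a path or open text stream."""
    if hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    return _model_from_doc(doc)


def write_model(model: LinearModel, dest: str | Path | IO[str]) -> None:
    """Write one model document (JSON) to a path or open text stream.

    Coefficients round-trip bit-identically (JSON repr of a float is
    exact for reading back).
    """
    doc = _model_to_doc(model)
    if hasattr(dest, "write"):
        json.dump(doc, dest, indent=2)
    else:
        with open(dest, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)


def read_model_set(source: str | Path | IO[str]) -> tuple[LinearModel, LinearModel, LinearModel]:
    """Read a three-model document (list of model objects, one per target)."""
    if hasattr(source, "read"):
        docs = json.load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            docs = json.load(fh)
    by_target = {doc["target"]: _model_from_doc(doc) for doc in docs}
    missing = set(TARGETS) - set(by_target)
    if missing:
        raise ParameterError(f"model document missing targets: {sorted(missing)}")
    return tuple(by_target[t] for t in TARGETS)  # type: ignore[return-value]


def write_model_set(
    models: tuple[LinearModel, LinearModel, LinearModel], dest: str | Path | IO[str]
) -> None:
    docs = [_model_to_doc(m) for m in models]
    if hasattr(dest, "write"):
        json.dump(docs, dest, indent=2)
    else:
        with open(dest, "w", encoding="utf-8") as fh:
            json.dump(docs, fh, indent=2)


def default_models() -> tuple[LinearModel, LinearModel, LinearModel]:
    """The production CL-a, CL-b and TCL models, in that order.

    Loaded from the model document shipped with the package, which
    carries the calibrated five-feature coefficients verbatim.
    """
    ref = resources.files("chloroleaf").joinpath("data", _DEFAULT_MODEL_RESOURCE)
    with ref.open("r", encoding="utf-8") as fh:
        return read_model_set(fh)
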