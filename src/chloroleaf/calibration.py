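"""Calibration workflow: fit, screen, refit and evaluate content models.

The model-building procedure that produced the production equations is
reproduced here end to end:

1. fit multiple linear regression (MLR, ordinary least squares) and
   partial least squares regression (PLSR) of a chlorophyll content on
   the 20 color features;
2. screen the MLR coefficients with classical t-tests and keep the
   features significant at ``alpha`` (0.05 by default);
3. refit on the retained subset (in the production calibration: the
   normalized blue index, the raw blue channel, and H, S, V);
4. evaluate with the coefficient of determination R2, root-mean-square
   error and mean absolute error, all on the fitting data.

Fitting pools crops (wheat + maize) by default, matching how the
production models were calibrated; per-crop subsets are available for
stratified evaluation.  A single-index helper supports baselines such
as regressing content on a SPAD column carried alongside the features.

MLR goes through statsmodels OLS (homoscedastic t-test p-values, as in
a classical significance table, with no multiple-testing correction);
PLSR goes through scikit-learn's NIPALS implementation.  Reported R2
is the plain fitting-set statistic, not adjusted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from sklearn.cross_decomposition import PLSRegression

from .colorspace import FEATURE_NAMES, ColorFeatures
from .errors import (
    CollinearityError,
    EmptyInputError,
    ParameterError,
    SampleSizeError,
)
from .models import TARGETS, LinearModel, predict

__all__ = [
    "CalibrationRow",
    "CalibrationDataset",
    "FitResult",
    "fit_mlr",
    "fit_plsr",
    "select_significant",
    "evaluate",
    "compare_single_index",
    "write_fit_report",
    "read_fit_report",
]

_TARGET_ATTR = {
    "chlorophyll_a": "cla",
    "chlorophyll_b": "clb",
    "total_chlorophyll": "tcl",
}

CROPS = ("wheat", "maize")


@dataclass(frozen=True)
class CalibrationRow:
    """One calibration sample: features paired with reference contents."""

    sample_id: str
    features: ColorFeatures
    cla: float
    clb: float
    tcl: float
    crop: str = "wheat"
    spad: float | None = None

    def __post_init__(self) -> None:
        if self.crop not in CROPS:
            raise ParameterError(f"crop must be one of {CROPS}, got {self.crop!r}")
        for name in ("cla", "clb", "tcl"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ParameterError(
                    f"reference {name} must be finite and > 0, got {value!r}"
                )


@dataclass(frozen=True)
class CalibrationDataset:
    """Paired (features, reference contents) rows used for fitting."""

    rows: tuple[CalibrationRow, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))

    def __len__(self) -> int:
        return len(self.rows)

    def subset(self, crop: str) -> "CalibrationDataset":
        """Rows of one crop only (for stratified evaluation)."""
        if crop not in CROPS:
            raise ParameterError(f"crop must be one of {CROPS}, got {crop!r}")
        return CalibrationDataset(tuple(r for r in self.rows if r.crop == crop))

    def feature_matrix(self, features: Sequence[str]) -> np.ndarray:
        """Design matrix (n x p) of the named features, canonical units.

        ``"spad"`` is accepted alongside the canonical color-feature
        names when the rows carry a SPAD column.
        """
        cols = []
        for name in features:
            if name == "spad":
                vals = [r.spad for r in self.rows]
                if any(v is None for v in vals):
                    raise ParameterError("dataset has no complete spad column")
                cols.append([float(v) for v in vals])  # type: ignore[arg-type]
            elif name in FEATURE_NAMES:
                cols.append([getattr(r.features, name) for r in self.rows])
            else:
                raise ParameterError(f"unknown feature {name!r}")
        return np.array(cols, dtype=float).T.reshape(len(self.rows), len(features))

    def target_vector(self, target: str) -> np.ndarray:
        if target not in _TARGET_ATTR:
            raise ParameterError(f"unknown target {target!r}; expected one of {TARGETS}")
        return np.array([getattr(r, _TARGET_ATTR[target]) for r in self.rows], dtype=float)


@dataclass(frozen=True)
class FitResult:
    """A fitted model with its significance table and fit metrics."""

    model: LinearModel
    pvalues: Mapping[str, float]
    r2: float
    rmse: float
    mae: float
    method: str  # "mlr" | "plsr"
    n_components: int | None = None


def _metrics(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float, float]:
    resid = y - yhat
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
    return r2, rmse, mae


def fit_mlr(
    data: CalibrationDataset,
    target: str,
    features: Sequence[str],
) -> FitResult:
    """Ordinary least squares fit of a content on the named features.

    P-values are per-coefficient two-sided t-tests under the classical
    homoscedastic OLS model; R2/RMSE/MAE are fitting-set statistics.

    Raises
    ------
    SampleSizeError
        If ``n <= len(features) + 1``.
    CollinearityError
        If the design matrix (with intercept) is rank deficient.
    """
    if len(data) == 0:
        raise EmptyInputError("empty calibration dataset")
    features = list(features)
    if len(data) <= len(features) + 1:
        raise SampleSizeError(
            f"need n > {len(features) + 1} samples for {len(features)} features, got {len(data)}"
        )
    X = data.feature_matrix(features)
    y = data.target_vector(target)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("design matrix is rank deficient (collinear features)")
    fit = sm.OLS(y, design).fit()
    intercept = float(fit.params[0])
    coefs = {name: float(c) for name, c in zip(features, fit.params[1:])}
    pvalues = {name: float(p) for name, p in zip(features, fit.pvalues[1:])}
    model_target = target if target in TARGETS else "total_chlorophyll"
    # spad baseline models reuse the LinearModel container only when the
    # predictor is a canonical feature; otherwise keep raw coefficients.
    if all(name in FEATURE_NAMES for name in features):
        model = LinearModel(
            target=model_target,
            intercept=intercept,
            coefficients=coefs,
            feature_order=tuple(features),
            metadata=f"MLR fit, n={len(data)}",
        )
        yhat = np.array([predict(model, r.features) for r in data.rows])
    else:
        model = None  # type: ignore[assignment]
        yhat = design @ fit.params
    r2, rmse, mae = _metrics(y, np.asarray(yhat, dtype=float))
    if model is None:
        model = LinearModel(
            target=model_target,
            intercept=intercept,
            coefficients={},
            metadata=f"MLR fit on non-canonical predictors {features}, n={len(data)}; "
            f"coefficients: {coefs}",
        )
    return FitResult(model=model, pvalues=pvalues, r2=r2, rmse=rmse, mae=mae, method="mlr")


def _loo_rmse_plsr(X: np.ndarray, y: np.ndarray, k: int) -> float:
    """Leave-one-out cross-validated RMSE of a k-component PLS fit."""
    n = X.shape[0]
    errs = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        pls = PLSRegression(n_components=k, scale=False)
        pls.fit(X[mask], y[mask])
        errs[i] = y[i] - float(pls.predict(X[i : i + 1]).ravel()[0])
    return float(np.sqrt(np.mean(errs**2)))


def fit_plsr(
    data: CalibrationDataset,
    target: str,
    features: Sequence[str] = FEATURE_NAMES,
    n_components: int | None = None,
) -> FitResult:
    """Partial least squares regression of a content on the features.

    With ``n_components=None`` the component count is chosen by
    leave-one-out cross-validated RMSE over 1..10 (capped by the data),
    ties resolved toward fewer components.  With the full component
    count on full-rank data, PLS predictions coincide with OLS.

    Raises
    ------
    ParameterError
        If ``n_components`` is outside ``[1, min(n-1, p)]``.
    """
    if len(data) == 0:
        raise EmptyInputError("empty calibration dataset")
    features = list(features)
    X = data.feature_matrix(features)
    y = data.target_vector(target)
    max_k = min(len(data) - 1, len(features))
    if max_k < 1:
        raise SampleSizeError("need at least 2 samples for PLSR")
    if n_components is None:
        candidates = range(1, min(10, max_k) + 1)
        scores = [(_loo_rmse_plsr(X, y, k), k) for k in candidates]
        n_components = min(scores)[1]  # ties break toward fewer components
    if not 1 <= n_components <= max_k:
        raise ParameterError(
            f"n_components must be in [1, {max_k}], got {n_components}"
        )
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    coef = np.asarray(pls.coef_).reshape(-1)
    # sklearn predicts on centered X; fold the centering into the intercept
    intercept = float(y.mean() - X.mean(axis=0) @ coef)
    yhat = pls.predict(X).ravel()
    r2, rmse, mae = _metrics(y, yhat)
    model_target = target if target in TARGETS else "total_chlorophyll"
    model = LinearModel(
        target=model_target,
        intercept=intercept,
        coefficients={name: float(c) for name, c in zip(features, coef)},
        feature_order=tuple(features),
        metadata=f"PLSR fit, n={len(data)}, {n_components} components",
    )
    return FitResult(
        model=model,
        pvalues={},
        r2=r2,
        rmse=rmse,
        mae=mae,
        method="plsr",
        n_components=n_components,
    )


def select_significant(pvalues: Mapping[str, float], alpha: float = 0.05) -> list[str]:
    """Features significant at level ``alpha`` (p < alpha), canonical order.

    Names not in the canonical feature set keep their input order,
    after the canonical ones.
    """
    if not 0 < alpha < 1 or not math.isfinite(alpha):
        raise ParameterError(f"alpha must be in (0, 1), got {alpha!r}")
    canonical = [n for n in FEATURE_NAMES if n in pvalues and pvalues[n] < alpha]
    extra = [
        n for n in pvalues if n not in FEATURE_NAMES and pvalues[n] < alpha
    ]
    return canonical + extra


def evaluate(
    model: LinearModel, data: CalibrationDataset, target: str
) -> dict[str, float]:
    """Fit metrics of a model against a dataset's reference contents.

    Returns ``{"r2": ..., "rmse": ..., "mae": ...}`` with
    ``rmse = sqrt(mean squared error)``, ``mae = mean |error|`` and
    ``r2 = 1 - SSE/SST``.

    Raises
    ------
    EmptyInputError
        On an empty dataset.
    """
    if len(data) == 0:
        raise EmptyInputError("cannot evaluate on an empty dataset")
    y = data.target_vector(target)
    yhat = np.array([predict(model, r.features) for r in data.rows])
    r2, rmse, mae = _metrics(y, yhat)
    return {"r2": r2, "rmse": rmse, "mae": mae}


def compare_single_index(
    data: CalibrationDataset, feature: str, target: str
) -> FitResult:
    """Simple linear regression of a content on one index.

    Supports baseline comparisons such as content-vs-SPAD when the
    dataset carries a ``spad`` column; delegates to :func:`fit_mlr`
    with a single predictor.
    """
    return fit_mlr(data, target, [feature])


def write_fit_report(result: FitResult, dest: str | Path | IO[str]) -> None:
    """Serialize a fit result (model + p-values + metrics) as JSON."""
    doc = {
        "method": result.method,
        "n_components": result.n_components,
        "r2": result.r2,
        "rmse": result.rmse,
        "mae": result.mae,
        "pvalues": dict(result.pvalues),
        "model": {
            "target": result.model.target,
            "intercept": result.model.intercept,
            "coefficients": dict(result.model.coefficients),
            "feature_order": list(result.model.feature_order),
            "metadata": result.model.metadata,
        },
    }
    if hasattr(dest, "write"):
        json.dump(doc, dest, indent=2)
    else:
        with open(dest, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2)


def read_fit_report(source: str | Path | IO[str]) -> FitResult:
    """Read a fit report written by :func:`write_fit_report`."""
    if hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    m = doc["model"]
    model = LinearModel(
        target=m["target"],
        intercept=float(m["intercept"]),
        coefficients={k: float(v) for k, v in m["coefficients"].items()},
        feature_order=tuple(m.get("feature_order") or ()),
        metadata=m.get("metadata", ""),
    )
    return FitResult(
        model=model,
        pvalues={k: float(v) for k, v in doc.get("pvalues", {}).items()},
        r2=float(doc["r2"]),
        rmse=float(doc["rmse"]),
        mae=float(doc["mae"]),
        method=doc["method"],
        n_components=doc.get("n_components"),
    )
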