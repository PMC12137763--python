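"""Gestational-age normative curves and centile classification.

For each (organ, measure) pair a mean trend is fitted to control data by
ordinary least squares — linear in GA for placental mean T2*, placental
volume and fetal-brain volume, quadratic for fetal-brain mean T2* — and
5th/95th centile curves of the same polynomial degree are fitted by
quantile (pinball-loss) regression. A new case's value is classified
against the centiles evaluated at its GA: "low" strictly below the 5th,
"high" strictly above the 95th, "normal" otherwise (values exactly on a
centile curve are normal).

No non-crossing constraint is imposed during fitting; crossing of the
5th and 95th curves anywhere on a dense GA grid inside the training
range raises a model-quality warning. Queries outside the training GA
range are answered but flagged as extrapolated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DegenerateInputError, InsufficientDataError
from .io_formats import MEASURES, ORGANS

#: Trend degree per (organ, measure): fetal-brain mean T2* follows a
#: quadratic GA trend; the other three combinations are linear.
TREND_BY_COMBO = {
    (organ, measure): "quadratic" if (organ, measure) == ("fetal_brain", "mean_t2star")
    else "linear"
    for organ in ORGANS
    for measure in MEASURES
}

_DEGREE = {"linear": 1, "quadratic": 2}

MIN_TRAIN = 10


def _design(ga: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(ga, degree + 1, increasing=True)


def _check_records(ga: np.ndarray, values: np.ndarray) -> None:
    if ga.size < MIN_TRAIN:
        raise InsufficientDataError(f"need >= {MIN_TRAIN} records, got {ga.size}")
    if np.ptp(ga) == 0:
        raise DegenerateInputError("all gestational ages equal: trend is unidentifiable")


def fit_trend(ga: Sequence[float], values: Sequence[float], trend: str) -> np.ndarray:
    """OLS polynomial trend. Returns ascending coefficients (c0..ck)."""
    ga = np.asarray(ga, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    _check_records(ga, values)
    degree = _DEGREE[trend]
    coeffs, *_ = np.linalg.lstsq(_design(ga, degree), values, rcond=None)
    return coeffs


def fit_quantile_curve(
    ga: Sequence[float], values: Sequence[float], trend: str, tau: float
) -> np.ndarray:
    """Quantile-regression polynomial curve at level ``tau``.

    Minimizes the pinball (check) loss over polynomial coefficients;
    deterministic given the data. Returns ascending coefficients.
    """
    if not 0 < tau < 1:
        raise ValueError(f"tau must be in (0, 1); got {tau}")
    ga = np.asarray(ga, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    _check_records(ga, values)
    degree = _DEGREE[trend]
    model = sm.QuantReg(values, _design(ga, degree))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # IterationLimitWarning surfaces as our own error below
        res = model.fit(q=tau, max_iter=5000)
    coeffs = np.asarray(res.params, dtype=np.float64)
    if not np.all(np.isfinite(coeffs)):
        raise DegenerateInputError(f"quantile regression at tau={tau} did not converge")
    return coeffs


def check_loss(ga, values, coeffs, tau: float) -> float:
    """Pinball loss of a polynomial curve — the quantile-fit objective."""
    ga = np.asarray(ga, dtype=np.float64)
    resid = np.asarray(values, dtype=np.float64) - np.polynomial.polynomial.polyval(ga, coeffs)
    return float(np.sum(np.where(resid >= 0, tau * resid, (tau - 1) * resid)))


@dataclass
class NormativeModel:
    """Mean + 5th/95th centile curves over GA for one (organ, measure)."""

    organ: str
    measure: str
    trend: str
    mean_coeffs: np.ndarray
    q05_coeffs: np.ndarray
    q95_coeffs: np.ndarray
    ga_range: tuple[float, float]
    n_train: int

    def _eval(self, coeffs: np.ndarray, ga: float | np.ndarray):
        return np.polynomial.polynomial.polyval(ga, np.asarray(coeffs))

    def mean_at(self, ga):
        return self._eval(self.mean_coeffs, ga)

    def q05_at(self, ga):
        return self._eval(self.q05_coeffs, ga)

    def q95_at(self, ga):
        return self._eval(self.q95_coeffs, ga)

    def check_crossing(self, n_grid: int = 100) -> bool:
        """Warn (and return True) if q05 > q95 anywhere inside ga_range."""
        grid = np.linspace(self.ga_range[0], self.ga_range[1], n_grid)
        q05, q95 = self.q05_at(grid), self.q95_at(grid)
        # tolerance so coincident curves (degenerate zero-noise data) do not warn
        crossing = bool(np.any(q05 - q95 > 1e-8 * np.maximum(1.0, np.abs(q95))))
        if crossing:
            warnings.warn(
                f"normative model ({self.organ}, {self.measure}): "
                "5th and 95th centile curves cross inside the training GA range",
                stacklevel=2,
            )
        return crossing


@dataclass
class CentileResult:
    """Classification of one value against a normative model."""

    organ: str
    measure: str
    ga_weeks: float
    value: float
    q05_at_ga: float
    q95_at_ga: float
    band: str  # low | normal | high
    extrapolated: bool


def build_normative_models(table: pd.DataFrame) -> dict[tuple[str, str], NormativeModel]:
    """Fit one normative model per (organ, measure) present in the table.

    Combinations with fewer than 10 records are omitted with a warning.
    Centile curves share the trend's polynomial degree.
    """
    models: dict[tuple[str, str], NormativeModel] = {}
    for organ in ORGANS:
        for measure in MEASURES:
            sub = table[(table["organ"] == organ) & (table["measure"] == measure)]
            if len(sub) < MIN_TRAIN:
                warnings.warn(
                    f"normative: insufficient rows for ({organ}, {measure}): "
                    f"{len(sub)} < {MIN_TRAIN}; model omitted",
                    stacklevel=2,
                )
                continue
            ga = sub["ga_weeks"].to_numpy()
            val = sub["value"].to_numpy()
            trend = TREND_BY_COMBO[(organ, measure)]
            model = NormativeModel(
                organ=organ,
                measure=measure,
                trend=trend,
                mean_coeffs=fit_trend(ga, val, trend),
                q05_coeffs=fit_quantile_curve(ga, val, trend, 0.05),
                q95_coeffs=fit_quantile_curve(ga, val, trend, 0.95),
                ga_range=(float(ga.min()), float(ga.max())),
                n_train=int(len(sub)),
            )
            model.check_crossing()
            models[(organ, measure)] = model
    return models


def classify(model: NormativeModel, ga_weeks: float, value: float) -> CentileResult:
    """Band a value against the model's centiles at one GA.

    "low" iff strictly below the 5th centile, "high" iff strictly above
    the 95th; values on a centile curve are "normal". GA outside the
    training range is answered but flagged ``extrapolated``.
    """
    q05 = float(model.q05_at(ga_weeks))
    q95 = float(model.q95_at(ga_weeks))
    if value < q05:
        band = "low"
    elif value > q95:
        band = "high"
    else:
        band = "normal"
    lo, hi = model.ga_range
    return CentileResult(
        organ=model.organ,
        measure=model.measure,
        ga_weeks=float(ga_weeks),
        value=float(value),
        q05_at_ga=q05,
        q95_at_ga=q95,
        band=band,
        extrapolated=not (lo <= ga_weeks <= hi),
    )


MODEL_STORE_VERSION = 1


def save_models(models: dict[tuple[str, str], NormativeModel], path: str | Path) -> None:
    """Serialize a model store to a versioned JSON document."""
    doc = {
        "version": MODEL_STORE_VERSION,
        "models": [
            {
                "organ": m.organ,
                "measure": m.measure,
                "trend": m.trend,
                "mean_coeffs": list(map(float, m.mean_coeffs)),
                "q05_coeffs": list(map(float, m.q05_coeffs)),
                "q95_coeffs": list(map(float, m.q95_coeffs)),
                "ga_range": list(m.ga_range),
                "n_train": m.n_train,
            }
            for m in models.values()
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_models(path: str | Path) -> dict[tuple[str, str], NormativeModel]:
    """Load a model store written by :func:`save_models`."""
    doc = json.loads(Path(path).read_text())
    models = {}
    for m in doc["models"]:
        model = NormativeModel(
            organ=m["organ"],
            measure=m["measure"],
            trend=m["trend"],
            mean_coeffs=np.asarray(m["mean_coeffs"], dtype=np.float64),
            q05_coeffs=np.asarray(m["q05_coeffs"], dtype=np.float64),
            q95_coeffs=np.asarray(m["q95_coeffs"], dtype=np.float64),
            ga_range=tuple(m["ga_range"]),
            n_train=int(m["n_train"]),
        )
        models[(model.organ, model.measure)] = model
    return models
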