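"""Prediction, internal/external validation residuals, and screening calls.

A model here is anything linear: either a :class:`~a2aqsar.models.FittedModel`
or a :class:`LinearModel` built from published coefficients.  Residuals use
the experimental-minus-predicted sign convention.  A screening compound is
called active when its predicted pEC50 strictly exceeds the cutoff; the
default cutoff 5.64936 is the potency of the weakest training compound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import InvalidValueError, TableFormatError
from .models import FittedModel
from .tables import CompoundRecord, DescriptorTable

#: pEC50 of the least potent training compound; screening activity threshold
DEFAULT_ACTIVITY_CUTOFF = 5.64936


@dataclass(frozen=True)
class LinearModel:
    """A linear activity model given directly by its coefficients."""

    intercept: float
    coefficients: Mapping[str, float]
    name: str = ""

    @classmethod
    def from_json(cls, path: str | Path, name: str = "") -> "LinearModel":
        payload = json.loads(Path(path).read_text())
        return cls(payload["intercept"], dict(payload["coefficients"]), name)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"intercept": self.intercept, "coefficients": dict(self.coefficients)},
                indent=2,
            )
        )


def _as_linear(model: FittedModel | LinearModel) -> LinearModel:
    if isinstance(model, FittedModel):
        return LinearModel(model.intercept, model.coefficients)
    return model


def predict(model: FittedModel | LinearModel, record: CompoundRecord) -> float:
    """intercept + sum(coefficient * descriptor) for one compound."""
    lin = _as_linear(model)
    total = lin.intercept
    for name, coef in lin.coefficients.items():
        if name not in record.descriptors:
            raise InvalidValueError(
                f"compound {record.compound_id!r} lacks descriptor {name!r}"
            )
        total += coef * record.descriptors[name]
    return total


def predict_table(model: FittedModel | LinearModel, table: DescriptorTable) -> pd.DataFrame:
    """Predictions for every row, order preserved."""
    rows = [
        {"compound_id": rec.compound_id, "predicted": predict(model, rec)}
        for rec in table
    ]
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Per-compound predicted/experimental/residual rows plus a summary."""

    rows: pd.DataFrame  # compound_id, experimental, predicted, residual
    model_name: str = ""

    @property
    def max_abs_residual(self) -> float:
        return float(self.rows["residual"].abs().max())

    @property
    def mean_residual(self) -> float:
        return float(self.rows["residual"].mean())


def residuals(
    model: FittedModel | LinearModel,
    table: DescriptorTable,
    activity: str = "pec50",
    model_name: str = "",
) -> ValidationReport:
    """Residual = experimental - predicted for every row of ``table``."""
    if len(table) == 0:
        raise TableFormatError("empty table")
    experimental = table.activity(activity)
    rows = []
    for rec, exp in zip(table, experimental):
        pred = predict(model, rec)
        rows.append(
            {
                "compound_id": rec.compound_id,
                "experimental": exp,
                "predicted": pred,
                "residual": exp - pred,
            }
        )
    return ValidationReport(pd.DataFrame(rows), model_name)


def classify_active(predicted: float, cutoff: float = DEFAULT_ACTIVITY_CUTOFF) -> bool:
    """Strictly greater than the cutoff; the boundary itself is inactive."""
    return predicted > cutoff


@dataclass
class ScreeningDecision:
    compound_id: str
    predictions: dict[str, float]  # model name -> predicted pEC50
    active: bool
    cutoff: float


def screen(
    models: Mapping[str, FittedModel | LinearModel],
    table: DescriptorTable,
    cutoff: float = DEFAULT_ACTIVITY_CUTOFF,
    decide_by: str | None = None,
) -> list[ScreeningDecision]:
    """Predict each screening compound under every model and call activity.

    The activity call uses the ``decide_by`` model (default: the last one in
    ``models``' ordering, conventionally the pentaparametric model).
    """
    names = list(models)
    if not names:
        raise InvalidValueError("no models supplied")
    key = decide_by if decide_by is not None else names[-1]
    if key not in models:
        raise InvalidValueError(f"decide_by model {key!r} not among {names}")
    out = []
    for rec in table:
        preds = {nm: predict(models[nm], rec) for nm in names}
        out.append(
            ScreeningDecision(rec.compound_id, preds, classify_active(preds[key], cutoff), cutoff)
        )
    return out
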