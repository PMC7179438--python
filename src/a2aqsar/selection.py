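"""Descriptor autoscaling and Pearson-correlation descriptor selection.

Before modelling, the descriptor matrix is autoscaled (each column centred
on its mean and divided by its sample standard deviation) so that every
descriptor carries equal weight.  Candidate descriptors are then screened
by the absolute Pearson correlation of each (raw) descriptor with the
activity; the default cutoff is |r| >= 0.5.  Correlation is invariant to
affine rescaling, so selection does not depend on whether the matrix was
autoscaled first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FitError, TableFormatError
from .tables import DescriptorTable

DEFAULT_CUTOFF = 0.5


@dataclass
class AutoscaleResult:
    """Autoscaled matrix with the statistics needed to invert the transform."""

    matrix: np.ndarray          # shape (n, m), columns mean 0 / sample sd 1
    columns: list[str]
    means: np.ndarray
    sds: np.ndarray

    def inverse(self) -> np.ndarray:
        return self.matrix * self.sds + self.means


@dataclass
class CorrelationReport:
    correlations: dict[str, float]
    cutoff: float
    selected: list[str]
    excluded_constant: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "correlations": self.correlations,
            "selected": self.selected,
            "excluded_constant": self.excluded_constant,
        }


def autoscale(table: DescriptorTable) -> AutoscaleResult:
    """Centre every descriptor column and scale it to unit sample variance.

    Raises :class:`FitError` naming the column if one has zero variance.
    """
    if len(table) < 2:
        raise TableFormatError("autoscaling needs at least 2 rows")
    cols = list(table.descriptor_names)
    X = np.array([[rec.descriptors[c] for c in cols] for rec in table], dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = [c for c, s in zip(cols, sds) if s == 0.0]
    if zero:
        raise FitError(f"zero-variance descriptor column(s): {zero}")
    return AutoscaleResult((X - means) / sds, cols, means, sds)


def correlate_with_activity(
    table: DescriptorTable,
    activity_column: str = "pec50",
    cutoff: float = DEFAULT_CUTOFF,
) -> CorrelationReport:
    """Pearson r of every descriptor against the activity column.

    Constant descriptors have undefined correlation; they are flagged in
    ``excluded_constant`` and never selected.
    """
    y = np.asarray(table.activity(activity_column), dtype=float)
    if y.std(ddof=1) == 0.0:
        raise FitError("activity column is constant; correlation undefined")
    correlations: dict[str, float] = {}
    excluded: list[str] = []
    for name in table.descriptor_names:
        x = np.array([rec.descriptors[name] for rec in table], dtype=float)
        if x.std(ddof=1) == 0.0:
            excluded.append(name)
            continue
        correlations[name] = float(np.corrcoef(x, y)[0, 1])
    selected = [n for n, r in correlations.items() if abs(r) >= cutoff]
    return CorrelationReport(correlations, cutoff, selected, excluded)


def select_descriptors(report: CorrelationReport, cutoff: float | None = None) -> list[str]:
    """Descriptor names whose |r| meets the cutoff, input order preserved."""
    c = report.cutoff if cutoff is None else cutoff
    return [n for n, r in report.correlations.items() if abs(r) >= c]
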