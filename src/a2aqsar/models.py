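"""Best-subset multiple linear regression for descriptor-based QSAR.

Candidate models are all size-p descriptor subsets (C(n, p) combinations
without repetition).  Each subset is fitted by ordinary least squares of
activity on the raw (unscaled) descriptors plus an intercept, and scored by

* r      -- multiple correlation coefficient, sqrt(R^2),
* r2     -- coefficient of determination, 1 - RSS/TSS,
* r2_adj -- explained variance, 1 - (1 - r2)(n - 1)/(n - p - 1),
* see    -- standard error of estimate, sqrt(RSS/(n - p - 1)),
* f      -- variance ratio, (r2/p) / ((1 - r2)/(n - p - 1)).

Models are ranked by higher r and F and smaller SEE.  Outlying training
compounds can be removed either by an iterative standardized-residual rule
or by pinning an explicit id set.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import FitError, InvalidValueError
from .tables import DescriptorTable


@dataclass(frozen=True)
class ModelSpec:
    """An ordered descriptor subset defining one candidate model."""

    descriptors: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.descriptors) < 1:
            raise InvalidValueError("a model needs at least one descriptor")
        if len(set(self.descriptors)) != len(self.descriptors):
            raise InvalidValueError(f"duplicate descriptors in {self.descriptors}")

    @property
    def p(self) -> int:
        return len(self.descriptors)


class ModelStats(NamedTuple):
    r: float
    r2: float
    r2_adj: float
    see: float
    f: float


@dataclass
class FittedModel:
    spec: ModelSpec
    intercept: float
    coefficients: dict[str, float]
    n_train: int
    training_ids: list[str]
    removed_outliers: list[str]
    stats: ModelStats

    def to_dict(self) -> dict:
        return {
            "descriptors": list(self.spec.descriptors),
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "n_train": self.n_train,
            "training_ids": self.training_ids,
            "removed_outliers": self.removed_outliers,
            "stats": self.stats._asdict(),
        }


def enumerate_models(descriptors: Sequence[str], sizes: Iterable[int]) -> list[ModelSpec]:
    """All size-p subsets of ``descriptors`` for each p in ``sizes``.

    Deterministic: sizes ascending, subsets in lexicographic order of the
    input descriptor ordering.
    """
    names = list(descriptors)
    specs: list[ModelSpec] = []
    for p in sorted(set(sizes)):
        if p < 1 or p > len(names):
            raise InvalidValueError(
                f"subset size {p} invalid for {len(names)} descriptors"
            )
        specs.extend(ModelSpec(combo) for combo in itertools.combinations(names, p))
    return specs


def model_stats(rss: float, tss: float, n: int, p: int) -> ModelStats:
    """Fit statistics from residual and total sums of squares.

    Degrees of freedom follow the n - p - 1 convention for an intercept
    model with p regressors.
    """
    if tss <= 0:
        raise FitError("total sum of squares is zero (constant activity)")
    dof = n - p - 1
    if dof < 1:
        raise FitError(f"no residual degrees of freedom (n={n}, p={p})")
    r2 = 1.0 - rss / tss
    r2 = max(r2, 0.0)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof
    see = math.sqrt(max(rss, 0.0) / dof)
    f = (r2 / p) / ((1.0 - r2) / dof) if r2 < 1.0 else math.inf
    return ModelStats(math.sqrt(r2), r2, r2_adj, see, f)


def _design(table: DescriptorTable, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    missing = [d for d in spec.descriptors if d not in table.descriptor_names]
    if missing:
        raise FitError(f"table lacks descriptor(s) {missing}")
    X = np.array(
        [[rec.descriptors[d] for d in spec.descriptors] for rec in table], dtype=float
    )
    return np.column_stack([np.ones(len(table)), X]), table.ids


def fit_ols(
    table: DescriptorTable, spec: ModelSpec, activity: str = "pec50"
) -> FittedModel:
    """Ordinary least squares of ``activity`` on the subset's raw descriptors."""
    n = len(table)
    if n < spec.p + 2:
        raise FitError(f"need at least p + 2 = {spec.p + 2} rows, got {n}")
    A, ids = _design(table, spec)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        corr = np.corrcoef(A[:, 1:], rowvar=False)
        pairs = [
            (spec.descriptors[i], spec.descriptors[j])
            for i in range(spec.p)
            for j in range(i + 1, spec.p)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise FitError(f"rank-deficient design; collinear columns: {pairs or spec.descriptors}")
    y = np.asarray(table.activity(activity), dtype=float)
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    return FittedModel(
        spec=spec,
        intercept=float(beta[0]),
        coefficients={d: float(b) for d, b in zip(spec.descriptors, beta[1:])},
        n_train=n,
        training_ids=ids,
        removed_outliers=[],
        stats=model_stats(rss, tss, n, spec.p),
    )


def rank_models(models: Sequence[FittedModel]) -> list[FittedModel]:
    """Sort by r descending, then F descending, SEE ascending, subset name.

    The final lexicographic key makes the order a deterministic total order.
    """
    return sorted(
        models,
        key=lambda m: (-m.stats.r, -m.stats.f, m.stats.see, m.spec.descriptors),
    )


def detect_outliers(
    table: DescriptorTable,
    spec: ModelSpec,
    activity: str = "pec50",
    rule: str = "auto",
    threshold: float = 2.0,
    pinned: Iterable[str] | None = None,
) -> set[str]:
    """Identify training compounds to exclude before the final fit.

    ``rule="pinned"`` returns the supplied id set unchanged (reproducing a
    fixed exclusion).  ``rule="auto"`` iterates: fit, standardize residuals
    by the SEE, drop the single worst row if it exceeds ``threshold``,
    refit; stops when no row exceeds the threshold.
    """
    if rule == "pinned":
        if pinned is None:
            raise InvalidValueError("pinned rule requires an explicit id set")
        ids = {str(i) for i in pinned}
        unknown = ids - set(table.ids)
        if unknown:
            raise InvalidValueError(f"pinned ids not in table: {sorted(unknown)}")
        if len(table) - len(ids) < spec.p + 2:
            raise FitError("pinned removal leaves too few rows to fit")
        return ids
    if rule != "auto":
        raise InvalidValueError(f"unknown outlier rule {rule!r}")

    removed: set[str] = set()
    current = table
    while True:
        model = fit_ols(current, spec, activity)
        A, ids = _design(current, spec)
        y = np.asarray(current.activity(activity), dtype=float)
        pred = A @ np.concatenate(
            [[model.intercept], [model.coefficients[d] for d in spec.descriptors]]
        )
        resid = y - pred
        if model.stats.see == 0.0:
            return removed
        z = np.abs(resid) / model.stats.see
        worst = int(np.argmax(z))
        if z[worst] <= threshold:
            return removed
        if len(current) - 1 < spec.p + 2:
            raise FitError(
                "outlier rule would leave too few rows to fit; "
                f"already removed {sorted(removed)}"
            )
        removed.add(ids[worst])
        current = current.drop([ids[worst]])


def fit_with_outlier_removal(
    table: DescriptorTable,
    spec: ModelSpec,
    activity: str = "pec50",
    rule: str = "auto",
    threshold: float = 2.0,
    pinned: Iterable[str] | None = None,
) -> FittedModel:
    """Convenience wrapper: detect outliers, refit on the cleaned table."""
    outliers = detect_outliers(table, spec, activity, rule, threshold, pinned)
    model = fit_ols(table.drop(outliers), spec, activity)
    model.removed_outliers = sorted(outliers)
    return model
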