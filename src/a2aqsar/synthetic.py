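"""Synthetic inputs emulating the statistical shape of every pipeline stage.

Three generators cover the pipeline's inputs:

* :func:`generate_table` -- descriptor tables with a known linear
  activity model plus Gaussian noise and optional injected outliers.
  Defaults mirror the study conditions: 21 compounds, descriptors drawn
  uniformly over the observed training ranges (MV 846-2394 A^3, MP 29-94,
  NA 38-120, PF 16-41, HG 1-18, AR 3-6, the integer counts rounded), the
  published pentaparametric coefficients as ground-truth betas, and a
  noise standard deviation of 0.3 pEC50 units -- the order of the fitted
  models' standard errors of estimate (0.28-0.32).
* :func:`generate_ranked_screen` -- labelled rankings of agonists,
  antagonists and decoys, with optional pinned label counts inside given
  rank prefixes (to construct screens with an exact recovery profile).
* :func:`generate_feature_cloud` -- a pharmacophore's features under a
  rigid transform with optional positional jitter and decoy features.

All generators are deterministic under a fixed seed.  They emulate only
the statistical structure of the tables, not real chemistry: descriptor
columns are sampled independently by default (real descriptors are highly
collinear), so tests passing on synthetic tables say nothing about the
conditioning of real descriptor sets unless correlation is injected via
``copula_correlation``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import InvalidValueError
from .pharmacophore import (
    PharmacophoreFeature,
    PharmacophoreModel,
    RankedScreen,
)
from .tables import CompoundRecord, DescriptorTable, INTEGER_DESCRIPTORS

#: descriptor ranges observed in the 21-compound training table
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "MV": (846.0, 2394.0),
    "MP": (29.0, 94.0),
    "NA": (38.0, 120.0),
    "PF": (16.0, 41.0),
    "HG": (1.0, 18.0),
    "AR": (3.0, 6.0),
}

#: published pentaparametric model, reused as ground-truth coefficients
DEFAULT_BETAS: dict[str, float] = {
    "MV": 0.023246,
    "MP": -0.829411,
    "NA": 0.242268,
    "PF": -0.081025,
    "HG": -0.072964,
}
DEFAULT_INTERCEPT = 4.478449


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic descriptor/activity table."""

    n_compounds: int = 21
    intercept: float = DEFAULT_INTERCEPT
    betas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETAS))
    noise_sd: float = 0.3
    descriptor_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    outlier_fraction: float = 0.0
    outlier_shift: float = 0.0
    copula_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise InvalidValueError("n_compounds must be >= 1")
        if self.noise_sd < 0:
            raise InvalidValueError("noise_sd must be >= 0")
        if not 0 <= self.outlier_fraction < 1:
            raise InvalidValueError("outlier_fraction must be in [0, 1)")
        if not -1 < self.copula_correlation < 1:
            raise InvalidValueError("copula_correlation must be in (-1, 1)")
        for name, (low, high) in self.descriptor_ranges.items():
            if not low < high:
                raise InvalidValueError(
                    f"descriptor {name!r}: invalid range ({low}, {high})"
                )
        missing = set(self.betas) - set(self.descriptor_ranges)
        if missing:
            raise InvalidValueError(f"betas reference unknown descriptors {sorted(missing)}")


@dataclass
class GroundTruth:
    intercept: float
    betas: dict[str, float]
    noise_sd: float
    outlier_ids: list[str]


def generate_table(spec: SyntheticSpec) -> tuple[DescriptorTable, GroundTruth]:
    """Draw a descriptor table with a known linear activity model.

    Descriptors are uniform over their ranges (integer descriptors
    rounded); with ``copula_correlation`` set, a Gaussian copula with
    constant pairwise correlation induces collinearity between columns.
    Activity is ``intercept + sum(beta*x) + N(0, noise_sd)``; a leading
    fraction of rows (chosen at random) additionally gets
    ``outlier_shift`` added to its activity.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.descriptor_ranges)
    n, m = spec.n_compounds, len(names)
    if spec.copula_correlation != 0.0:
        rho = spec.copula_correlation
        cov = np.full((m, m), rho) + (1 - rho) * np.eye(m)
        z = rng.multivariate_normal(np.zeros(m), cov, size=n, method="cholesky")
        u = norm.cdf(z)
    else:
        u = rng.uniform(size=(n, m))
    X = np.empty((n, m))
    for j, name in enumerate(names):
        low, high = spec.descriptor_ranges[name]
        col = low + u[:, j] * (high - low)
        if name in INTEGER_DESCRIPTORS:
            col = np.round(col)
        X[:, j] = col

    activity = spec.intercept + np.zeros(n)
    for j, name in enumerate(names):
        activity += spec.betas.get(name, 0.0) * X[:, j]
    activity += rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0

    n_out = int(round(spec.outlier_fraction * n))
    outlier_idx = sorted(rng.choice(n, size=n_out, replace=False)) if n_out else []
    for i in outlier_idx:
        activity[i] += spec.outlier_shift

    records = [
        CompoundRecord(
            compound_id=f"S{i + 1}",
            code=f"SYN-{i + 1}",
            role="training",
            pec50=float(activity[i]),
            descriptors={name: float(X[i, j]) for j, name in enumerate(names)},
        )
        for i in range(n)
    ]
    truth = GroundTruth(
        spec.intercept,
        dict(spec.betas),
        spec.noise_sd,
        [f"S{i + 1}" for i in outlier_idx],
    )
    return DescriptorTable(records, names), truth


def generate_ranked_screen(
    n_decoys: int = 500,
    n_agonists: int = 15,
    n_antagonists: int = 15,
    placements: tuple[tuple[int, str, int], ...] = (),
    seed: int = 0,
) -> RankedScreen:
    """A labelled ranking, optionally pinned to exact prefix label counts.

    ``placements`` is a tuple of ``(k, label, count)`` constraints, each
    requiring exactly ``count`` compounds of ``label`` within the top
    ``k``.  Constraints must be nested (sorted by k, counts
    non-decreasing per label).  Unconstrained positions are filled at
    random.
    """
    if min(n_decoys, n_agonists, n_antagonists) < 0:
        raise InvalidValueError("counts must be non-negative")
    total = n_decoys + n_agonists + n_antagonists
    pool = {
        "agonist": [f"AGO{i + 1}" for i in range(n_agonists)],
        "antagonist": [f"ANT{i + 1}" for i in range(n_antagonists)],
        "decoy": [f"DEC{i + 1}" for i in range(n_decoys)],
    }
    labels = {cid: lab for lab, ids in pool.items() for cid in ids}
    rng = np.random.default_rng(seed)

    # assign a label to each rank slot in the constrained prefix
    slots: list[str | None] = [None] * total
    prev_k = 0
    placed = {lab: 0 for lab in pool}
    for k, label, count in sorted(placements):
        if label not in pool:
            raise InvalidValueError(f"unknown label {label!r}")
        if k > total or count > len(pool[label]):
            raise InvalidValueError(f"placement ({k}, {label}, {count}) infeasible")
        need = count - placed[label]
        free = [i for i in range(k) if slots[i] is None]
        if need < 0 or need > len(free):
            raise InvalidValueError(
                f"placement ({k}, {label}, {count}) infeasible given earlier constraints"
            )
        for i in rng.choice(len(free), size=need, replace=False):
            slots[free[i]] = label
        placed[label] = count
        prev_k = max(prev_k, k)

    # a constrained label's prefix count is exact, so unfilled prefix slots
    # may only take unconstrained labels
    constrained = {lab for _, lab, _ in placements}
    unconstrained_ids = [
        cid for lab in ("decoy", "agonist", "antagonist")
        if lab not in constrained for cid in pool[lab]
    ]
    rng.shuffle(unconstrained_ids)
    open_prefix = [i for i in range(prev_k) if slots[i] is None]
    if len(open_prefix) > len(unconstrained_ids):
        raise InvalidValueError("placements leave prefix slots that cannot be filled")

    queues = {lab: list(pool[lab]) for lab in pool}
    ids_out: list[str | None] = [None] * total
    fill = iter(unconstrained_ids)
    for i in range(prev_k):
        ids_out[i] = queues[slots[i]].pop(0) if slots[i] is not None else next(fill)
    tail = [c for c in list(fill) + [c for lab in constrained for c in queues[lab]]]
    rng.shuffle(tail)
    for i, cid in zip(range(prev_k, total), tail):
        ids_out[i] = cid
    return RankedScreen([c for c in ids_out if c is not None], labels)


def reference_screen(seed: int = 0) -> RankedScreen:
    """Synthetic stand-in for the contaminated 530-compound evaluation screen.

    The real ranking is not recoverable; this screen encodes only its
    published summary: 500 decoys plus 15 agonists and 15 antagonists,
    with 12 agonists in the top 13 and 4 antagonists in the top 19.
    """
    return generate_ranked_screen(
        500, 15, 15,
        placements=((13, "agonist", 12), (19, "antagonist", 4)),
        seed=seed,
    )


def random_rigid_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a random translation."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20.0, 20.0, size=3)
    return R, t


def generate_feature_cloud(
    model: PharmacophoreModel,
    transform: tuple[np.ndarray, np.ndarray] | None = None,
    jitter_sd: float = 0.0,
    extra_decoys: int = 0,
    seed: int = 0,
) -> list[PharmacophoreFeature]:
    """The model's features under a rigid transform, jittered, plus decoys.

    With ``jitter_sd`` = 0 a perfect match is guaranteed to exist.  Decoy
    features are random points of random type within the (transformed)
    model's bounding region, inflated by 10 A.
    """
    rng = np.random.default_rng(seed)
    if transform is None:
        R, t = random_rigid_transform(rng)
    else:
        R, t = transform
    out = []
    for f in model.features:
        pos = R @ f.xyz + t
        if jitter_sd > 0:
            pos = pos + rng.normal(0.0, jitter_sd, size=3)
        out.append(PharmacophoreFeature(f.kind, tuple(pos), f.radius))
    if extra_decoys:
        pts = np.array([f.xyz for f in out])
        lo, hi = pts.min(axis=0) - 10.0, pts.max(axis=0) + 10.0
        kinds = [f.kind for f in model.features]
        for _ in range(extra_decoys):
            pos = rng.uniform(lo, hi)
            kind = kinds[rng.integers(len(kinds))]
            out.append(PharmacophoreFeature(kind, tuple(pos), model.features[0].radius))
    return out
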