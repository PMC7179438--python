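"""3D pharmacophore model, rigid-body matching, and screen recovery metrics.

A pharmacophore is a small set of typed spheres (aromatic ring centres,
hydrogen-bond acceptors/donors, hydrophobes, ions) in 3D.  A candidate
feature cloud matches the model when some type-consistent one-to-one
assignment, after least-squares rigid superposition, places every model
feature within its own tolerance radius of its assigned candidate feature.

Ranked screening lists are scored by recovery: the fraction of labelled
agonists found in the best-ranked k compounds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import InvalidValueError

FEATURE_KINDS = ("aromatic", "h_acceptor", "h_donor", "hydrophobic", "cation", "anion")
SCREEN_LABELS = ("agonist", "antagonist", "decoy")


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: str
    position: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise InvalidValueError(f"unknown feature kind {self.kind!r}")
        if not self.radius > 0:
            raise InvalidValueError(f"radius must be positive, got {self.radius}")
        if not all(math.isfinite(c) for c in self.position):
            raise InvalidValueError("feature coordinates must be finite")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)


@dataclass
class PharmacophoreModel:
    features: list[PharmacophoreFeature]
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.features:
            raise InvalidValueError("a pharmacophore needs at least one feature")

    @classmethod
    def from_json(cls, path: str | Path) -> "PharmacophoreModel":
        payload = json.loads(Path(path).read_text())
        feats = [
            PharmacophoreFeature(f["kind"], tuple(f["xyz"]), f["radius"])
            for f in payload["features"]
        ]
        return cls(feats, payload.get("score"))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "score": self.score,
                    "features": [
                        {"kind": f.kind, "xyz": list(f.position), "radius": f.radius}
                        for f in self.features
                    ],
                },
                indent=2,
            )
        )


def superpose(
    points_a: Sequence[Sequence[float]], points_b: Sequence[Sequence[float]]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``points_b`` onto ``points_a``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ b + translation`` approximates ``a``; the rotation is
    proper (determinant +1).
    """
    A = np.asarray(points_a, dtype=float)
    B = np.asarray(points_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise InvalidValueError(f"point sets must both be (n, 3); got {A.shape} vs {B.shape}")
    if A.shape[0] < 3:
        raise InvalidValueError("superposition needs at least 3 points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    rot, rssd = Rotation.align_vectors(A - ca, B - cb)
    R = rot.as_matrix()
    t = ca - R @ cb
    rmsd = rssd / math.sqrt(A.shape[0])
    return R, t, float(rmsd)


@dataclass
class MatchResult:
    matched: bool
    assignment: dict[int, int] = field(default_factory=dict)
    rmsd: float = math.inf
    n_matched: int = 0


def _assignments(model_feats, cand_feats, model_d, cand_d):
    """Type-consistent injective assignments, pruned by pairwise distances."""
    by_kind: dict[str, list[int]] = {}
    for j, f in enumerate(cand_feats):
        by_kind.setdefault(f.kind, []).append(j)
    order = list(range(len(model_feats)))

    def extend(i: int, used: set[int], partial: list[int]):
        if i == len(order):
            yield list(partial)
            return
        mi = order[i]
        for j in by_kind.get(model_feats[mi].kind, []):
            if j in used:
                continue
            ok = True
            for prev_i, prev_j in zip(order[:i], partial):
                tol = model_feats[mi].radius + model_feats[prev_i].radius
                if abs(model_d[mi, prev_i] - cand_d[j, prev_j]) > tol:
                    ok = False
                    break
            if ok:
                used.add(j)
                partial.append(j)
                yield from extend(i + 1, used, partial)
                partial.pop()
                used.remove(j)

    yield from extend(0, set(), [])


def match(
    model: PharmacophoreModel,
    candidate_features: Sequence[PharmacophoreFeature],
    require_all: bool = True,
) -> MatchResult:
    """Search for the best rigid match of a candidate cloud to the model.

    Every type-consistent injective assignment that survives pairwise
    distance pruning is refined by superposition and accepted when each
    model feature lies within its own radius of its assigned candidate
    feature.  The accepted assignment with the lowest RMSD wins.  An
    unmatched result is a valid outcome, not an error.
    """
    if not require_all:
        raise NotImplementedError("partial matching is not supported")
    mfeats = model.features
    if len(candidate_features) < len(mfeats) or len(mfeats) < 3:
        return MatchResult(False)
    mpos = np.array([f.xyz for f in mfeats])
    cpos = np.array([f.xyz for f in candidate_features])
    model_d = np.linalg.norm(mpos[:, None] - mpos[None, :], axis=-1)
    cand_d = np.linalg.norm(cpos[:, None] - cpos[None, :], axis=-1)

    best = MatchResult(False)
    for assign in _assignments(mfeats, candidate_features, model_d, cand_d):
        R, t, rmsd = superpose(mpos, cpos[assign])
        moved = (R @ cpos[assign].T).T + t
        dists = np.linalg.norm(moved - mpos, axis=1)
        if all(d <= f.radius + 1e-9 for d, f in zip(dists, mfeats)):
            if rmsd < best.rmsd:
                best = MatchResult(
                    True, {i: j for i, j in enumerate(assign)}, rmsd, len(mfeats)
                )
    return best


@dataclass
class RankedScreen:
    """An ordered screening list with agonist/antagonist/decoy labels."""

    ids: list[str]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise InvalidValueError("screen ids must be unique")
        for cid in self.ids:
            if self.labels.get(cid) not in SCREEN_LABELS:
                raise InvalidValueError(f"compound {cid!r} lacks a valid label")

    def __len__(self) -> int:
        return len(self.ids)

    def count(self, label: str) -> int:
        return sum(1 for cid in self.ids if self.labels[cid] == label)


@dataclass
class RecoveryReport:
    k: int
    counts: dict[str, int]
    percent_actives_recovered: float


def recovery(screen: RankedScreen, k: int) -> RecoveryReport:
    """Label counts within the top-k and the percent of agonists recovered."""
    if not 0 <= k <= len(screen):
        raise InvalidValueError(f"k={k} out of range for screen of size {len(screen)}")
    counts = {label: 0 for label in SCREEN_LABELS}
    for cid in screen.ids[:k]:
        counts[screen.labels[cid]] += 1
    total_agonists = screen.count("agonist")
    percent = 100.0 * counts["agonist"] / total_agonists if total_agonists else 0.0
    return RecoveryReport(k, counts, percent)


def recovery_curve(screen: RankedScreen, ks: Iterable[int]) -> list[RecoveryReport]:
    return [recovery(screen, k) for k in ks]
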