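"""MM/GBSA energy bookkeeping and hydrogen-bond occupancy.

End-point binding free energies decompose as

    dG_bind = dE_MM + dG_solv - T*dS
    dE_MM   = dE_internal + dE_electrostatic + dE_vdW
    dG_solv = dG_GB + dG_SASA

so with the entropy term omitted the total is the plain sum of the van der
Waals, electrostatic, polar (GB) and non-polar (SASA) components.  The
per-residue decomposition sums the same four contributions per residue.
Standard errors of independent component means combine in quadrature.

A hydrogen bond holds in a frame when the donor-acceptor distance is at
most 3.5 A and the acceptor-H-donor angle is at least 120 degrees;
occupancy is the percentage of frames in which the bond holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import InvalidValueError


@dataclass(frozen=True)
class EnergyTerm:
    """A component mean with its standard error, kcal/mol."""

    mean: float
    sem: float = 0.0

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise InvalidValueError(f"sem must be non-negative, got {self.sem}")


@dataclass
class EnergyBreakdown:
    vdw: EnergyTerm
    ele: EnergyTerm
    gb: EnergyTerm
    np: EnergyTerm
    internal: EnergyTerm | None = None
    tds: EnergyTerm | None = None
    bind: EnergyTerm | None = None
    ligand: str = ""


def binding_energy(
    vdw: EnergyTerm,
    ele: EnergyTerm,
    gb: EnergyTerm,
    np: EnergyTerm,
    internal: EnergyTerm | None = None,
    tds: EnergyTerm | None = None,
    ligand: str = "",
) -> EnergyBreakdown:
    """Total binding free energy from its components.

    ``bind = vdw + ele + internal + gb + np - tds`` (absent optional terms
    contribute zero); SEMs combine in quadrature.
    """
    terms = [vdw, ele, gb, np]
    if internal is not None:
        terms.append(internal)
    mean = sum(t.mean for t in terms)
    var = sum(t.sem**2 for t in terms)
    if tds is not None:
        mean -= tds.mean
        var += tds.sem**2
    return EnergyBreakdown(
        vdw, ele, gb, np, internal, tds, EnergyTerm(mean, math.sqrt(var)), ligand
    )


@dataclass(frozen=True)
class PerResidueTerm:
    residue_id: str
    vdw: float
    elec: float
    pol: float
    np: float

    @property
    def total(self) -> float:
        return per_residue_total(self.vdw, self.elec, self.pol, self.np)


def per_residue_total(vdw: float, elec: float, pol: float, np: float) -> float:
    """Per-residue MM/GBSA contribution: vdW + electrostatic + polar + non-polar."""
    return vdw + elec + pol + np


@dataclass(frozen=True)
class HBondCriteria:
    max_donor_acceptor_distance: float = 3.5
    min_angle: float = 120.0

    def __post_init__(self) -> None:
        if not self.max_donor_acceptor_distance > 0:
            raise InvalidValueError("distance cutoff must be positive")
        if not 0 < self.min_angle <= 180:
            raise InvalidValueError("angle cutoff must be in (0, 180]")


def is_hbond(
    distance: float, angle: float, criteria: HBondCriteria = HBondCriteria()
) -> bool:
    """True when the distance and angle criteria both hold."""
    if not distance > 0:
        raise InvalidValueError(f"distance must be positive, got {distance}")
    if not 0 <= angle <= 180:
        raise InvalidValueError(f"angle must be in [0, 180], got {angle}")
    return distance <= criteria.max_donor_acceptor_distance and angle >= criteria.min_angle


def occupancy(frames: Iterable[bool]) -> float:
    """Percentage of frames in which the bond holds."""
    flags = list(frames)
    if not flags:
        raise InvalidValueError("occupancy needs at least one frame")
    return 100.0 * sum(bool(f) for f in flags) / len(flags)


def occupancy_from_frames(
    frames: Sequence[tuple[float, float]], criteria: HBondCriteria = HBondCriteria()
) -> float:
    """Occupancy straight from per-frame (distance, angle) pairs."""
    return occupancy(is_hbond(d, a, criteria) for d, a in frames)


def read_energy_table(path: str | Path) -> list[EnergyBreakdown]:
    """Read a per-ligand component table (mean/sem columns per term).

    The stored ``bind`` column is kept as-is so it can be checked against
    the recomputed sum.
    """
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(
            EnergyBreakdown(
                vdw=EnergyTerm(row["vdw_mean"], row["vdw_sem"]),
                ele=EnergyTerm(row["ele_mean"], row["ele_sem"]),
                gb=EnergyTerm(row["gb_mean"], row["gb_sem"]),
                np=EnergyTerm(row["np_mean"], row["np_sem"]),
                bind=EnergyTerm(row["bind_mean"], row["bind_sem"]),
                ligand=str(row["ligand"]),
            )
        )
    return out


def read_hbond_frames(path: str | Path) -> list[tuple[float, float]]:
    """Read a per-frame TSV with ``frame``, ``distance_A``, ``angle_deg`` columns."""
    df = pd.read_csv(path, sep="\t")
    return list(zip(df["distance_A"].astype(float), df["angle_deg"].astype(float)))
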