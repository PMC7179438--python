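"""Compound/descriptor/activity tables and their TSV/CSV serialisation.

The in-memory model is a :class:`DescriptorTable`: an ordered collection of
:class:`CompoundRecord` objects, each carrying an identifier, an optional
potency (EC50 in nM and/or pEC50 on the molar scale) and a named map of
molecular descriptors.  The canonical descriptor names are the field's
abbreviations:

====  =======================================
MV    molar volume (cubic angstroms)
MP    molecular polarizability
NA    number of atoms
PF    pharmacophore feature count
HG    hydrophobic group count
AR    aromatic ring count
====  =======================================

NA, PF, HG and AR are non-negative integer counts; MV and MP are positive
reals.  Readers accept case-insensitive aliases of these names and of the
bookkeeping columns (``compound_id``, ``code``, ``role``, ``ec50_nM``,
``pec50``).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import InvalidValueError, TableFormatError

#: canonical descriptor column order
CANONICAL_DESCRIPTORS = ("MV", "MP", "NA", "PF", "HG", "AR")
INTEGER_DESCRIPTORS = frozenset({"NA", "PF", "HG", "AR"})
POSITIVE_REAL_DESCRIPTORS = frozenset({"MV", "MP"})

ROLES = ("training", "test", "screening", "reference")

_META_COLUMNS = ("compound_id", "code", "role", "ec50_nM", "pec50")
_ALIASES = {c.lower(): c for c in _META_COLUMNS}
_ALIASES.update({c.lower(): c for c in CANONICAL_DESCRIPTORS})
_ALIASES["ec50"] = "ec50_nM"
_ALIASES["id"] = "compound_id"


@dataclass(frozen=True)
class FeatureCounts:
    """Per-molecule pharmacophore feature counts.

    The total feature count is the sum of hydrogen-bond donors and
    acceptors, cationic and anionic centres, aromatic rings and
    hydrophobic groups.
    """

    hbd: int = 0
    hba: int = 0
    cation: int = 0
    anion: int = 0
    ar: int = 0
    hg: int = 0

    def __post_init__(self) -> None:
        for name in ("hbd", "hba", "cation", "anion", "ar", "hg"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise InvalidValueError(
                    f"feature count {name!r} must be a non-negative integer, got {v!r}"
                )


def compute_pf(counts: FeatureCounts) -> int:
    """Total pharmacophore feature count: HBD + HBA + cation + anion + AR + HG."""
    return counts.hbd + counts.hba + counts.cation + counts.anion + counts.ar + counts.hg


@dataclass
class CompoundRecord:
    """One compound: identifiers, optional potency, named descriptors."""

    compound_id: str
    code: str = ""
    role: str = "training"
    ec50_nM: float | None = None
    pec50: float | None = None
    descriptors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise InvalidValueError(
                f"compound {self.compound_id!r}: unknown role {self.role!r}"
            )
        if self.ec50_nM is not None and not self.ec50_nM > 0:
            raise InvalidValueError(
                f"compound {self.compound_id!r}: EC50 must be positive, got {self.ec50_nM}"
            )
        if self.ec50_nM is not None and self.pec50 is not None:
            implied = round(9.0 - math.log10(self.ec50_nM), 5)
            if abs(implied - self.pec50) > 5e-6:
                raise InvalidValueError(
                    f"compound {self.compound_id!r}: pEC50 {self.pec50} inconsistent "
                    f"with EC50 {self.ec50_nM} nM (implies {implied})"
                )
        for name, value in self.descriptors.items():
            if name in INTEGER_DESCRIPTORS:
                if value < 0 or value != int(value):
                    raise InvalidValueError(
                        f"compound {self.compound_id!r}: descriptor {name} must be a "
                        f"non-negative integer, got {value}"
                    )
            elif name in POSITIVE_REAL_DESCRIPTORS and not value > 0:
                raise InvalidValueError(
                    f"compound {self.compound_id!r}: descriptor {name} must be positive, "
                    f"got {value}"
                )
            if not math.isfinite(value):
                raise InvalidValueError(
                    f"compound {self.compound_id!r}: descriptor {name} is not finite"
                )


@dataclass
class DescriptorTable:
    """Ordered compound records with a shared descriptor column set."""

    records: list[CompoundRecord]
    descriptor_names: list[str]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.compound_id in seen:
                raise TableFormatError(f"duplicate compound_id {rec.compound_id!r}")
            seen.add(rec.compound_id)
            missing = [n for n in self.descriptor_names if n not in rec.descriptors]
            if missing:
                raise TableFormatError(
                    f"compound {rec.compound_id!r} is missing descriptor(s) {missing}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    def get(self, compound_id: str) -> CompoundRecord:
        for rec in self.records:
            if rec.compound_id == compound_id:
                return rec
        raise KeyError(compound_id)

    def subset(self, ids: Iterable[str]) -> "DescriptorTable":
        """Rows restricted to ``ids``, input order preserved."""
        wanted = set(ids)
        unknown = wanted - set(self.ids)
        if unknown:
            raise KeyError(f"unknown compound ids: {sorted(unknown)}")
        return DescriptorTable(
            [r for r in self.records if r.compound_id in wanted],
            list(self.descriptor_names),
        )

    def drop(self, ids: Iterable[str]) -> "DescriptorTable":
        """Rows with ``ids`` removed, input order preserved."""
        dropped = set(ids)
        return DescriptorTable(
            [r for r in self.records if r.compound_id not in dropped],
            list(self.descriptor_names),
        )

    def activity(self, column: str = "pec50") -> list[float]:
        """Activity values for all rows; raises if any row lacks one."""
        out = []
        for rec in self.records:
            v = rec.pec50 if column == "pec50" else getattr(rec, column, None)
            if v is None:
                raise TableFormatError(
                    f"compound {rec.compound_id!r} has no {column} value"
                )
            out.append(float(v))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row: dict[str, object] = {
                "compound_id": rec.compound_id,
                "code": rec.code,
                "role": rec.role,
                "ec50_nM": rec.ec50_nM,
                "pec50": rec.pec50,
            }
            row.update({n: rec.descriptors[n] for n in self.descriptor_names})
            rows.append(row)
        return pd.DataFrame(rows, columns=list(_META_COLUMNS) + self.descriptor_names)


def _canonical_columns(columns: Sequence[str]) -> dict[str, str]:
    mapping = {}
    for col in columns:
        key = col.strip().lower()
        mapping[col] = _ALIASES.get(key, col.strip())
    return mapping


def read_compound_table(source: str | Path | io.TextIOBase, dialect: str = "tsv") -> DescriptorTable:
    """Read a compound table from a TSV/CSV path, text, or file object.

    The header must name an id column; ``code``, ``role``, ``ec50_nM`` and
    ``pec50`` are optional.  Every remaining column is treated as a
    descriptor.  Row order is preserved.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise InvalidValueError(f"unknown dialect {dialect!r}")
    if isinstance(source, str) and not source.strip():
        raise TableFormatError("empty table")
    if isinstance(source, str) and ("\n" in source or "\t" in source):
        buf: io.TextIOBase | Path = io.StringIO(source)
    elif isinstance(source, (str, Path)):
        buf = Path(source)
    else:
        buf = source
    try:
        df = pd.read_csv(buf, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError("empty table") from exc
    if df.empty:
        raise TableFormatError("table has a header but no rows")
    df = df.rename(columns=_canonical_columns(df.columns))
    if "compound_id" not in df.columns:
        raise TableFormatError("missing required column 'compound_id'")

    descriptor_names = [c for c in df.columns if c not in _META_COLUMNS]
    records = []
    for idx, row in df.iterrows():
        cid = str(row["compound_id"]).strip()
        if not cid:
            raise TableFormatError(f"row {idx}: empty compound_id")

        def _num(col: str, optional: bool = False) -> float | None:
            raw = str(row[col]).strip() if col in df.columns else ""
            if raw == "":
                if optional:
                    return None
                raise TableFormatError(f"row {idx} ({cid!r}): empty cell in column {col!r}")
            try:
                return float(raw)
            except ValueError as exc:
                raise TableFormatError(
                    f"row {idx} ({cid!r}): non-numeric value {raw!r} in column {col!r}"
                ) from exc

        try:
            rec = CompoundRecord(
                compound_id=cid,
                code=str(row.get("code", "")).strip(),
                role=str(row.get("role", "training")).strip() or "training",
                ec50_nM=_num("ec50_nM", optional=True) if "ec50_nM" in df.columns else None,
                pec50=_num("pec50", optional=True) if "pec50" in df.columns else None,
                descriptors={n: _num(n) for n in descriptor_names},
            )
        except InvalidValueError as exc:
            raise TableFormatError(str(exc)) from exc
        records.append(rec)
    return DescriptorTable(records, descriptor_names)


def write_compound_table(table: DescriptorTable, path: str | Path, dialect: str = "tsv") -> None:
    """Write ``table`` as TSV/CSV with the canonical column layout."""
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise InvalidValueError(f"unknown dialect {dialect!r}")
    df = table.to_dataframe()
    df.to_csv(path, sep=sep, index=False, na_rep="")
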