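"""Packaged study tables: compounds, published models, energies, pharmacophore.

All fixtures are small TSV/JSON files shipped with the package, holding the
published values of the study tables.  One cell is corrected relative to the
printed training table: the molar volume of compound 7 is 846.19 A^3 (the
printed descriptor table shows 846.90, but the stated MV range minimum, the
back-solved internal-validation predictions and the reported refit
statistics all require 846.19; see docs/methods.md).

The 530-compound evaluation screen is not recoverable and is provided as a
synthetic ranking consistent with the published summary counts
(:func:`a2aqsar.synthetic.reference_screen`).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .pharmacophore import PharmacophoreModel
from .tables import DescriptorTable, read_compound_table
from .validation import LinearModel

_DATA = resources.files("a2aqsar") / "data"


def _path(name: str) -> Path:
    with resources.as_file(_DATA / name) as p:
        return Path(p)


def load_training_table() -> DescriptorTable:
    """The 21 agonists with descriptors and activities (training set)."""
    return read_compound_table(_path("training_compounds.tsv"))


def load_test_table() -> DescriptorTable:
    """The 7 external-validation compounds."""
    return read_compound_table(_path("test_compounds.tsv"))


def load_screening_table() -> DescriptorTable:
    """The 6 virtual-screening hits (descriptors only, no measured EC50)."""
    return read_compound_table(_path("screening_compounds.tsv"))


def load_printed_models() -> dict:
    """Published model coefficients, reported statistics, outlier ids, cutoff."""
    return json.loads(_path("printed_models.json").read_text())


def load_linear_models() -> dict[str, LinearModel]:
    """The published tetra/penta/hexa models as :class:`LinearModel` objects."""
    payload = load_printed_models()
    return {
        name: LinearModel(entry["intercept"], entry["coefficients"], name)
        for name, entry in payload["models"].items()
    }


def training_outlier_ids() -> list[str]:
    """Compound ids excluded from the training fit (n goes 21 -> 16)."""
    return list(load_printed_models()["training_outliers"])


def activity_cutoff() -> float:
    """Screening activity cutoff: pEC50 of the weakest training compound."""
    return float(load_printed_models()["activity_cutoff"])


def load_pharmacophore_model() -> PharmacophoreModel:
    """Two aromatic (r = 1.1 A) and four H-acceptor (r = 0.5 A) features."""
    return PharmacophoreModel.from_json(_path("pharmacophore_model.json"))


def load_energy_table() -> pd.DataFrame:
    """Per-ligand MM/GBSA component means and SEMs with reported totals."""
    return pd.read_csv(_path("energy_components.tsv"), sep="\t")


def load_binding_affinity() -> pd.DataFrame:
    """Reference Ki values with the reported free energies."""
    return pd.read_csv(_path("binding_affinity.tsv"), sep="\t")


def load_hbond_occupancy() -> pd.DataFrame:
    """Reported H-bond occupancies and mean distances (reporting fixture)."""
    return pd.read_csv(_path("hbond_occupancy.tsv"), sep="\t")


def load_internal_validation_expected() -> pd.DataFrame:
    """Published per-compound training predictions and residuals."""
    return pd.read_csv(_path("internal_validation_expected.tsv"), sep="\t",
                       dtype={"compound_id": str})


def load_external_validation_expected() -> pd.DataFrame:
    """Published per-compound test-set predictions and residuals."""
    return pd.read_csv(_path("external_validation_expected.tsv"), sep="\t",
                       dtype={"compound_id": str})


def load_screening_predictions_expected() -> pd.DataFrame:
    """Published model predictions for the six screening hits."""
    return pd.read_csv(_path("screening_predictions_expected.tsv"), sep="\t",
                       dtype={"compound_id": str})
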