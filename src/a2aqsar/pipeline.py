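"""End-to-end orchestration: select -> fit -> validate -> screen -> enrich -> energetics.

A :class:`PipelineConfig` (defaults mirror the study settings: correlation
cutoff 0.5, subset sizes {4, 5, 6}, pinned outliers, activity cutoff
5.64936) drives the full analysis over the packaged fixtures or any
user-supplied tables, writing one file per stage plus a machine-readable
summary.  Runs are deterministic given config and seed.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import datasets
from .energetics import EnergyTerm, binding_energy
from .errors import QsarError
from .models import enumerate_models, fit_ols, rank_models, fit_with_outlier_removal
from .pharmacophore import recovery
from .selection import correlate_with_activity
from .synthetic import reference_screen
from .tables import read_compound_table
from .validation import residuals, screen

log = logging.getLogger("a2aqsar.pipeline")


@dataclass
class PipelineConfig:
    training_path: str | None = None    # None -> packaged fixture
    test_path: str | None = None
    screening_path: str | None = None
    energy_path: str | None = None
    activity_column: str = "pec50"
    correlation_cutoff: float = 0.5
    model_sizes: tuple[int, ...] = (4, 5, 6)
    outlier_mode: str = "pinned"        # "pinned" | "auto" | "none"
    pinned_outliers: tuple[str, ...] | None = None  # None -> packaged ids
    activity_cutoff: float | None = None            # None -> packaged cutoff
    recovery_ks: tuple[int, ...] = (13, 19)
    seed: int = 0
    output_dir: str = "qsar_out"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        cfg = cls(**payload)
        cfg.model_sizes = tuple(cfg.model_sizes)
        cfg.recovery_ks = tuple(cfg.recovery_ks)
        if cfg.pinned_outliers is not None:
            cfg.pinned_outliers = tuple(str(i) for i in cfg.pinned_outliers)
        return cfg


@dataclass
class RunReport:
    output_dir: Path
    files: dict[str, Path] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def _load(path: str | None, fallback):
    if path is None:
        return fallback()
    p = Path(path)
    if not p.exists():
        raise QsarError(f"input file not found: {p}")
    return read_compound_table(p)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage over the configured inputs; write per-stage outputs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(out)
    summary: dict = {"seed": config.seed}

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("load")
        training = _load(config.training_path, datasets.load_training_table)
        test = _load(config.test_path, datasets.load_test_table)
        screening = _load(config.screening_path, datasets.load_screening_table)
        log.info("rows: training=%d test=%d screening=%d",
                 len(training), len(test), len(screening))

        stage("select")
        corr = correlate_with_activity(training, config.activity_column,
                                       config.correlation_cutoff)
        (out / "correlation.json").write_text(json.dumps(corr.to_dict(), indent=2))
        report.files["correlation"] = out / "correlation.json"
        summary["selected_descriptors"] = corr.selected

        stage("fit")
        if config.outlier_mode == "pinned":
            pinned = config.pinned_outliers
            if pinned is None:
                pinned = tuple(datasets.training_outlier_ids())
            cleaned = training.drop(pinned)
            removed = sorted(pinned)
        elif config.outlier_mode == "none":
            cleaned, removed = training, []
        elif config.outlier_mode == "auto":
            cleaned, removed = None, None  # per-model removal below
        else:
            raise QsarError(f"unknown outlier mode {config.outlier_mode!r}")

        specs = enumerate_models(corr.selected, config.model_sizes)
        fitted = []
        for spec in specs:
            if config.outlier_mode == "auto":
                model = fit_with_outlier_removal(training, spec, config.activity_column)
            else:
                model = fit_ols(cleaned, spec, config.activity_column)
                model.removed_outliers = list(removed)
            fitted.append(model)
        ranked = rank_models(fitted)
        (out / "models.json").write_text(
            json.dumps([m.to_dict() for m in ranked], indent=2)
        )
        report.files["models"] = out / "models.json"
        summary["n_candidate_models"] = len(specs)
        summary["top_model"] = list(ranked[0].spec.descriptors)
        log.info("fitted %d candidate models", len(specs))

        stage("validate")
        printed = datasets.load_linear_models()
        for label, table in (("internal", cleaned if cleaned is not None else training),
                             ("external", test)):
            frames = []
            for name, model in printed.items():
                rep = residuals(model, table, config.activity_column, name)
                frame = rep.rows.rename(
                    columns={"predicted": name, "residual": f"{name}_residual"}
                )
                frames.append(frame.set_index(["compound_id", "experimental"]))
            merged = pd.concat(frames, axis=1).reset_index()
            path = out / f"{label}_validation.tsv"
            merged.to_csv(path, sep="\t", index=False)
            report.files[f"{label}_validation"] = path
            log.info("%s validation: %d rows", label, len(merged))

        stage("screen")
        cutoff = (config.activity_cutoff if config.activity_cutoff is not None
                  else datasets.activity_cutoff())
        decisions = screen(printed, screening, cutoff, decide_by="penta")
        rows = [
            {"compound_id": d.compound_id, **d.predictions,
             "active": d.active, "cutoff": d.cutoff}
            for d in decisions
        ]
        path = out / "screening_decisions.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        report.files["screening"] = path
        summary["actives"] = sorted(d.compound_id for d in decisions if d.active)

        stage("enrich")
        screen_fixture = reference_screen(seed=config.seed)
        enrich = {
            str(k): {
                "counts": recovery(screen_fixture, k).counts,
                "percent_actives_recovered":
                    recovery(screen_fixture, k).percent_actives_recovered,
            }
            for k in config.recovery_ks
        }
        (out / "enrichment.json").write_text(json.dumps(enrich, indent=2))
        report.files["enrichment"] = out / "enrichment.json"
        summary["enrichment"] = enrich

        stage("energetics")
        energy = (pd.read_csv(config.energy_path, sep="\t")
                  if config.energy_path else datasets.load_energy_table())
        erows = []
        for _, row in energy.iterrows():
            bd = binding_energy(
                EnergyTerm(row["vdw_mean"], row["vdw_sem"]),
                EnergyTerm(row["ele_mean"], row["ele_sem"]),
                EnergyTerm(row["gb_mean"], row["gb_sem"]),
                EnergyTerm(row["np_mean"], row["np_sem"]),
                ligand=str(row["ligand"]),
            )
            erows.append({
                "ligand": bd.ligand,
                "bind_mean_computed": round(bd.bind.mean, 6),
                "bind_sem_quadrature": round(bd.bind.sem, 6),
                "bind_mean_reported": row.get("bind_mean"),
            })
        path = out / "energetics.tsv"
        pd.DataFrame(erows).to_csv(path, sep="\t", index=False)
        report.files["energetics"] = path
        log.info("energetics: %d ligands", len(erows))

    except QsarError as exc:
        raise QsarError(f"pipeline failed: {exc}") from exc

    report.summary = summary
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    report.files["summary"] = out / "summary.json"
    return report


def configure_logging(verbose: bool = True) -> None:
    logging.basicConfig(stream=sys.stderr, level=logging.INFO if verbose else logging.WARNING,
                        format="%(name)s: %(message)s")
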