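"""Persist and reload a complete screening dataset as plain-text artifacts.

Every artifact uses a format the pipeline itself reads: CSV tables, msp
spectral libraries, and one YAML metadata file carrying the generator
configuration, sample roster and provenance (seed, config hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from pathlib import Path

import pandas as pd
import yaml

from .confidence import S9Detection
from .io_formats import read_spectra, read_table, write_spectra
from .ratios import ExcretionRecord
from .registry import SuspectEntry
from .synthetic import Dataset, GeneratorConfig, GroundTruth

_TABLES = (
    "calibration", "external_calibration", "ilis", "ilis_standards",
    "recovery", "standards", "flows",
)


def config_hash(config: GeneratorConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_dataset(dataset: Dataset, outdir: str | os.PathLike) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.features.to_csv(out / "features.csv", index=False)
    write_spectra(dataset.spectra, out / "spectra.msp")
    write_spectra(dataset.standard_spectra, out / "standard_spectra.msp")
    write_spectra(
        [d.ms2 for d in dataset.s9_detections], out / "s9_spectra.msp"
    )
    from .io_formats import suspects_to_table

    suspects_to_table(dataset.suspects).to_csv(out / "suspects.csv", index=False)
    for name in _TABLES:
        getattr(dataset, name).to_csv(out / f"{name}.csv", index=False)

    excretion_rows = []
    for record in dataset.excretion_records:
        excretion_rows.append(
            {
                "parent": record.parent.name,
                "compound": record.parent.name,
                "phase": "parent",
                "molar_fraction": record.parent_fraction,
                "mw": record.parent.monoisotopic_mass,
                "back_cleavable": False,
            }
        )
        for met, fraction, cleavable in record.metabolite_fractions:
            excretion_rows.append(
                {
                    "parent": record.parent.name,
                    "compound": met.name,
                    "phase": met.phase,
                    "molar_fraction": fraction,
                    "mw": met.monoisotopic_mass,
                    "back_cleavable": cleavable,
                }
            )
    pd.DataFrame(excretion_rows).to_csv(out / "excretion.csv", index=False)

    meta = {
        "config": dataclasses.asdict(dataset.config),
        "config_hash": config_hash(dataset.config),
        "seed": dataset.config.seed,
        "sample_ids": dataset.sample_ids,
        "blank_ids": dataset.blank_ids,
        "populations": dataset.populations,
        "population_reference": dataset.population_reference,
    }
    with open(out / "meta.yaml", "w", encoding="utf-8") as handle:
        yaml.safe_dump(meta, handle, sort_keys=True)

    gt_dir = out / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    gt = dataset.ground_truth
    gt.compounds.to_csv(gt_dir / "compounds.csv", index=False)
    gt.concentrations.to_csv(gt_dir / "concentrations.csv", index=False)
    gt.feature_ledger.to_csv(gt_dir / "feature_ledger.csv", index=False)
    gt_meta = {
        "rt_slope": gt.rt_slope,
        "rt_intercept": gt.rt_intercept,
        "rt_noise_sd": gt.rt_noise_sd,
        "suppression_plant": gt.suppression_plant,
        "suppression_factor": gt.suppression_factor,
        "sewer_loss_factor": gt.sewer_loss_factor,
        "consumption_kg_yr": gt.consumption_kg_yr,
        "ms2_sources": gt.ms2_sources,
    }
    with open(gt_dir / "truth.yaml", "w", encoding="utf-8") as handle:
        yaml.safe_dump(gt_meta, handle, sort_keys=True)


def load_dataset(indir: str | os.PathLike) -> Dataset:
    src = Path(indir)
    with open(src / "meta.yaml", encoding="utf-8") as handle:
        meta = yaml.safe_load(handle)
    cfg = meta["config"]
    for key, value in cfg.items():
        if isinstance(value, list):
            cfg[key] = tuple(value)
    config = GeneratorConfig(**cfg)

    from .io_formats import suspects_from_table

    suspects = suspects_from_table(read_table(src / "suspects.csv", "suspects"))
    by_name = {s.name: s for s in suspects}

    features = read_table(src / "features.csv", "features")
    spectra = read_spectra(src / "spectra.msp")
    standard_spectra = (
        read_spectra(src / "standard_spectra.msp")
        if (src / "standard_spectra.msp").stat().st_size
        else []
    )
    s9_spectra = (
        read_spectra(src / "s9_spectra.msp")
        if (src / "s9_spectra.msp").stat().st_size
        else []
    )
    s9_detections = [
        S9Detection(
            compound=sp.identifier.removeprefix("S9_"),
            mz=sp.precursor_mz,
            rt=sp.rt,
            ms2=sp,
        )
        for sp in s9_spectra
    ]

    tables = {name: pd.read_csv(src / f"{name}.csv") for name in _TABLES}

    excretion = read_table(src / "excretion.csv", "excretion")
    records = []
    for parent_name, grp in excretion.groupby("parent", sort=True):
        parent = by_name[parent_name]
        parent_fraction = None
        met_fracs = []
        for r in grp.itertuples(index=False):
            if r.compound == parent_name:
                parent_fraction = float(r.molar_fraction)
            else:
                met_fracs.append(
                    (by_name[r.compound], float(r.molar_fraction),
                     bool(r.back_cleavable))
                )
        records.append(
            ExcretionRecord(
                parent=parent,
                parent_fraction=parent_fraction,
                metabolite_fractions=met_fracs,
            )
        )

    gt_dir = src / "ground_truth"
    ground_truth = None
    if gt_dir.exists():
        with open(gt_dir / "truth.yaml", encoding="utf-8") as handle:
            gt_meta = yaml.safe_load(handle)
        ground_truth = GroundTruth(
            compounds=pd.read_csv(gt_dir / "compounds.csv"),
            concentrations=pd.read_csv(gt_dir / "concentrations.csv"),
            feature_ledger=pd.read_csv(gt_dir / "feature_ledger.csv"),
            **gt_meta,
        )

    return Dataset(
        config=config,
        suspects=suspects,
        features=features,
        spectra=spectra,
        calibration=tables["calibration"],
        external_calibration=tables["external_calibration"],
        ilis=tables["ilis"],
        ilis_standards=tables["ilis_standards"],
        recovery=tables["recovery"],
        standards=tables["standards"],
        standard_spectra=standard_spectra,
        s9_detections=s9_detections,
        excretion_records=records,
        flows=tables["flows"],
        populations={str(k): float(v) for k, v in meta["populations"].items()},
        population_reference=float(meta["population_reference"]),
        sample_ids=list(meta["sample_ids"]),
        blank_ids=list(meta["blank_ids"]),
        ground_truth=ground_truth,
    )
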