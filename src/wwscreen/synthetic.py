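"""Synthetic suspect-screening datasets with planted ground truth.

The generator emulates the structure of an influent-wastewater LC-HRMS/MS
screening campaign over several treatment plants and sampling days: parent
pharmaceuticals and their metabolites appear as monoisotopic ion features
with carbon-isotopologue and sodium-adduct satellites, retention times are
linear in logD with Gaussian scatter, intensities are log-normal (so the
intensity filter bites on a known subset), MS2 spectra are emitted
preferentially for intense features and share direct and mass-shifted
fragments between parent and metabolite, blanks carry background features,
and isobaric decoys sit within a few ppm of suspect masses but at displaced
retention times with unrelated MS2.  Concentrations derive from planted
per-parent consumption figures, plant flows and excretion fractions, so
quantification and consumption back-calculation have an exact truth to
recover.  All randomness flows from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .confidence import S9Detection
from .constants import C13_ABUNDANCE, C13_DELTA, PROTON_MASS
from .io_formats import Spectrum
from .registry import (
    SuspectEntry,
    apply_biotransformation,
    monoisotopic_mass,
    parse_formula,
)
from .ratios import ExcretionRecord

_PHASE1 = ("hydroxylation", "demethylation", "carboxylation", "deacetylation")
_PHASE2 = ("glucuronidation", "sulfation")


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic screening campaign."""

    seed: int
    n_parents: int = 50
    metabolites_per_parent: int = 3
    n_plants: int = 3
    n_days: int = 5
    n_blanks: int = 2
    # chromatography: RT = slope * logD + intercept + N(0, sd), 0-34 min run
    rt_slope: float = 3.0
    rt_intercept: float = 5.0
    rt_noise_sd: float = 0.2
    rt_jitter_sd: float = 0.05  # per-sample RT reproducibility
    run_window: tuple[float, float] = (0.0, 34.0)
    # intensities
    response_factor_median: float = 2500.0  # counts per ng/L
    response_factor_sigma: float = 0.7
    response_noise_cv: float = 0.05
    intensity_floor: float = 500.0  # detection limit, counts
    mz_noise_ppm: float = 0.5
    adduct_prob: float = 0.5
    # MS2 emission and fragment sharing
    ms2_fraction: float = 0.35
    shared_fragment_fraction: float = 0.35
    shifted_fragment_fraction: float = 0.35
    fragment_range: tuple[int, int] = (8, 14)
    # decoys and background
    decoy_rate: float = 0.10
    n_background: int = 30
    background_suspect_fraction: float = 0.5
    background_ms2_prob: float = 0.5
    # matrix effects
    suppression_plant_index: int = 2  # 0-based; the third plant
    suppression_factor: float = 0.5
    # quantification
    n_ilis: int = 10
    ilis_spike_conc: float = 500.0  # ng/L
    calibration_levels: tuple[float, ...] = (10.0, 50.0, 100.0, 250.0, 500.0, 1000.0)
    calibration_noise_cv: float = 0.01
    standard_fraction: float = 0.4  # compounds with a reference standard
    s9_fraction: float = 0.5  # unconfirmed metabolites with an S9 detection
    n_external_calibrated: int = 4  # semiquantified via external curves
    # consumption / WBE
    consumption_median_kg_yr: float = 75.0
    consumption_sigma: float = 1.0
    flow_median_L_day: float = 2e7
    flow_sigma: float = 0.1
    populations: tuple[float, ...] = (8e4, 1e5, 1.2e5)
    population_reference: float = 1e6
    sewer_loss_factor: float = 1.0  # <1 = in-sewer metabolite degradation

    def __post_init__(self) -> None:
        for name in (
            "ms2_fraction", "shared_fragment_fraction",
            "shifted_fragment_fraction", "decoy_rate",
            "background_suspect_fraction", "background_ms2_prob",
            "adduct_prob", "standard_fraction", "s9_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.shared_fragment_fraction + self.shifted_fragment_fraction > 1.0:
            raise ValueError("shared + shifted fragment fractions exceed 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if len(self.populations) < self.n_plants:
            raise ValueError("need one population per plant")


@dataclass
class GroundTruth:
    """Everything the generator planted, for oracle-style checks."""

    compounds: pd.DataFrame  # one row per planted compound / decoy
    concentrations: pd.DataFrame  # compound, sample_id, conc_ng_L
    feature_ledger: pd.DataFrame  # every emitted feature with its source
    rt_slope: float
    rt_intercept: float
    rt_noise_sd: float
    suppression_plant: str
    suppression_factor: float
    sewer_loss_factor: float
    consumption_kg_yr: dict[str, float]
    ms2_sources: dict[str, str]  # spectrum id -> compound name


@dataclass
class Dataset:
    """All artifacts of one synthetic campaign."""

    config: GeneratorConfig
    suspects: list[SuspectEntry]
    features: pd.DataFrame  # io_formats "features" schema
    spectra: list[Spectrum]
    calibration: pd.DataFrame  # analyte, level_conc, analyte_area, ilis_area
    external_calibration: pd.DataFrame  # analyte, level_conc, analyte_area
    ilis: pd.DataFrame  # ilis_id, mz, rt, spike_conc
    ilis_standards: pd.DataFrame  # ilis_id, intensity (in calibration standards)
    recovery: pd.DataFrame  # target, ilis_id, relative_recovery
    standards: pd.DataFrame  # compound, rt; reference-standard RTs
    standard_spectra: list[Spectrum]
    s9_detections: list[S9Detection]
    excretion_records: list[ExcretionRecord]
    flows: pd.DataFrame  # plant, day, flow_L_day
    populations: dict[str, float]
    population_reference: float
    sample_ids: list[str]
    blank_ids: list[str]
    ground_truth: GroundTruth


def _random_parent_formula(rng: np.random.Generator) -> str:
    """Random small-molecule formula with an [M+H]+ between 150 and 800."""
    while True:
        c = int(rng.integers(10, 25))
        h = int(rng.integers(int(1.0 * c), int(1.7 * c) + 1))
        n = int(rng.integers(0, 4))
        o = int(rng.integers(1, 6))
        s = int(rng.integers(0, 2))
        parts = {"C": c, "H": h, "N": n, "O": o, "S": s}
        formula = "".join(
            f"{el}{cnt}" if cnt > 1 else el for el, cnt in parts.items() if cnt > 0
        )
        mz = monoisotopic_mass(formula) + PROTON_MASS
        if 150.0 <= mz <= 800.0:
            return formula


def _fragment_grid(rng: np.random.Generator, n: int, lo: float, hi: float) -> list[float]:
    """Distinct fragment m/z values on a 0.01 Da grid."""
    values: set[float] = set()
    while len(values) < n:
        values.add(round(float(rng.uniform(lo, hi)), 2))
    return sorted(values)


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Generate one complete synthetic campaign; reproducible given the seed."""
    rng = np.random.default_rng(config.seed)
    plants = [f"P{i + 1}" for i in range(config.n_plants)]
    samples = [f"{p}_D{d + 1}" for p in plants for d in range(config.n_days)]
    blanks = [f"BLANK{i + 1}" for i in range(config.n_blanks)]
    suppression_plant = plants[config.suppression_plant_index]

    def plant_of(sample: str) -> str:
        return sample.split("_")[0]

    def suppression(sample: str) -> float:
        return (
            config.suppression_factor
            if plant_of(sample) == suppression_plant
            else 1.0
        )

    # --- suspect list -----------------------------------------------------
    suspects: list[SuspectEntry] = []
    compound_rows: list[dict] = []
    excretion_records: list[ExcretionRecord] = []
    parents: list[SuspectEntry] = []
    children_of: dict[str, list[tuple[SuspectEntry, bool]]] = {}

    for p_idx in range(config.n_parents):
        name = f"parent{p_idx + 1:03d}"
        formula = _random_parent_formula(rng)
        logd = float(rng.uniform(1.5, 7.8))
        parent = SuspectEntry(
            name=name, formula=formula, phase="parent", logD_pos=logd,
        )
        parents.append(parent)
        children: list[tuple[SuspectEntry, bool]] = []
        counts = parse_formula(formula)
        applicable = [t for t in _PHASE1 + _PHASE2]
        # glucuronidation must stay below the m/z 1000 scan limit
        if parent.monoisotopic_mass + PROTON_MASS + 176.0321 > 1000:
            applicable.remove("glucuronidation")
        if counts.get("C", 0) < 3:
            applicable = [t for t in applicable if t not in
                          ("demethylation", "deacetylation")]
        k = min(config.metabolites_per_parent, len(applicable))
        chosen = list(rng.choice(applicable, size=k, replace=False))
        for t in chosen:
            try:
                child = apply_biotransformation(parent, t)
            except ValueError:
                continue
            child.logD_pos = max(0.0, parent.logD_pos - float(rng.uniform(0.3, 1.5)))
            children.append((child, t in _PHASE2))
        children_of[name] = children
        suspects.append(parent)
        suspects.extend(child for child, _ in children)

        f_parent = float(rng.uniform(0.05, 0.5))
        budget = float(rng.uniform(0.2, 0.9)) * (1.0 - f_parent)
        if children:
            shares = rng.dirichlet(np.ones(len(children)))
            met_fracs = [
                (child, float(budget * share),
                 is_p2 and bool(rng.random() < 0.7))
                for (child, is_p2), share in zip(children, shares)
            ]
        else:
            met_fracs = []
        parent.excretion_fraction = f_parent
        for child, frac, _ in met_fracs:
            child.excretion_fraction = frac
        excretion_records.append(
            ExcretionRecord(
                parent=parent,
                parent_fraction=f_parent,
                metabolite_fractions=met_fracs,
            )
        )

    # --- consumption, flows, concentrations -------------------------------
    consumption = {
        p.name: float(
            rng.lognormal(np.log(config.consumption_median_kg_yr),
                          config.consumption_sigma)
        )
        for p in parents
    }
    flows_rows = []
    flow_map: dict[tuple[str, int], float] = {}
    for plant in plants:
        for day in range(1, config.n_days + 1):
            flow = float(
                rng.lognormal(np.log(config.flow_median_L_day), config.flow_sigma)
            )
            flows_rows.append({"plant": plant, "day": day, "flow_L_day": flow})
            flow_map[(plant, day)] = flow
    populations = {p: float(config.populations[i]) for i, p in enumerate(plants)}

    conc_rows = []
    conc_map: dict[tuple[str, str], float] = {}
    for record in excretion_records:
        parent = record.parent
        dose_g_day = consumption[parent.name] * 1000.0 / 365.0
        analytes = [(parent, parent.excretion_fraction, False)] + [
            (child, frac, True) for child, frac, _ in record.metabolite_fractions
        ]
        for entry, fraction, is_met in analytes:
            mw_ratio = entry.monoisotopic_mass / parent.monoisotopic_mass
            loss = config.sewer_loss_factor if is_met else 1.0
            for sample in samples:
                plant = plant_of(sample)
                day = int(sample.split("_D")[1])
                conc = (
                    dose_g_day * fraction * mw_ratio * loss
                    * (populations[plant] / config.population_reference)
                    / flow_map[(plant, day)] * 1e9
                )
                conc_rows.append(
                    {"compound": entry.name, "sample_id": sample,
                     "conc_ng_L": conc}
                )
                conc_map[(entry.name, sample)] = conc

    # --- per-compound measurement properties ------------------------------
    rf = {
        s.name: float(
            rng.lognormal(np.log(config.response_factor_median),
                          config.response_factor_sigma)
        )
        for s in suspects
    }
    true_rt = {
        s.name: config.rt_slope * s.logD_pos + config.rt_intercept
        + float(rng.normal(0.0, config.rt_noise_sd))
        for s in suspects
    }
    rating = {s.name: float(rng.uniform(3.0, 10.0)) for s in suspects}
    has_adduct = {s.name: bool(rng.random() < config.adduct_prob) for s in suspects}
    adduct_ratio = {s.name: float(rng.uniform(0.05, 0.3)) for s in suspects}
    carbon = {s.name: parse_formula(s.formula).get("C", 0) for s in suspects}
    mz_mh = {s.name: s.monoisotopic_mass + PROTON_MASS for s in suspects}

    # reference standards for a subset; targets are the standards
    has_standard = {
        s.name: bool(rng.random() < config.standard_fraction) for s in suspects
    }
    # analyte preparation recovery: applied to targets only (corrected later);
    # semiquantified compounds are simulated without preparation losses
    prep_recovery = {
        s.name: float(rng.uniform(0.70, 1.00)) if has_standard[s.name] else 1.0
        for s in suspects
    }

    # --- features ---------------------------------------------------------
    feature_rows: list[dict] = []
    ledger_rows: list[dict] = []

    def emit(sample: str, mz: float, rt: float, intensity: float,
             rate: float, source: str, role: str) -> None:
        if intensity < config.intensity_floor:
            return
        row = {
            "sample_id": sample,
            "mz": round(mz, 6),
            "rt": round(rt, 4),
            "intensity": round(intensity, 2),
            "peak_rating": round(rate, 2),
        }
        feature_rows.append(row)
        ledger_rows.append({**row, "source": source, "role": role})

    def noise() -> float:
        return float(np.exp(rng.normal(0.0, config.response_noise_cv)))

    def mz_jitter(mz: float) -> float:
        return mz * (1.0 + rng.normal(0.0, config.mz_noise_ppm) * 1e-6)

    for s in suspects:
        name = s.name
        for sample in samples:
            conc = conc_map[(name, sample)]
            base = rf[name] * conc * suppression(sample) * prep_recovery[name]
            inten = base * noise()
            rt_s = true_rt[name] + float(rng.normal(0.0, config.rt_jitter_sd))
            emit(sample, mz_jitter(mz_mh[name]), rt_s, inten,
                 rating[name], name, "mono")
            iso = inten * C13_ABUNDANCE * carbon[name] * noise()
            emit(sample, mz_jitter(mz_mh[name] + C13_DELTA),
                 rt_s + float(rng.normal(0.0, 0.01)), iso,
                 rating[name], name, "isotopologue")
            if has_adduct[name]:
                na_mz = s.monoisotopic_mass + 22.989221
                emit(sample, mz_jitter(na_mz), rt_s + float(rng.normal(0.0, 0.01)),
                     inten * adduct_ratio[name] * noise(),
                     rating[name], name, "adduct")

    # --- decoys -----------------------------------------------------------
    n_decoys = int(round(config.decoy_rate * len(suspects)))
    decoy_targets = list(rng.choice(len(suspects), size=n_decoys, replace=False))
    decoys: list[dict] = []
    for d_idx, s_idx in enumerate(decoy_targets):
        target = suspects[int(s_idx)]
        name = f"decoy{d_idx + 1:03d}"
        mz = mz_mh[target.name] * (1.0 + float(rng.uniform(-4, 4)) * 1e-6)
        predicted = config.rt_slope * target.logD_pos + config.rt_intercept
        offset = float(rng.uniform(2.5, 6.0))
        lo_ok = predicted - offset >= 4.3
        hi_ok = predicted + offset <= 29.7
        if lo_ok and hi_ok:
            sign = 1.0 if rng.random() < 0.5 else -1.0
        elif lo_ok:
            sign = -1.0
        else:
            sign = 1.0
        rt = predicted + sign * offset
        base = max(float(rng.lognormal(np.log(5e5), 0.8)), 2e5)
        rate = float(rng.uniform(6.0, 10.0))
        decoys.append(
            {"name": name, "target": target.name, "mz": mz, "rt": rt,
             "intensity": base, "rating": rate}
        )
        for sample in samples:
            emit(sample, mz_jitter(mz),
                 rt + float(rng.normal(0.0, config.rt_jitter_sd)),
                 base * suppression(sample) * noise(), rate, name, "decoy")

    # --- blank / background features --------------------------------------
    backgrounds: list[dict] = []
    for b_idx in range(config.n_background):
        name = f"background{b_idx + 1:03d}"
        if rng.random() < config.background_suspect_fraction and suspects:
            target = suspects[int(rng.integers(0, len(suspects)))]
            mz = mz_mh[target.name] * (1.0 + float(rng.uniform(-4, 4)) * 1e-6)
        else:
            mz = float(rng.uniform(100.0, 1000.0))
        rt = float(rng.uniform(1.0, 33.0))
        base = float(rng.lognormal(np.log(3e5), 0.6))
        rate = float(rng.uniform(2.0, 9.0))
        ms2 = bool(rng.random() < config.background_ms2_prob)
        backgrounds.append(
            {"name": name, "mz": mz, "rt": rt, "intensity": base,
             "rating": rate, "ms2": ms2}
        )
        sample_scale = float(rng.uniform(0.3, 3.0))
        for blank in blanks:
            emit(blank, mz_jitter(mz),
                 rt + float(rng.normal(0.0, config.rt_jitter_sd)),
                 base * noise(), rate, name, "background")
        for sample in samples:
            emit(sample, mz_jitter(mz),
                 rt + float(rng.normal(0.0, config.rt_jitter_sd)),
                 base * sample_scale * noise(), rate, name, "background")

    # --- ILIS -------------------------------------------------------------
    ilis_rows = []
    ilis_std_rows = []
    ilis_rt = {}
    rf_ilis = {}
    for i_idx in range(config.n_ilis):
        ilis_id = f"ILIS{i_idx + 1:02d}"
        mz = float(rng.uniform(150.0, 800.0))
        rt = float(rng.uniform(5.0, 29.0))
        ilis_rt[ilis_id] = rt
        rf_ilis[ilis_id] = float(
            rng.lognormal(np.log(config.response_factor_median), 0.3)
        )
        ilis_rows.append(
            {"ilis_id": ilis_id, "mz": mz, "rt": rt,
             "spike_conc": config.ilis_spike_conc}
        )
        ilis_std_rows.append(
            {"ilis_id": ilis_id,
             "intensity": rf_ilis[ilis_id] * config.ilis_spike_conc}
        )
        for sample in samples:
            inten = (
                rf_ilis[ilis_id] * config.ilis_spike_conc
                * suppression(sample) * noise()
            )
            emit(sample, mz_jitter(mz),
                 rt + float(rng.normal(0.0, config.rt_jitter_sd)),
                 inten, 9.5, ilis_id, "ilis")

    # relative recoveries from the spike experiment: analyte recovery over
    # ILIS recovery (ILIS taken to recover fully), in percent
    recovery_rows = []
    for s in suspects:
        if not has_standard[s.name]:
            continue
        for ilis_id in ilis_rt:
            recovery_rows.append(
                {
                    "target": s.name,
                    "ilis_id": ilis_id,
                    "relative_recovery": prep_recovery[s.name] * 100.0
                    * float(np.exp(rng.normal(0.0, 0.01))),
                }
            )

    # --- calibration series ------------------------------------------------
    cal_rows = []
    ext_rows = []
    # assign each target the ILIS nearest in RT for its calibration series
    for s in suspects:
        if not has_standard[s.name]:
            continue
        nearest = min(ilis_rt, key=lambda i: abs(ilis_rt[i] - true_rt[s.name]))
        ilis_area = rf_ilis[nearest] * config.ilis_spike_conc
        for conc in config.calibration_levels:
            cal_rows.append(
                {
                    "analyte": s.name,
                    "level_conc": conc,
                    "analyte_area": rf[s.name] * conc
                    * float(np.exp(rng.normal(0.0, config.calibration_noise_cv))),
                    "ilis_area": ilis_area
                    * float(np.exp(rng.normal(0.0, config.calibration_noise_cv))),
                }
            )
    # external (ultrapure water) curves for a few unconfirmed metabolites
    unconfirmed = [
        s for s in suspects
        if not has_standard[s.name] and s.phase != "parent"
    ]
    ext_set = [s.name for s in unconfirmed[: config.n_external_calibrated]]
    for name in ext_set:
        for conc in config.calibration_levels:
            ext_rows.append(
                {
                    "analyte": name,
                    "level_conc": conc,
                    "analyte_area": rf[name] * conc
                    * float(np.exp(rng.normal(0.0, config.calibration_noise_cv))),
                }
            )

    # --- MS2 spectra --------------------------------------------------------
    # emission probability increases with intensity; overall rate matches
    # the configured fraction
    max_intensity = {}
    for row in ledger_rows:
        if row["role"] == "mono":
            max_intensity[row["source"]] = max(
                max_intensity.get(row["source"], 0.0), row["intensity"]
            )
    planted_names = [s.name for s in suspects if s.name in max_intensity]
    log_i = np.array([np.log10(max_intensity[n]) for n in planted_names])
    cutoff = float(np.quantile(log_i, 1.0 - config.ms2_fraction)) if len(log_i) else 0.0
    ms2_emitted = {}
    for n in planted_names:
        if config.ms2_fraction >= 0.999:
            p = 1.0
        elif config.ms2_fraction <= 0.001:
            p = 0.0
        else:
            p = 1.0 / (1.0 + np.exp(-(np.log10(max_intensity[n]) - cutoff) / 0.25))
        ms2_emitted[n] = bool(rng.random() < p)

    spectra: list[Spectrum] = []
    ms2_sources: dict[str, str] = {}
    parent_fragments: dict[str, list[tuple[float, float]]] = {}

    def fragment_list(precursor: float, n: int) -> list[tuple[float, float]]:
        mzs = _fragment_grid(rng, n, 53.0, max(60.0, precursor - 12.0))
        return [(mz, float(rng.uniform(0.1, 1.0)) * 1e4) for mz in mzs]

    for p in parents:
        n_frag = int(rng.integers(*config.fragment_range))
        parent_fragments[p.name] = fragment_list(mz_mh[p.name], n_frag)

    spectrum_index = 0

    def add_spectrum(name: str, precursor: float, rt: float,
                     peaks: list[tuple[float, float]]) -> Spectrum:
        nonlocal spectrum_index
        spectrum_index += 1
        sp = Spectrum(
            identifier=f"MS2_{spectrum_index:04d}",
            precursor_mz=round(precursor, 5),
            polarity="positive",
            rt=round(rt, 3),
            peaks=[(round(mz, 5), round(inten, 3)) for mz, inten in peaks],
        )
        spectra.append(sp)
        ms2_sources[sp.identifier] = name
        return sp

    metabolite_peaks: dict[str, list[tuple[float, float]]] = {}
    for p in parents:
        if ms2_emitted.get(p.name):
            add_spectrum(p.name, mz_mh[p.name], true_rt[p.name],
                         parent_fragments[p.name])
        for child, _ in children_of[p.name]:
            frags = parent_fragments[p.name]
            n = len(frags)
            n_shared = int(round(config.shared_fragment_fraction * n))
            n_shifted = int(round(config.shifted_fragment_fraction * n))
            order = rng.permutation(n)
            shift = mz_mh[child.name] - mz_mh[p.name]
            peaks: list[tuple[float, float]] = []
            for pos in order[:n_shared]:
                peaks.append(frags[pos])
            for pos in order[n_shared:n_shared + n_shifted]:
                mz = frags[pos][0] + shift
                if 50.0 < mz < mz_mh[child.name] - 5.0:
                    peaks.append((mz, frags[pos][1]))
            n_unique = n - len(peaks)
            if n_unique > 0:
                peaks.extend(fragment_list(mz_mh[child.name], n_unique))
            peaks = sorted(set(peaks))
            metabolite_peaks[child.name] = peaks
            if ms2_emitted.get(child.name):
                add_spectrum(child.name, mz_mh[child.name],
                             true_rt[child.name], peaks)

    for decoy in decoys:
        n_frag = int(rng.integers(*config.fragment_range))
        add_spectrum(decoy["name"], decoy["mz"], decoy["rt"],
                     fragment_list(decoy["mz"], n_frag))
        ms2_emitted[decoy["name"]] = True
    for bg in backgrounds:
        if bg["ms2"] and bg["mz"] > 80.0:
            n_frag = int(rng.integers(*config.fragment_range))
            add_spectrum(bg["name"], bg["mz"], bg["rt"],
                         fragment_list(bg["mz"], n_frag))
        ms2_emitted[bg["name"]] = bool(bg["ms2"])

    # --- reference standards and S9 runs -----------------------------------
    def perturb(peaks: list[tuple[float, float]]) -> list[tuple[float, float]]:
        return [
            (mz, inten * float(np.exp(rng.normal(0.0, 0.1))))
            for mz, inten in peaks
        ]

    standard_rows = []
    standard_spectra = []
    for s in suspects:
        if not has_standard[s.name]:
            continue
        peaks = (
            parent_fragments.get(s.name) or metabolite_peaks.get(s.name) or []
        )
        rt_std = true_rt[s.name] + float(rng.normal(0.0, 0.05))
        standard_rows.append({"compound": s.name, "rt": rt_std})
        if peaks:
            sp = Spectrum(
                identifier=f"STD_{s.name}",
                precursor_mz=round(mz_mh[s.name], 5),
                polarity="positive",
                rt=round(rt_std, 3),
                peaks=[(round(mz, 5), round(i, 3)) for mz, i in perturb(peaks)],
            )
            standard_spectra.append(sp)

    s9_detections = []
    for p in parents:
        for child, _ in children_of[p.name]:
            if has_standard[child.name] or not ms2_emitted.get(child.name):
                continue
            if rng.random() >= config.s9_fraction:
                continue
            peaks = perturb(metabolite_peaks[child.name])
            sp = Spectrum(
                identifier=f"S9_{child.name}",
                precursor_mz=round(mz_mh[child.name] * (1 + rng.normal(0, 1e-6)), 5),
                polarity="positive",
                rt=round(true_rt[child.name] + float(rng.normal(0.0, 0.1)), 3),
                peaks=[(round(mz, 5), round(i, 3)) for mz, i in peaks],
            )
            s9_detections.append(
                S9Detection(
                    compound=child.name,
                    mz=sp.precursor_mz,
                    rt=sp.rt,
                    ms2=sp,
                )
            )

    # --- assemble -----------------------------------------------------------
    def compound_row(name: str, kind: str, **extra) -> dict:
        return {"name": name, "kind": kind, **extra}

    for s in suspects:
        compound_rows.append(
            compound_row(
                s.name,
                "parent" if s.phase == "parent" else "metabolite",
                formula=s.formula,
                parent_name=s.parent_name or "",
                phase=s.phase,
                biotransformation=s.biotransformation or "",
                mass=s.monoisotopic_mass,
                mz_mh=mz_mh[s.name],
                logD=s.logD_pos,
                true_rt=true_rt[s.name],
                peak_rating=rating[s.name],
                ms2_emitted=bool(ms2_emitted.get(s.name, False)),
                has_standard=has_standard[s.name],
                excretion_fraction=s.excretion_fraction,
                max_intensity=max_intensity.get(s.name, 0.0),
                prep_recovery=prep_recovery[s.name],
            )
        )
    for decoy in decoys:
        compound_rows.append(
            compound_row(
                decoy["name"], "decoy", formula="", parent_name="",
                phase="", biotransformation="", mass=np.nan,
                mz_mh=decoy["mz"], logD=np.nan, true_rt=decoy["rt"],
                peak_rating=decoy["rating"], ms2_emitted=True,
                has_standard=False, excretion_fraction=np.nan,
                max_intensity=decoy["intensity"], prep_recovery=1.0,
                decoy_target=decoy["target"],
            )
        )
    for bg in backgrounds:
        compound_rows.append(
            compound_row(
                bg["name"], "background", formula="", parent_name="",
                phase="", biotransformation="", mass=np.nan, mz_mh=bg["mz"],
                logD=np.nan, true_rt=bg["rt"], peak_rating=bg["rating"],
                ms2_emitted=bg["ms2"], has_standard=False,
                excretion_fraction=np.nan, max_intensity=bg["intensity"],
                prep_recovery=1.0,
            )
        )

    features = pd.DataFrame(feature_rows).sort_values(
        ["sample_id", "mz", "rt"], kind="mergesort"
    ).reset_index(drop=True)
    ledger = pd.DataFrame(ledger_rows).sort_values(
        ["sample_id", "mz", "rt"], kind="mergesort"
    ).reset_index(drop=True)

    s9_names = {d.compound for d in s9_detections}
    compounds_df = pd.DataFrame(compound_rows)
    compounds_df["has_s9"] = compounds_df["name"].isin(s9_names)

    ground_truth = GroundTruth(
        compounds=compounds_df,
        concentrations=pd.DataFrame(conc_rows),
        feature_ledger=ledger,
        rt_slope=config.rt_slope,
        rt_intercept=config.rt_intercept,
        rt_noise_sd=config.rt_noise_sd,
        suppression_plant=suppression_plant,
        suppression_factor=config.suppression_factor,
        sewer_loss_factor=config.sewer_loss_factor,
        consumption_kg_yr=consumption,
        ms2_sources=ms2_sources,
    )
    return Dataset(
        config=config,
        suspects=suspects,
        features=features,
        spectra=spectra,
        calibration=pd.DataFrame(cal_rows),
        external_calibration=pd.DataFrame(ext_rows),
        ilis=pd.DataFrame(ilis_rows),
        ilis_standards=pd.DataFrame(ilis_std_rows),
        recovery=pd.DataFrame(recovery_rows),
        standards=pd.DataFrame(standard_rows),
        standard_spectra=standard_spectra,
        s9_detections=s9_detections,
        excretion_records=excretion_records,
        flows=pd.DataFrame(flows_rows),
        populations=populations,
        population_reference=config.population_reference,
        sample_ids=samples,
        blank_ids=blanks,
        ground_truth=ground_truth,
    )
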