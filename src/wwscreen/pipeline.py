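"""End-to-end orchestration of the screening stages on one dataset.

Stage order mirrors the screening workflow: componentization and alignment
of the MS1 feature tables, exact-mass suspect matching, the prioritization
filter cascade, molecular networking of the retained hits' MS2 spectra,
RT-model fitting on standard-confirmed hits and plausibility flagging,
confidence-level assignment with the harmonized score, quantification
(target calibration with ILIS recovery correction, external-calibration
semiquantification with matrix sensitivity factors, pluggable
ionization-efficiency semiquantification), and finally metabolite/parent
ratio and consumption analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import components as comp_mod
from .components import AlignedComponent
from .confidence import (
    EvidenceBundle,
    assign_level,
    harmonized_score,
    rt_plausibility_score,
    s9_match,
)
from .constants import C13_ABUNDANCE
from .io_formats import FeatureRecord, Spectrum
from .networking import build_network, modified_cosine, parent_link_fraction
from .quant import (
    fit_calibration,
    quantify_target,
    select_ilis,
    semiquant_negative,
    semiquant_positive,
    sensitivity_factor,
)
from .ratios import WBEInput, literature_ratio, measured_ratio, wbe_consumption
from .registry import default_adducts, parse_formula
from .rt_model import RTModel, fit_rt_model, rt_plausible
from .screening import SuspectHit, filter_cascade, match_suspects
from .synthetic import Dataset


@dataclass
class PipelineParams:
    """Tolerances and thresholds shared across stages."""

    ppm_tol: float = 5.0
    rt_tol_within: float = 0.1
    rt_tol_across: float = 0.5
    frag_tol_da: float = 0.01
    min_intensity: float = 1e5
    rt_window: tuple[float, float] = (4.0, 30.0)
    blank_fold: float = 10.0
    min_peak_rating: float = 5.0
    min_similarity: float = 0.5
    min_matched: int = 4
    max_links_per_node: int = 10
    rt_level: float = 0.99
    s9_min_similarity: float = 0.8
    score_weights: dict | None = None


@dataclass
class PipelineResult:
    aligned: list[AlignedComponent]
    hits: list[SuspectHit]
    retained: list[SuspectHit]
    filter_report: object
    graph: object
    rt_model: RTModel | None
    parent_link_frac: float | None
    quant: pd.DataFrame
    ratios: pd.DataFrame
    consumption: pd.DataFrame
    ms2_by_row: dict[int, Spectrum] = field(default_factory=dict)
    counts: dict = field(default_factory=dict)


def componentize_and_align(
    features: pd.DataFrame, params: PipelineParams
) -> list[AlignedComponent]:
    records = [
        FeatureRecord(
            mz=float(r.mz), rt=float(r.rt), sample_id=str(r.sample_id),
            intensity=float(r.intensity),
            peak_rating=float(getattr(r, "peak_rating", 10.0)),
        )
        for r in features.itertuples(index=False)
    ]
    adducts = default_adducts("positive")
    per_sample = []
    for sample in sorted({r.sample_id for r in records}):
        sample_feats = [r for r in records if r.sample_id == sample]
        per_sample.append(
            comp_mod.group_features(
                sample_feats, rt_tol=params.rt_tol_within,
                mz_tol=params.ppm_tol, adducts=adducts,
            )
        )
    aligned = comp_mod.align_components(
        per_sample, mz_tol=params.ppm_tol, rt_tol=params.rt_tol_across
    )
    return comp_mod.gap_fill(
        aligned, records, mz_tol=params.ppm_tol, rt_tol=params.rt_tol_across
    )


def attach_ms2(
    aligned: list[AlignedComponent],
    spectra: list[Spectrum],
    params: PipelineParams,
) -> dict[int, Spectrum]:
    """Assign each MS2 spectrum to the closest aligned component in
    (m/z, RT); returns row_id -> spectrum (most intense precursor wins)."""
    ms2_by_row: dict[int, Spectrum] = {}
    rows = sorted(aligned, key=lambda r: r.mz)
    mzs = np.array([r.mz for r in rows])
    for sp in spectra:
        tol = sp.precursor_mz * params.ppm_tol * 1e-6
        lo = int(np.searchsorted(mzs, sp.precursor_mz - tol, "left"))
        hi = int(np.searchsorted(mzs, sp.precursor_mz + tol, "right"))
        best = None
        for row in rows[lo:hi]:
            if sp.rt is not None and abs(row.rt - sp.rt) > params.rt_tol_across:
                continue
            d = abs(row.mz - sp.precursor_mz)
            if best is None or d < best[0]:
                best = (d, row)
        if best is not None:
            row = best[1]
            if row.row_id not in ms2_by_row:
                ms2_by_row[row.row_id] = sp
    return ms2_by_row


def isotope_fit_score(row: AlignedComponent, formula: str) -> float:
    """Agreement of the observed M+1/M intensity ratio with the carbon count
    expected from the formula; 1 = perfect, 0 = no isotopologue seen."""
    try:
        n_c = parse_formula(formula).get("C", 0)
    except Exception:
        return 0.0
    if n_c == 0:
        return 0.0
    expected = C13_ABUNDANCE * n_c
    ratios = []
    for member in row.members:
        if member.isotopologue_members and member.intensity > 0:
            iso = member.isotopologue_members[0].intensity
            ratios.append(iso / member.intensity)
    if not ratios:
        return 0.0
    observed = float(np.median(ratios))
    return float(max(0.0, 1.0 - abs(observed - expected) / expected))


def run_pipeline(
    dataset: Dataset,
    params: PipelineParams | None = None,
    ie_predictor=None,
) -> PipelineResult:
    params = params or PipelineParams()
    samples = dataset.sample_ids
    blanks = dataset.blank_ids
    counts: dict = {}

    # 1-2. componentization, alignment, gap filling
    aligned = componentize_and_align(dataset.features, params)
    counts["aligned_components"] = len(aligned)

    # 3. MS2 assignment
    ms2_by_row = attach_ms2(aligned, dataset.spectra, params)

    # 4. suspect matching
    adducts = [a for a in default_adducts("positive") if a.label == "[M+H]+"]
    hits = match_suspects(aligned, dataset.suspects, adducts, params.ppm_tol)
    counts["initial_hits"] = len(hits)

    # 5. prioritization cascade
    retained, report = filter_cascade(
        hits,
        sample_ids=samples,
        blank_ids=blanks,
        min_intensity=params.min_intensity,
        rt_window=params.rt_window,
        blank_fold=params.blank_fold,
        min_peak_rating=params.min_peak_rating,
        ms2_lookup=lambda h: ms2_by_row.get(h.component.row_id),
    )
    counts["retained_hits"] = len(retained)
    counts["removed"] = dict(report.removed_per_criterion)

    # 6. molecular networking over the retained hits' spectra
    net_spectra = {}
    for hit in retained:
        sp = ms2_by_row.get(hit.component.row_id)
        if sp is not None:
            net_spectra[sp.identifier] = sp
    graph = None
    if len(net_spectra) >= 2:
        graph = build_network(
            list(net_spectra.values()),
            min_similarity=params.min_similarity,
            min_matched=params.min_matched,
            max_links_per_node=params.max_links_per_node,
            frag_tol_da=params.frag_tol_da,
        )
        for hit in retained:
            sp = ms2_by_row.get(hit.component.row_id)
            if sp is not None and sp.identifier in graph:
                hit.network_links = sorted(graph.neighbors(sp.identifier))

    # 7. reference-standard comparison (drives RT-model training)
    standards_rt = (
        dict(zip(dataset.standards["compound"], dataset.standards["rt"]))
        if len(dataset.standards)
        else {}
    )
    standard_ms2 = {sp.identifier.removeprefix("STD_"): sp
                    for sp in dataset.standard_spectra}
    std_eval: dict[int, tuple[bool, bool]] = {}
    for idx, hit in enumerate(retained):
        name = hit.suspect.name
        if name not in standards_rt:
            continue
        rt_ok = abs(hit.component.rt - standards_rt[name]) <= params.rt_tol_across
        sp = ms2_by_row.get(hit.component.row_id)
        ms2_ok = False
        if sp is not None and name in standard_ms2:
            sim, _ = modified_cosine(sp, standard_ms2[name], params.frag_tol_da)
            ms2_ok = sim >= params.s9_min_similarity
        std_eval[idx] = (rt_ok, ms2_ok)

    model = None
    train_x, train_y = [], []
    for idx, (rt_ok, ms2_ok) in std_eval.items():
        hit = retained[idx]
        if rt_ok and ms2_ok and hit.suspect.logD_pos is not None:
            train_x.append(hit.suspect.logD_pos)
            train_y.append(hit.component.rt)
    if len(train_x) >= 3 and len(set(train_x)) > 1:
        model = fit_rt_model(train_x, train_y, polarity="positive")
    counts["rt_model_n"] = len(train_x)

    # 8. confidence
    parent_root = {}
    for s in dataset.suspects:
        parent_root[s.name] = s.parent_name or s.name
    node_parent = {}
    for hit in retained:
        sp = ms2_by_row.get(hit.component.row_id)
        if sp is not None:
            node_parent.setdefault(sp.identifier, parent_root[hit.suspect.name])

    for idx, hit in enumerate(retained):
        name = hit.suspect.name
        logd = hit.suspect.logD_pos
        if model is not None and logd is not None:
            hit.rt_plausible = rt_plausible(
                model, logd, hit.component.rt, params.rt_level
            )
            rt_score = rt_plausibility_score(model, logd, hit.component.rt)
        else:
            hit.rt_plausible = None
            rt_score = 1.0
        has_std = name in standards_rt
        rt_ok, ms2_ok = std_eval.get(idx, (False, False))
        sp = ms2_by_row.get(hit.component.row_id)
        matched_s9, _, s9_sim = s9_match(
            hit, dataset.s9_detections,
            ppm_tol=params.ppm_tol, rt_tol=params.rt_tol_across,
            min_similarity=params.s9_min_similarity, hit_ms2=sp,
        )
        sim_best = s9_sim
        if sp is not None and graph is not None and sp.identifier in graph:
            for nb in graph.neighbors(sp.identifier):
                sim_best = max(sim_best, graph.edges[sp.identifier, nb]["similarity"])
        if idx in std_eval and ms2_ok:
            sim_best = max(sim_best, params.s9_min_similarity)
        evidence = EvidenceBundle(
            has_reference_standard=has_std,
            standard_rt_match=has_std and rt_ok,
            standard_ms2_match=has_std and ms2_ok,
            s9_match=matched_s9,
            in_silico_support=False,
            formula_unequivocal=bool(hit.suspect.formula),
            ppm_error=hit.ppm_error,
            isotope_fit=isotope_fit_score(hit.component, hit.suspect.formula),
            ms2_similarity=min(1.0, sim_best),
            rt_plausible=bool(hit.rt_plausible) if hit.rt_plausible is not None else True,
        )
        hit.confidence_level = assign_level(evidence)
        hit.harmonized_score = harmonized_score(
            evidence, params.score_weights, params.ppm_tol, rt_score=rt_score
        ).total

    # parent-link statistic over confirmed metabolites (levels 1-3)
    confirmed_nodes = []
    for hit in retained:
        sp = ms2_by_row.get(hit.component.row_id)
        if (
            sp is not None
            and hit.confidence_level in ("1", "2a", "2b", "3")
            and hit.suspect.parent_name
        ):
            confirmed_nodes.append(sp.identifier)
    plf = (
        parent_link_fraction(graph, sorted(set(confirmed_nodes)), node_parent)
        if graph is not None
        else None
    )
    counts["confirmed_metabolite_nodes"] = len(set(confirmed_nodes))

    # 9. quantification
    quant_rows = []
    ilis_sample_intensity = _ilis_sample_intensities(dataset, params)
    ilis_standard_intensity = dict(
        zip(dataset.ilis_standards["ilis_id"], dataset.ilis_standards["intensity"])
    )
    factors = _sensitivity_factors(dataset, ilis_sample_intensity)
    calibrated = (
        set(dataset.calibration["analyte"]) if len(dataset.calibration) else set()
    )
    ext_calibrated = (
        set(dataset.external_calibration["analyte"])
        if len(dataset.external_calibration)
        else set()
    )
    ilis_candidates = _ilis_candidates(dataset)
    for hit in retained:
        name = hit.suspect.name
        row = hit.component
        sample_int = {s: row.intensity.get(s, 0.0) for s in samples}
        if name in calibrated:
            concs = _quantify_with_standard(
                dataset, name, row, sample_int, ilis_sample_intensity,
                ilis_candidates, ilis_standard_intensity,
            )
            method = "target"
        elif name in ext_calibrated:
            concs = _semiquant_external(dataset, name, sample_int, factors)
            method = "semiquant_neg"
        else:
            concs = None
            if ie_predictor is not None:
                calibrants = _ie_calibrants(dataset, retained, samples)
                concs = semiquant_positive(
                    name, sample_int, ie_predictor, calibrants
                )
            method = "semiquant_pos" if concs is not None else "unquantified"
        if concs is not None:
            hit.concentration_ng_L = {
                s: (c[0] if isinstance(c, tuple) else c) for s, c in concs.items()
            }
            hit.quant_method = method
            for s, c in hit.concentration_ng_L.items():
                quant_rows.append(
                    {"compound": name, "sample_id": s, "conc_ng_L": c,
                     "method": method, "level": hit.confidence_level}
                )
    quant = pd.DataFrame(quant_rows)

    # 10. ratios and consumption
    ratios_df, consumption_df = _ratios_and_wbe(dataset, quant)

    return PipelineResult(
        aligned=aligned,
        hits=hits,
        retained=retained,
        filter_report=report,
        graph=graph,
        rt_model=model,
        parent_link_frac=plf,
        quant=quant,
        ratios=ratios_df,
        consumption=consumption_df,
        ms2_by_row=ms2_by_row,
        counts=counts,
    )


def _ilis_sample_intensities(dataset: Dataset, params: PipelineParams):
    """ILIS intensity per (ilis_id, sample) extracted from the feature table."""
    out: dict[str, dict[str, float]] = {}
    feats = dataset.features
    for row in dataset.ilis.itertuples(index=False):
        tol = row.mz * params.ppm_tol * 1e-6
        sel = feats[
            (feats["mz"].sub(row.mz).abs() <= tol)
            & (feats["rt"].sub(row.rt).abs() <= params.rt_tol_across)
        ]
        per_sample = sel.groupby("sample_id")["intensity"].max().to_dict()
        out[str(row.ilis_id)] = per_sample
    return out


def _sensitivity_factors(dataset: Dataset, ilis_sample_intensity):
    """Per-plant sensitivity factor from ILIS responses."""
    std = dict(
        zip(dataset.ilis_standards["ilis_id"], dataset.ilis_standards["intensity"])
    )
    plants = sorted({s.split("_")[0] for s in dataset.sample_ids})
    factors = {}
    for plant in plants:
        sample_vals, std_vals = [], []
        for ilis_id, per_sample in ilis_sample_intensity.items():
            if ilis_id not in std:
                continue
            for sample, inten in per_sample.items():
                if sample.startswith(plant + "_") and inten > 0:
                    sample_vals.append(inten)
                    std_vals.append(std[ilis_id])
        if sample_vals:
            factors[plant] = sensitivity_factor(sample_vals, std_vals)
        else:
            factors[plant] = 1.0
    return factors


def _ilis_candidates(dataset: Dataset) -> dict[str, list[dict]]:
    """Per-target ILIS candidate lists from the spike-recovery table."""
    rt_of = dict(zip(dataset.ilis["ilis_id"], dataset.ilis["rt"]))
    identical = {}
    if "target" in dataset.ilis.columns:
        for r in dataset.ilis.itertuples(index=False):
            tgt = getattr(r, "target", None)
            if tgt not in (None, "") and not (isinstance(tgt, float) and np.isnan(tgt)):
                identical[str(r.ilis_id)] = str(tgt)
    out: dict[str, list[dict]] = {}
    for r in dataset.recovery.itertuples(index=False):
        out.setdefault(str(r.target), []).append(
            {
                "ilis_id": str(r.ilis_id),
                "rt": float(rt_of[r.ilis_id]),
                "relative_recovery": float(r.relative_recovery),
                "identical_to": identical.get(str(r.ilis_id)),
            }
        )
    return out


def _quantify_with_standard(
    dataset, name, row, sample_int, ilis_sample_intensity, ilis_candidates,
    ilis_standard_intensity,
):
    candidates = ilis_candidates.get(name, [])
    if not candidates:
        return None
    try:
        assignment = select_ilis(name, row.rt, candidates)
    except ValueError:
        return None
    # the calibration curve must use the SAME internal standard that
    # normalizes the sample responses
    std_area = ilis_standard_intensity.get(assignment.ilis_id)
    if not std_area or std_area <= 0:
        return None
    cal = dataset.calibration[dataset.calibration["analyte"] == name]
    levels = [
        (float(r.level_conc), float(r.analyte_area) / std_area)
        for r in cal.itertuples(index=False)
    ]
    curve = fit_calibration(levels, weighting="1/X", analyte=name)
    ilis_int = ilis_sample_intensity.get(assignment.ilis_id, {})
    analyte_areas = {s: v for s, v in sample_int.items() if s in ilis_int and v > 0}
    if not analyte_areas:
        return None
    return quantify_target(
        analyte_areas,
        {s: ilis_int[s] for s in analyte_areas},
        curve,
        assignment.relative_recovery,
    )


def _semiquant_external(dataset, name, sample_int, factors):
    cal = dataset.external_calibration[
        dataset.external_calibration["analyte"] == name
    ]
    levels = [
        (float(r.level_conc), float(r.analyte_area))
        for r in cal.itertuples(index=False)
    ]
    curve = fit_calibration(levels, weighting="1/X", analyte=name)
    out = {}
    for sample, inten in sample_int.items():
        if inten <= 0:
            continue
        plant = sample.split("_")[0]
        out[sample] = semiquant_negative(inten, curve, factors.get(plant, 1.0))
    return out or None


def _ie_calibrants(dataset, retained, samples):
    """Calibrant triples (name, known conc, intensity) from target hits."""
    calibrants = []
    calibrated = set(dataset.calibration["analyte"]) if len(dataset.calibration) else set()
    for hit in retained:
        if hit.suspect.name in calibrated and hit.concentration_ng_L:
            for s in samples:
                conc = hit.concentration_ng_L.get(s)
                inten = hit.component.intensity.get(s, 0.0)
                if conc and conc > 0 and inten > 0:
                    calibrants.append((hit.suspect.name, conc, inten))
                    break
    return calibrants


def _ratios_and_wbe(dataset: Dataset, quant: pd.DataFrame):
    """Literature vs measured metabolite/parent ratios and consumption."""
    ratio_rows = []
    cons_rows = []
    plants = sorted({s.split("_")[0] for s in dataset.sample_ids})
    conc_by_compound: dict[str, dict[str, float]] = {}
    if len(quant):
        # ratio/consumption analysis uses identified compounds only
        # (levels 1-3); isobaric components can yield several quantified
        # hits per suspect, so keep the strongest identification
        quant = quant[quant["level"].isin(["1", "2a", "2b", "3"])]
    if len(quant):
        level_rank = {"1": 0, "2a": 1, "2b": 2, "3": 3}
        ranked = quant.assign(
            _rank=quant["level"].map(lambda lv: level_rank.get(lv, 6))
        ).sort_values(["_rank"], kind="mergesort")
        for (compound, sample), grp in ranked.groupby(
            ["compound", "sample_id"], sort=True
        ):
            conc_by_compound.setdefault(compound, {})[sample] = float(
                grp["conc_ng_L"].iloc[0]
            )

    flow_by_plant = {
        plant: dataset.flows[dataset.flows["plant"] == plant]
        .sort_values("day")["flow_L_day"]
        .tolist()
        for plant in plants
    }

    for record in dataset.excretion_records:
        parent = record.parent
        lit = literature_ratio(record, back_cleavage=False)
        lit_bc = literature_ratio(record, back_cleavage=True)
        parent_concs_all = conc_by_compound.get(parent.name, {})
        met_names = [m.name for m, _, _ in record.metabolite_fractions]
        for plant in plants:
            parent_concs = {
                s: c for s, c in parent_concs_all.items()
                if s.startswith(plant + "_")
            }
            mets = {
                m: {
                    s: c for s, c in conc_by_compound.get(m, {}).items()
                    if s.startswith(plant + "_")
                }
                for m in met_names
            }
            mets = {m: c for m, c in mets.items() if c}
            meas = measured_ratio(parent_concs, mets) if parent_concs else None
            ratio_rows.append(
                {
                    "parent": parent.name,
                    "plant": plant,
                    "literature_ratio": lit,
                    "literature_ratio_backcleavage": lit_bc,
                    "measured_ratio": meas,
                }
            )

        # consumption back-calculation per analyte with known excretion
        analytes = [(parent, parent.excretion_fraction)] + [
            (m, f) for m, f, _ in record.metabolite_fractions
        ]
        for entry, fraction in analytes:
            if fraction in (None, 0) or entry.name not in conc_by_compound:
                continue
            for plant in plants:
                concs = []
                flows = flow_by_plant[plant]
                per_sample = conc_by_compound[entry.name]
                day_concs = [
                    per_sample.get(f"{plant}_D{d + 1}") for d in range(len(flows))
                ]
                if any(c is None or c <= 0 for c in day_concs):
                    continue
                inp = WBEInput(
                    concentration_ng_L=day_concs,
                    flow_L_day=flows,
                    excretion_fraction=fraction,
                    population_served=dataset.populations[plant],
                    population_reference=dataset.population_reference,
                    mw_parent=parent.monoisotopic_mass,
                    mw_analyte=entry.monoisotopic_mass,
                )
                mean, sd = wbe_consumption(inp)
                cons_rows.append(
                    {
                        "parent": parent.name,
                        "analyte": entry.name,
                        "basis": "parent" if entry.name == parent.name else "metabolite",
                        "plant": plant,
                        "consumption_kg_yr": mean,
                        "consumption_sd_kg_yr": sd,
                    }
                )
    return pd.DataFrame(ratio_rows), pd.DataFrame(cons_rows)
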