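"""Group MS1 features into components, align across samples, gap-fill.

A *component* is the set of MS1 features attributable to one chemical entity
at one retention time: the monoisotopic ion, its carbon-isotopologue
satellites and adduct satellites.  Grouping is greedy, seeded by descending
intensity with first-match-wins assignment; ties broken lexicographically by
(m/z, RT), which makes the procedure deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import C13_DELTA
from .io_formats import FeatureRecord, Spectrum
from .registry import AdductSpec

DEFAULT_MZ_TOL_PPM = 5.0
DEFAULT_RT_TOL_WITHIN = 0.1  # min, within one sample
DEFAULT_RT_TOL_ACROSS = 0.5  # min, across samples

MEASURED, GAP_FILLED, ABSENT = "measured", "gap-filled", "absent"


@dataclass
class Component:
    """A grouped isotopologue/adduct feature cluster in one sample."""

    component_id: str
    representative_mz: float  # smallest-mass ion member (monoisotopic ion)
    rt: float
    sample_id: str
    intensity: float  # monoisotopic-ion intensity
    peak_rating: float
    adduct_members: list[FeatureRecord] = field(default_factory=list)
    isotopologue_members: list[FeatureRecord] = field(default_factory=list)
    ms2: Spectrum | None = None

    @property
    def n_members(self) -> int:
        return 1 + len(self.adduct_members) + len(self.isotopologue_members)


def _ppm_window(mz: float, ppm: float) -> float:
    return mz * ppm * 1e-6


def group_features(
    features: list[FeatureRecord],
    rt_tol: float = DEFAULT_RT_TOL_WITHIN,
    mz_tol: float = DEFAULT_MZ_TOL_PPM,
    adducts: list[AdductSpec] | None = None,
) -> list[Component]:
    """Group one sample's features into components.

    Two features co-elute into one component if their RT difference is within
    ``rt_tol`` and their m/z difference matches a carbon-isotopologue spacing
    (k * 1.00336/z, k = 1 or 2, requiring lower intensity than the
    monoisotopic partner) or a pairwise adduct mass difference, both within
    ``mz_tol`` (ppm).  Every feature ends up in exactly one component.
    """
    if not features:
        return []
    sample_ids = {f.sample_id for f in features}
    if len(sample_ids) > 1:
        raise ValueError(f"group_features expects one sample, got {sorted(sample_ids)}")
    sample_id = next(iter(sample_ids))

    adducts = adducts or []
    # mass difference between two singly charged adduct forms of one neutral
    pair_deltas = []
    for a in adducts:
        for b in adducts:
            if a.label >= b.label or a.charge != b.charge:
                continue
            delta = (b.mass_delta - a.mass_delta) / abs(a.charge)
            pair_deltas.append(abs(delta))

    order = sorted(
        range(len(features)),
        key=lambda i: (-features[i].intensity, features[i].mz, features[i].rt),
    )
    assigned = [False] * len(features)
    by_mz = sorted(range(len(features)), key=lambda i: features[i].mz)
    mz_sorted = np.array([features[i].mz for i in by_mz])

    components: list[Component] = []
    for seed_idx in order:
        if assigned[seed_idx]:
            continue
        seed = features[seed_idx]
        assigned[seed_idx] = True
        members = [(seed_idx, "mono")]

        def claim(lo_mz: float, hi_mz: float, role: str, max_intensity: float | None):
            lo = int(np.searchsorted(mz_sorted, lo_mz, side="left"))
            hi = int(np.searchsorted(mz_sorted, hi_mz, side="right"))
            candidates = []
            for pos in range(lo, hi):
                j = by_mz[pos]
                f = features[j]
                if assigned[j] or abs(f.rt - seed.rt) > rt_tol:
                    continue
                if max_intensity is not None and f.intensity >= max_intensity:
                    continue
                candidates.append(j)
            # deterministic: closest in mz, then (mz, rt)
            candidates.sort(
                key=lambda j: (abs(features[j].mz - (lo_mz + hi_mz) / 2),
                               features[j].mz, features[j].rt)
            )
            if candidates:
                j = candidates[0]
                assigned[j] = True
                members.append((j, role))
                return j
            return None

        # isotopologue satellites above the seed (charge 1 assumed)
        tol = _ppm_window(seed.mz, mz_tol)
        prev_intensity = seed.intensity
        for k in (1, 2):
            target = seed.mz + k * C13_DELTA
            j = claim(target - tol, target + tol, "isotopologue", prev_intensity)
            if j is None:
                break
            prev_intensity = features[j].intensity
        # adduct satellites in either direction
        for delta in pair_deltas:
            for sign in (+1, -1):
                target = seed.mz + sign * delta
                if target <= 0:
                    continue
                claim(target - tol, target + tol, "adduct", None)

        idxs = [j for j, _ in members]
        rep_idx = min(idxs, key=lambda j: (features[j].mz, features[j].rt))
        rep = features[rep_idx]
        components.append(
            Component(
                component_id=f"{sample_id}:{len(components)}",
                representative_mz=rep.mz,
                rt=rep.rt,
                sample_id=sample_id,
                intensity=rep.intensity,
                peak_rating=rep.peak_rating,
                adduct_members=[features[j] for j, r in members if r == "adduct"],
                isotopologue_members=[
                    features[j] for j, r in members if r == "isotopologue"
                ],
            )
        )
    return components


@dataclass
class AlignedComponent:
    """One component aligned across samples."""

    row_id: int
    mz: float  # intensity-weighted mean representative m/z
    rt: float  # mean RT
    intensity: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)  # sample -> flag
    peak_rating: float = 10.0
    members: list[Component] = field(default_factory=list)

    def max_intensity(self, samples: list[str] | None = None) -> float:
        vals = [
            v
            for s, v in self.intensity.items()
            if (samples is None or s in samples)
            and self.provenance.get(s) != ABSENT
        ]
        return max(vals, default=0.0)

    def mean_intensity(self, samples: list[str]) -> float:
        vals = [self.intensity.get(s, 0.0) for s in samples]
        return float(np.mean(vals)) if vals else 0.0


def align_components(
    per_sample_components: list[list[Component]],
    mz_tol: float = DEFAULT_MZ_TOL_PPM,
    rt_tol: float = DEFAULT_RT_TOL_ACROSS,
) -> list[AlignedComponent]:
    """Merge components across samples by representative m/z and RT.

    Components are clustered greedily in ascending (m/z, RT) order; a
    component joins the current cluster when its m/z is within ``mz_tol``
    (ppm) of the cluster mean and its RT within ``rt_tol`` of the cluster
    mean.  Missing samples are left as gaps.  Alignment is invariant to the
    order samples are supplied in.
    """
    flat = [c for comps in per_sample_components for c in comps]
    if not flat:
        return []
    flat.sort(key=lambda c: (c.representative_mz, c.rt, c.sample_id))
    clusters: list[list[Component]] = []
    for comp in flat:
        placed = False
        # scan open clusters from newest; m/z-sorted input keeps this short
        for cluster in reversed(clusters):
            mean_mz = float(np.mean([c.representative_mz for c in cluster]))
            if comp.representative_mz - mean_mz > _ppm_window(mean_mz, mz_tol):
                break
            mean_rt = float(np.mean([c.rt for c in cluster]))
            if (
                abs(comp.representative_mz - mean_mz) <= _ppm_window(mean_mz, mz_tol)
                and abs(comp.rt - mean_rt) <= rt_tol
                and comp.sample_id not in {c.sample_id for c in cluster}
            ):
                cluster.append(comp)
                placed = True
                break
        if not placed:
            clusters.append([comp])

    clusters.sort(key=lambda cl: (min(c.representative_mz for c in cl),
                                  min(c.rt for c in cl)))
    aligned = []
    for row_id, cluster in enumerate(clusters):
        weights = np.array([max(c.intensity, 1e-12) for c in cluster])
        mzs = np.array([c.representative_mz for c in cluster])
        aligned.append(
            AlignedComponent(
                row_id=row_id,
                mz=float(np.average(mzs, weights=weights)),
                rt=float(np.mean([c.rt for c in cluster])),
                intensity={c.sample_id: c.intensity for c in cluster},
                provenance={c.sample_id: MEASURED for c in cluster},
                peak_rating=float(max(c.peak_rating for c in cluster)),
                members=list(cluster),
            )
        )
    return aligned


def gap_fill(
    aligned: list[AlignedComponent],
    raw_features: list[FeatureRecord],
    mz_tol: float = DEFAULT_MZ_TOL_PPM,
    rt_tol: float = DEFAULT_RT_TOL_ACROSS,
    sample_ids: list[str] | None = None,
) -> list[AlignedComponent]:
    """Fill alignment gaps from the raw feature lists.

    For every (row, sample) pair with no component, the sample's raw features
    are searched within the m/z and RT tolerances; the most intense match is
    filled and flagged ``gap-filled``, otherwise the cell records intensity 0
    with flag ``absent``.  Rows without gaps are returned unchanged.
    """
    if sample_ids is None:
        sample_ids = sorted({f.sample_id for f in raw_features}.union(
            s for row in aligned for s in row.intensity
        ))
    by_sample: dict[str, list[FeatureRecord]] = {s: [] for s in sample_ids}
    for f in raw_features:
        by_sample.setdefault(f.sample_id, []).append(f)
    for s in by_sample:
        by_sample[s].sort(key=lambda f: f.mz)
    mz_arrays = {s: np.array([f.mz for f in fs]) for s, fs in by_sample.items()}

    for row in aligned:
        tol = _ppm_window(row.mz, mz_tol)
        for sample in sample_ids:
            if sample in row.provenance:
                continue
            feats = by_sample.get(sample, [])
            mzs = mz_arrays.get(sample, np.array([]))
            lo = int(np.searchsorted(mzs, row.mz - tol, side="left"))
            hi = int(np.searchsorted(mzs, row.mz + tol, side="right"))
            best = None
            for f in feats[lo:hi]:
                if abs(f.rt - row.rt) <= rt_tol and (
                    best is None or f.intensity > best.intensity
                ):
                    best = f
            if best is not None:
                row.intensity[sample] = best.intensity
                row.provenance[sample] = GAP_FILLED
            else:
                row.intensity[sample] = 0.0
                row.provenance[sample] = ABSENT
    return aligned


def aligned_to_table(aligned: list[AlignedComponent]) -> pd.DataFrame:
    """Long-format aligned component table with per-cell provenance flags."""
    rows = []
    for row in aligned:
        for sample, inten in sorted(row.intensity.items()):
            rows.append(
                {
                    "row_id": row.row_id,
                    "mz": row.mz,
                    "rt": row.rt,
                    "sample_id": sample,
                    "intensity": inten,
                    "provenance": row.provenance.get(sample, MEASURED),
                    "peak_rating": row.peak_rating,
                }
            )
    return pd.DataFrame(rows)
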