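"""Exact-mass suspect matching, the prioritization filter cascade, and
conjugate-specific neutral-loss / diagnostic-fragment searches.

Suspect screening annotates aligned components whose monoisotopic-ion m/z
matches a suspect's adduct m/z within a ppm tolerance, then prioritizes the
annotated hits with an ordered cascade of exclusion criteria (intensity,
peak shape, MS2 presence, background, retention-time window).  Each removed
hit is attributed to the first failing criterion, and the filter report
conserves counts: input = retained + sum(removed per criterion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .components import AlignedComponent
from .io_formats import Spectrum
from .registry import AdductSpec, SuspectEntry, adduct_mz

CRITERIA = ("intensity", "peak_shape", "ms2", "background", "rt")


def ppm_error(observed_mz: float, expected_mz: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if expected_mz <= 0:
        raise ValueError("expected m/z must be positive")
    return (observed_mz - expected_mz) / expected_mz * 1e6


@dataclass
class SuspectHit:
    """One (component, suspect, adduct) exact-mass annotation."""

    component: AlignedComponent
    suspect: SuspectEntry
    adduct: AdductSpec
    ppm_error: float
    passed_filters: bool | None = None
    removal_reason: str | None = None
    network_links: list = field(default_factory=list)
    rt_plausible: bool | None = None  # None = untested
    confidence_level: str | None = None
    harmonized_score: float | None = None
    concentration_ng_L: dict[str, float] | None = None
    quant_method: str | None = None

    @property
    def rt(self) -> float:
        return self.component.rt


@dataclass
class FilterReport:
    """Accounting of the prioritization cascade."""

    input_count: int
    removed_per_criterion: dict[str, int]
    retained_count: int

    def __post_init__(self) -> None:
        total = self.retained_count + sum(self.removed_per_criterion.values())
        if total != self.input_count:
            raise ValueError(
                f"filter accounting violated: input {self.input_count} != "
                f"retained {self.retained_count} + removed {total - self.retained_count}"
            )


def match_suspects(
    components: list[AlignedComponent],
    suspects: list[SuspectEntry],
    adducts: list[AdductSpec],
    tol_ppm: float = 5.0,
) -> list[SuspectHit]:
    """Annotate components whose m/z matches a suspect adduct within tol_ppm.

    One component may hit several suspects (isobars are kept and
    disambiguated downstream by RT and MS2 evidence).
    """
    expected = []
    for suspect in suspects:
        mass = suspect.monoisotopic_mass
        for adduct in adducts:
            expected.append((adduct_mz(mass, adduct), suspect, adduct))
    expected.sort(key=lambda t: t[0])
    exp_mz = np.array([t[0] for t in expected])

    hits: list[SuspectHit] = []
    for comp in components:
        tol = comp.mz * tol_ppm * 1e-6
        lo = int(np.searchsorted(exp_mz, comp.mz - tol, side="left"))
        hi = int(np.searchsorted(exp_mz, comp.mz + tol, side="right"))
        for mz_expected, suspect, adduct in expected[lo:hi]:
            err = ppm_error(comp.mz, mz_expected)
            if abs(err) <= tol_ppm:
                hits.append(SuspectHit(comp, suspect, adduct, err))
    return hits


def _failing_criteria(
    hit: SuspectHit,
    sample_ids: list[str],
    blank_ids: list[str],
    min_intensity: float,
    rt_window: tuple[float, float],
    require_ms2: bool,
    blank_fold: float,
    min_peak_rating: float,
    ms2_lookup,
) -> set[str]:
    failing = set()
    comp = hit.component
    if comp.max_intensity(sample_ids) <= min_intensity:
        failing.add("intensity")
    if comp.peak_rating < min_peak_rating:
        failing.add("peak_shape")
    if require_ms2 and ms2_lookup(hit) is None:
        failing.add("ms2")
    if blank_ids:
        blank_mean = comp.mean_intensity(blank_ids)
        sample_mean = comp.mean_intensity(sample_ids)
        if blank_mean > 0 and blank_mean * blank_fold >= sample_mean:
            failing.add("background")
    if not (rt_window[0] <= comp.rt <= rt_window[1]):
        failing.add("rt")
    return failing


def filter_cascade(
    hits: list[SuspectHit],
    sample_ids: list[str],
    blank_ids: list[str] | None = None,
    min_intensity: float = 1e5,
    rt_window: tuple[float, float] = (4.0, 30.0),
    require_ms2: bool = True,
    blank_fold: float = 10.0,
    min_peak_rating: float = 5.0,
    ms2_lookup=None,
    order: tuple[str, ...] = CRITERIA,
) -> tuple[list[SuspectHit], FilterReport]:
    """Apply the prioritization criteria in a fixed, documented order.

    Criteria (defaults): monoisotopic intensity above ``min_intensity`` in at
    least one sample; peak rating at least ``min_peak_rating``; an acquired
    MS2 spectrum; not background-dominated (mean blank intensity times
    ``blank_fold`` below the mean sample intensity); elution inside
    ``rt_window`` (after the LC dead time, before the late-eluting cutoff).
    Each removed hit is attributed to the FIRST failing criterion in
    ``order``; permuting the order changes only the attribution, never the
    retained set.
    """
    if set(order) != set(CRITERIA):
        raise ValueError(f"order must be a permutation of {CRITERIA}")
    blank_ids = blank_ids or []
    if ms2_lookup is None:
        def ms2_lookup(hit: SuspectHit) -> Spectrum | None:
            for member in hit.component.members:
                if member.ms2 is not None:
                    return member.ms2
            return None

    removed = {c: 0 for c in order}
    retained: list[SuspectHit] = []
    for hit in hits:
        failing = _failing_criteria(
            hit, sample_ids, blank_ids, min_intensity, rt_window,
            require_ms2, blank_fold, min_peak_rating, ms2_lookup,
        )
        if failing:
            first = next(c for c in order if c in failing)
            hit.passed_filters = False
            hit.removal_reason = first
            removed[first] += 1
        else:
            hit.passed_filters = True
            hit.removal_reason = None
            retained.append(hit)
    report = FilterReport(
        input_count=len(hits),
        removed_per_criterion=removed,
        retained_count=len(retained),
    )
    return retained, report


def neutral_loss_search(
    spectra: list[Spectrum],
    losses: list[tuple[str, float]] | None = None,
    tol_da: float = 0.005,
) -> dict[str, list[str]]:
    """Flag spectra showing a diagnostic neutral loss from the precursor.

    A spectrum is flagged with a loss label when any fragment satisfies
    |precursor_mz - fragment_mz - loss| <= tol_da.  Defaults cover the
    glucuronide (C6H8O6, 176.03209 Da) and sulfate (SO3, 79.95682 Da)
    conjugate losses.
    """
    if losses is None:
        from .constants import DEFAULT_NEUTRAL_LOSSES
        losses = DEFAULT_NEUTRAL_LOSSES
    flags: dict[str, list[str]] = {}
    for sp in spectra:
        hit_labels = []
        for label, loss in losses:
            target = sp.precursor_mz - loss
            if any(abs(mz - target) <= tol_da for mz in sp.mz):
                hit_labels.append(label)
        flags[sp.identifier] = hit_labels
    return flags


def diagnostic_fragment_search(
    spectra: list[Spectrum],
    fragments: list[tuple[str, float]] | None = None,
    tol_da: float = 0.005,
) -> dict[str, list[str]]:
    """Flag spectra containing a diagnostic conjugate fragment ion.

    Defaults ship the negative-mode glucuronide (175.02481, 113.02442) and
    glutathione (306.07653) ions, computed from their elemental compositions.
    """
    if fragments is None:
        from .constants import DEFAULT_DIAGNOSTIC_FRAGMENTS
        fragments = DEFAULT_DIAGNOSTIC_FRAGMENTS
    flags: dict[str, list[str]] = {}
    for sp in spectra:
        hit_labels = []
        for label, frag_mz in fragments:
            if any(abs(mz - frag_mz) <= tol_da for mz in sp.mz):
                if label not in hit_labels:
                    hit_labels.append(label)
        flags[sp.identifier] = hit_labels
    return flags
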