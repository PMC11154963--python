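"""Identification confidence: level assignment, harmonized score, and
in vitro (human liver S9) diagnostic confirmation.

Confidence levels follow the community five-level scheme for small-molecule
identification by HRMS: 1 = confirmed by reference standard (matching RT and
MS2); 2a = probable structure by MS2 library match; 2b = probable structure
by diagnostic evidence (here, a match to an in vitro generated metabolite);
3 = tentative candidate; 4 = unequivocal molecular formula; 5 = exact mass
of interest only.  A tested-but-mismatching reference standard demotes a
candidate to level 4 or 5 depending on whether the formula is unequivocal.

The harmonized identification score aggregates mass accuracy, isotope
pattern fit, MS2 match quality and RT plausibility into a single weighted
number in [0, 1], with the RT component derived from the fitted RT
prediction model's bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .networking import modified_cosine
from .rt_model import RTModel, predict_interval
from .screening import SuspectHit

LEVELS = ("1", "2a", "2b", "3", "4", "5")
#: ordering used for monotonicity checks; higher rank = stronger identification
LEVEL_RANK = {"5": 0, "4": 1, "3": 2, "2b": 3, "2a": 4, "1": 5}


@dataclass
class EvidenceBundle:
    """All identification evidence available for one suspect hit."""

    has_reference_standard: bool = False
    standard_rt_match: bool = False
    standard_ms2_match: bool = False
    library_ms2_match: bool = False
    s9_match: bool = False
    in_silico_support: bool = False
    formula_unequivocal: bool = False
    ppm_error: float = 0.0
    isotope_fit: float = 0.0  # in [0, 1]
    ms2_similarity: float = 0.0  # in [0, 1]
    rt_plausible: bool = True

    def __post_init__(self) -> None:
        if (self.standard_rt_match or self.standard_ms2_match) and not (
            self.has_reference_standard
        ):
            raise ValueError(
                "standard match flags require has_reference_standard"
            )
        for name in ("isotope_fit", "ms2_similarity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def assign_level(evidence: EvidenceBundle) -> str:
    """Decision table mapping an evidence bundle to a confidence level.

    A reference standard, when tested, is decisive: RT and MS2 both matching
    confirms the structure (level 1); any mismatch demotes to level 4 when
    the molecular formula is unequivocal, otherwise level 5.  Without a
    standard, an MS2 library match gives 2a, an in vitro metabolite match
    gives 2b, in silico fragment support gives 3, an unequivocal formula 4,
    and exact mass alone 5.
    """
    e = evidence
    if e.has_reference_standard:
        if e.standard_rt_match and e.standard_ms2_match:
            return "1"
        return "4" if e.formula_unequivocal else "5"
    if e.library_ms2_match:
        return "2a"
    if e.s9_match:
        return "2b"
    if e.in_silico_support:
        return "3"
    if e.formula_unequivocal:
        return "4"
    return "5"


@dataclass
class HarmonizedScore:
    components: dict[str, float]
    weights: dict[str, float]
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = sum(
            self.weights[k] * self.components[k] for k in self.components
        )


DEFAULT_WEIGHTS = {
    "mass_accuracy": 0.25,
    "isotope_fit": 0.25,
    "ms2_match": 0.25,
    "rt_plausibility": 0.25,
}


def rt_plausibility_score(
    model: RTModel, logD: float, observed_rt: float
) -> float:
    """RT component of the harmonized score from the model's bands.

    1 inside the 95% prediction band, decaying linearly to 0 at the 99% band
    edge, 0 beyond.
    """
    center = model.predict(logD)
    lo95, hi95 = predict_interval(model, logD, 0.95)
    lo99, hi99 = predict_interval(model, logD, 0.99)
    d = abs(observed_rt - center)
    hw95 = hi95 - center
    hw99 = hi99 - center
    if d <= hw95:
        return 1.0
    if d >= hw99:
        return 0.0
    return float((hw99 - d) / (hw99 - hw95))


def harmonized_score(
    evidence: EvidenceBundle,
    weights: dict[str, float] | None = None,
    ppm_tol: float = 5.0,
    rt_score: float | None = None,
) -> HarmonizedScore:
    """Weighted aggregate of the four evidence components.

    mass_accuracy = max(0, 1 - |ppm error| / ppm_tol); isotope fit and MS2
    similarity pass through; the RT component is either supplied directly
    (``rt_score``, typically from :func:`rt_plausibility_score`) or taken as
    1/0 from the boolean plausibility flag.
    """
    weights = dict(weights or DEFAULT_WEIGHTS)
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError("score weights must sum to 1")
    if set(weights) != set(DEFAULT_WEIGHTS):
        raise ValueError(f"weights must cover {sorted(DEFAULT_WEIGHTS)}")
    components = {
        "mass_accuracy": max(0.0, 1.0 - abs(evidence.ppm_error) / ppm_tol),
        "isotope_fit": evidence.isotope_fit,
        "ms2_match": evidence.ms2_similarity,
        "rt_plausibility": (
            rt_score
            if rt_score is not None
            else (1.0 if evidence.rt_plausible else 0.0)
        ),
    }
    return HarmonizedScore(components=components, weights=weights)


@dataclass
class S9Detection:
    """A metabolite detected in a human liver S9 incubation run."""

    compound: str
    mz: float
    rt: float
    ms2: object  # Spectrum


def s9_match(
    hit: SuspectHit,
    s9_detections: list[S9Detection],
    ppm_tol: float = 5.0,
    rt_tol: float = 0.5,
    min_similarity: float = 0.8,
    hit_ms2=None,
) -> tuple[bool, S9Detection | None, float]:
    """Match a wastewater suspect hit against in vitro S9 detections.

    A match requires agreement in m/z (ppm), RT (an extended window, to
    absorb the matrix difference between wastewater and S9 extracts) and an
    MS2 modified-cosine similarity of at least ``min_similarity``.  Returns
    (matched, best detection, best similarity).
    """
    if hit_ms2 is None:
        for member in hit.component.members:
            if member.ms2 is not None:
                hit_ms2 = member.ms2
                break
    if hit_ms2 is None:
        return False, None, 0.0
    best: tuple[float, S9Detection | None] = (0.0, None)
    for det in s9_detections:
        if abs(det.mz - hit.component.mz) / hit.component.mz * 1e6 > ppm_tol:
            continue
        if abs(det.rt - hit.component.rt) > rt_tol:
            continue
        sim, _ = modified_cosine(hit_ms2, det.ms2)
        if sim > best[0]:
            best = (sim, det)
    matched = best[0] >= min_similarity and best[1] is not None
    return matched, best[1], best[0]
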