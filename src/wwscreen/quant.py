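"""Target quantification and semiquantification.

Targets with reference standards are quantified against a linear calibration
curve (1/X weighting) of analyte/internal-standard peak-area ratios, with an
isotope-labeled internal standard (ILIS) chosen per analyte: a structurally
identical ILIS when available, otherwise the ILIS closest to 100% relative
recovery among those eluting nearby.  Concentrations are corrected by the
relative recovery of the assigned ILIS.

Suspects without standards are semiquantified: in negative mode against an
external calibration curve in ultrapure water, after correcting sample
intensities by a sensitivity factor (mean ILIS intensity in calibration
standards over mean ILIS intensity in the matrix); in positive mode through
a pluggable ionization-efficiency predictor anchored to calibrant targets
(the shipped default predictor is a linear surrogate intended for testing).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np


@dataclass
class CalibrationCurve:
    analyte: str
    levels: list[tuple[float, float]]  # (concentration ng/L, response)
    weighting: str  # "1/X" or "none"
    slope: float
    intercept: float
    loq: float | None = None  # ng/L

    def invert(self, response: float) -> float:
        if self.slope <= 0:
            raise ValueError(f"{self.analyte}: non-positive calibration slope")
        return (response - self.intercept) / self.slope


def fit_calibration(
    levels: list[tuple[float, float]],
    weighting: str = "1/X",
    analyte: str = "",
    loq_accuracy: float = 0.30,
) -> CalibrationCurve:
    """Weighted least-squares line through calibration levels.

    Minimizes sum w_i (y_i - a - b x_i)^2 with w_i = 1/x_i under "1/X"
    weighting (all concentrations must then be strictly positive) or w_i = 1.
    The limit of quantification is set operationally to the lowest level
    whose back-calculated concentration is accurate within ``loq_accuracy``
    (relative).
    """
    if len(levels) < 3:
        raise ValueError("calibration needs at least 3 levels")
    x = np.array([lv[0] for lv in levels], dtype=float)
    y = np.array([lv[1] for lv in levels], dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("calibration levels must be finite")
    if weighting == "1/X":
        if (x <= 0).any():
            raise ValueError("1/X weighting requires strictly positive concentrations")
        w = 1.0 / x
    elif weighting == "none":
        w = np.ones_like(x)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    sw = w.sum()
    xw = (w * x).sum() / sw
    yw = (w * y).sum() / sw
    sxx = (w * (x - xw) ** 2).sum()
    if sxx == 0:
        raise ValueError("zero concentration variance")
    slope = float((w * (x - xw) * (y - yw)).sum() / sxx)
    intercept = float(yw - slope * xw)
    curve = CalibrationCurve(
        analyte=analyte,
        levels=sorted(levels),
        weighting=weighting,
        slope=slope,
        intercept=intercept,
    )
    if slope > 0:
        for conc, resp in sorted(levels):
            back = curve.invert(resp)
            if conc > 0 and abs(back - conc) / conc <= loq_accuracy:
                curve.loq = conc
                break
    return curve


@dataclass
class ILISAssignment:
    target: str
    ilis_id: str
    relative_recovery: float  # percent of spiked amount recovered
    rt_distance: float  # min

    def __post_init__(self) -> None:
        if self.relative_recovery <= 0:
            raise ValueError("relative recovery must be positive")


def select_ilis(
    target: str,
    target_rt: float,
    candidates: list[dict],
    rt_window: float = 5.0,
) -> ILISAssignment:
    """Assign an ILIS to a target analyte.

    ``candidates`` carry keys ilis_id, rt, relative_recovery (percent) and
    optionally identical_to (the target the ILIS is the labeled analogue
    of).  A structurally identical ILIS wins outright; otherwise, among
    candidates within ``rt_window`` minutes, the one with recovery closest
    to 100% is chosen, ties broken by smaller RT distance.
    """
    identical = [c for c in candidates if c.get("identical_to") == target]
    if identical:
        c = identical[0]
        return ILISAssignment(
            target, c["ilis_id"], float(c["relative_recovery"]),
            abs(float(c["rt"]) - target_rt),
        )
    in_window = [
        c for c in candidates if abs(float(c["rt"]) - target_rt) <= rt_window
    ]
    if not in_window:
        raise ValueError(
            f"no ILIS within {rt_window} min of {target} (RT {target_rt}); "
            "widen the RT window"
        )
    best = min(
        in_window,
        key=lambda c: (
            abs(float(c["relative_recovery"]) - 100.0),
            abs(float(c["rt"]) - target_rt),
            str(c["ilis_id"]),
        ),
    )
    return ILISAssignment(
        target, best["ilis_id"], float(best["relative_recovery"]),
        abs(float(best["rt"]) - target_rt),
    )


def quantify_target(
    analyte_areas: dict[str, float],
    ilis_areas: dict[str, float],
    curve: CalibrationCurve,
    relative_recovery: float = 100.0,
) -> dict[str, tuple[float, bool]]:
    """Back-calculate per-sample concentrations from area ratios.

    Returns sample -> (concentration ng/L corrected by the relative
    recovery, below_loq flag).
    """
    if curve.slope <= 0:
        raise ValueError("calibration slope must be positive")
    if relative_recovery <= 0:
        raise ValueError("relative recovery must be positive")
    out = {}
    for sample, area in analyte_areas.items():
        ilis = ilis_areas[sample]
        if ilis <= 0:
            raise ValueError(f"non-positive ILIS area in sample {sample}")
        conc = curve.invert(area / ilis) / (relative_recovery / 100.0)
        below = curve.loq is not None and conc < curve.loq
        out[sample] = (conc, below)
    return out


def sensitivity_factor(
    ilis_sample_intensities: list[float],
    ilis_standard_intensities: list[float],
) -> float:
    """Matrix sensitivity correction: mean(standards) / mean(samples).

    Applied multiplicatively to sample intensities before inverting an
    external calibration curve, compensating ion suppression in the matrix.
    """
    if not ilis_sample_intensities or not ilis_standard_intensities:
        raise ValueError("both intensity lists must be non-empty")
    samples = np.asarray(ilis_sample_intensities, dtype=float)
    standards = np.asarray(ilis_standard_intensities, dtype=float)
    if (samples <= 0).any() or (standards <= 0).any():
        raise ValueError("intensities must be positive")
    mean_samples = samples.mean()
    if mean_samples == 0:
        raise ValueError("zero mean sample intensity")
    return float(standards.mean() / mean_samples)


def semiquant_negative(
    intensity: float, external_curve: CalibrationCurve, factor: float = 1.0
) -> float:
    """Semiquantification against an external (ultrapure water) curve.

    conc = (intensity * factor - intercept) / slope; the result is
    semiquantitative by construction.
    """
    return external_curve.invert(intensity * factor)


class IonizationEfficiencyPredictor(Protocol):
    """Interface for positive-mode response-factor prediction.

    Implementations map a compound descriptor (name, structure, fingerprint
    — whatever the backing model consumes) to a predicted response factor in
    intensity counts per ng/L, on an arbitrary instrument scale that the
    anchoring step rescales.
    """

    def predict_response_factor(self, compound: str) -> float: ...


@dataclass
class LinearSurrogatePredictor:
    """Testing surrogate: a lookup of response factors with optional bias.

    Stands in for an external ionization-efficiency model during testing and
    in the synthetic demo; ``bias`` multiplies every prediction so error
    propagation stays transparent (a 2x response-factor error yields a 2x
    concentration error).
    """

    response_factors: dict[str, float]
    bias: float = 1.0

    def predict_response_factor(self, compound: str) -> float:
        return self.response_factors[compound] * self.bias


def semiquant_positive(
    compound: str,
    intensities: dict[str, float],
    predictor: IonizationEfficiencyPredictor | None,
    calibrants: list[tuple[str, float, float]] | None = None,
) -> dict[str, float] | None:
    """Positive-mode semiquantification through a pluggable predictor.

    ``calibrants`` are (compound, known concentration ng/L, measured
    intensity) triples used to anchor the predictor's arbitrary response
    scale: the median ratio of measured to predicted response factor
    rescales all predictions.  Returns sample -> concentration, or None
    (unquantified, not an error) when no predictor is available.
    """
    if predictor is None:
        return None
    scale = 1.0
    if calibrants:
        ratios = []
        for name, conc, inten in calibrants:
            if conc <= 0:
                continue
            predicted = predictor.predict_response_factor(name)
            if predicted > 0:
                ratios.append((inten / conc) / predicted)
        if ratios:
            scale = float(np.median(ratios))
    rf = predictor.predict_response_factor(compound) * scale
    if rf <= 0:
        return None
    return {sample: inten / rf for sample, inten in intensities.items()}
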