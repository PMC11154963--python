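"""Linear retention-time model on logD with prediction intervals.

Reversed-phase retention correlates with hydrophobicity; a straight line of
RT on logD (at the chromatographic pH of the ionization mode) gives a coarse
but useful plausibility check for suspect candidates.  Because the bands are
used to judge single new observations, prediction intervals (which add the
residual variance of a new point to the uncertainty of the fitted line) are
used rather than confidence intervals for the mean; a fixed half-width band
can be configured instead.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats


@dataclass
class RTModel:
    """Ordinary least squares fit of RT (min) on logD."""

    slope: float  # min per logD unit
    intercept: float  # min
    residual_sd: float  # min, from n-2 degrees of freedom
    n_train: int
    polarity: str
    x_mean: float
    sxx: float  # sum of squared centered logD of the training set
    fixed_half_width: float | None = None  # optional constant-width band, min

    def __post_init__(self) -> None:
        if self.n_train < 3:
            raise ValueError("RT model needs at least 3 training points")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be nonnegative")

    def predict(self, logD: float) -> float:
        return self.slope * logD + self.intercept

    def standard_errors(self) -> tuple[float, float]:
        """Standard errors of (slope, intercept)."""
        se_slope = self.residual_sd / np.sqrt(self.sxx)
        se_intercept = self.residual_sd * np.sqrt(
            1.0 / self.n_train + self.x_mean**2 / self.sxx
        )
        return float(se_slope), float(se_intercept)


def fit_rt_model(
    logD: list[float] | np.ndarray,
    rt: list[float] | np.ndarray,
    polarity: str = "positive",
) -> RTModel:
    """Fit RT = slope * logD + intercept by ordinary least squares."""
    x = np.asarray(logD, dtype=float)
    y = np.asarray(rt, dtype=float)
    if x.shape != y.shape:
        raise ValueError("logD and rt must have equal length")
    if x.size < 3:
        raise ValueError("RT model needs at least 3 training points")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("RT model requires finite inputs")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("zero variance in logD: cannot fit a line")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (x.size - 2)))
    return RTModel(
        slope=slope,
        intercept=intercept,
        residual_sd=residual_sd,
        n_train=int(x.size),
        polarity=polarity,
        x_mean=float(x.mean()),
        sxx=sxx,
    )


def predict_interval(
    model: RTModel, logD: float, level: float = 0.95
) -> tuple[float, float]:
    """Prediction interval for the RT of a new compound at the given logD.

    Uses the t distribution with n-2 degrees of freedom and accounts for the
    leverage of the new point; with ``fixed_half_width`` set on the model,
    a constant-width band around the regression line is returned instead.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    center = model.predict(logD)
    if model.fixed_half_width is not None:
        hw = model.fixed_half_width
    else:
        t_crit = stats.t.ppf(0.5 + level / 2.0, model.n_train - 2)
        hw = (
            t_crit
            * model.residual_sd
            * np.sqrt(
                1.0
                + 1.0 / model.n_train
                + (logD - model.x_mean) ** 2 / model.sxx
            )
        )
    return float(center - hw), float(center + hw)


def rt_plausible(
    model: RTModel, logD: float, observed_rt: float, level: float = 0.99
) -> bool:
    """Whether an observed RT lies inside the prediction band at ``level``.

    Implausible candidates are flagged, not deleted: the rejection decision
    combines RT with MS2 and other evidence downstream.
    """
    low, high = predict_interval(model, logD, level)
    return low <= observed_rt <= high


def metabolite_rt_monotone(
    parent_logD: float,
    parent_rt: float,
    metabolite_logD: float,
    metabolite_rt: float,
    rt_slack: float = 0.0,
) -> bool:
    """Companion sign check: a metabolite more polar than its parent (lower
    logD) is expected to elute earlier; returns False when the RT ordering
    contradicts the logD ordering by more than ``rt_slack`` minutes."""
    if metabolite_logD < parent_logD:
        return metabolite_rt <= parent_rt + rt_slack
    return True


def save_model(model: RTModel, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(asdict(model), handle, indent=2)


def load_model(path) -> RTModel:
    with open(path, encoding="utf-8") as handle:
        return RTModel(**json.load(handle))
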