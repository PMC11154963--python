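"""Metabolite/parent concentration ratios and wastewater-based epidemiology.

Literature excretion data (molar fractions of an administered dose excreted
as the parent or as each metabolite) predict the metabolite-to-parent
mass-concentration ratio expected in raw wastewater; comparing it with the
measured ratio per treatment plant reveals in-sewer transformation or
analytical losses.  Phase-II conjugates known to cleave back to the parent
during sewer transport can be reassigned to the parent ("back-cleavage"
scenario), which strictly lowers the expected ratio.

The same excretion fractions support back-calculating population consumption
from measured loads (concentration x flow), correcting for the molecular
weight difference between the measured analyte and the parent drug.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .registry import SuspectEntry


@dataclass
class ExcretionRecord:
    """Excreted fractions of one parent pharmaceutical."""

    parent: SuspectEntry
    parent_fraction: float | None  # molar fraction excreted unchanged
    #: (metabolite entry, molar fraction, back-cleavable phase-II flag)
    metabolite_fractions: list[tuple[SuspectEntry, float, bool]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        fractions = [f for _, f, _ in self.metabolite_fractions]
        if any(f < 0 for f in fractions):
            raise ValueError("negative metabolite fraction")
        if self.parent_fraction is not None:
            if self.parent_fraction < 0:
                raise ValueError("negative parent fraction")
            if self.parent_fraction + sum(fractions) > 1.0 + 1e-6:
                raise ValueError(
                    f"{self.parent.name}: excreted fractions exceed the dose"
                )


def literature_ratio(
    record: ExcretionRecord,
    back_cleavage: bool = False,
    basis: str = "mass",
) -> float | None:
    """Expected metabolite/parent concentration ratio from excretion data.

    On a mass basis the molar fractions are weighted by molecular weight:
    ratio = sum_m(f_m * MW_m) / (f_p * MW_p).  With ``back_cleavage``, each
    back-cleavable phase-II fraction is removed from the numerator and added
    (as parent mass) to the parent fraction, emulating complete deconjugation
    during sewer transport.  Returns None when the parent fraction is unknown
    or zero without back-cleavage rescue.
    """
    if basis not in ("mass", "molar"):
        raise ValueError("basis must be 'mass' or 'molar'")
    if record.parent_fraction is None:
        return None
    f_parent = record.parent_fraction
    mw_parent = record.parent.monoisotopic_mass
    numerator = 0.0
    for met, fraction, cleavable in record.metabolite_fractions:
        if back_cleavage and cleavable:
            f_parent += fraction
        else:
            mw = met.monoisotopic_mass if basis == "mass" else mw_parent
            numerator += fraction * (mw / mw_parent if basis == "mass" else 1.0)
    if f_parent <= 0:
        return None
    return numerator / f_parent


def measured_ratio(
    parent_concs: dict[str, float],
    metabolite_concs_by_compound: dict[str, dict[str, float]],
) -> float | None:
    """Measured metabolite/parent ratio for one plant.

    ``parent_concs`` maps sample -> ng/L for the parent; each metabolite maps
    likewise.  The ratio is the summed metabolite mean concentrations over
    the parent mean concentration; undefined (None) when the parent was not
    detected.
    """
    parent_vals = [v for v in parent_concs.values() if v > 0]
    if not parent_vals:
        return None
    parent_mean = float(np.mean(list(parent_concs.values())))
    if parent_mean <= 0:
        return None
    total = 0.0
    for concs in metabolite_concs_by_compound.values():
        if concs:
            total += float(np.mean(list(concs.values())))
    return total / parent_mean


@dataclass
class WBEInput:
    """Inputs for one consumption back-calculation."""

    concentration_ng_L: float | list[float]  # per sampling day, or a scalar
    flow_L_day: float | list[float]
    excretion_fraction: float  # molar fraction of the dose as the analyte
    population_served: float
    population_reference: float
    mw_parent: float
    mw_analyte: float

    def __post_init__(self) -> None:
        concs = np.atleast_1d(np.asarray(self.concentration_ng_L, dtype=float))
        flows = np.atleast_1d(np.asarray(self.flow_L_day, dtype=float))
        if concs.size != flows.size and 1 not in (concs.size, flows.size):
            raise ValueError("per-day concentrations and flows must align")
        if (flows <= 0).any():
            raise ValueError("flow must be positive")
        if not (0.0 < self.excretion_fraction <= 1.0):
            raise ValueError("excretion fraction must be in (0, 1]")
        if self.population_served <= 0 or self.population_reference <= 0:
            raise ValueError("populations must be positive")
        if self.mw_parent <= 0 or self.mw_analyte <= 0:
            raise ValueError("molecular weights must be positive")


def wbe_consumption(inp: WBEInput) -> tuple[float, float]:
    """Yearly parent-compound consumption, kg/year, as mean +/- sd.

    Per sampling day: load (g/day) = conc (ng/L) x flow (L/day) x 1e-9,
    converted to parent equivalents by the molecular-weight ratio, divided
    by the molar excretion fraction, scaled to the reference population and
    to a year.  The uncertainty is the standard deviation over sampling days
    (zero for a single day).
    """
    concs = np.atleast_1d(np.asarray(inp.concentration_ng_L, dtype=float))
    flows = np.atleast_1d(np.asarray(inp.flow_L_day, dtype=float))
    loads_g_day = concs * flows * 1e-9
    parent_equiv = loads_g_day * (inp.mw_parent / inp.mw_analyte)
    consumption = (
        parent_equiv
        / inp.excretion_fraction
        * (inp.population_reference / inp.population_served)
        * 365.0
        / 1000.0
    )
    mean = float(np.mean(consumption))
    sd = float(np.std(consumption, ddof=1)) if consumption.size > 1 else 0.0
    return mean, sd
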