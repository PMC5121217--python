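"""Period-level mass-balance engine for a chain-elongation bioreactor.

Carboxylates leave the reactor by two routes: in-line membrane extraction
into the alkaline trap, and washout with the effluent.  Per operating
period, the extraction rate of a species is the least-squares slope of its
cumulative amount in the alkaline extraction solution against time; the
washout rate is the period-average broth concentration times the effluent
flow; and the production rate is their sum.  Productivity (g COD/L-d),
membrane flux (g COD/m2-d), yield (product COD per substrate COD fed),
specificity (product COD per total product COD) and the C8:C6 product ratio
follow by normalisation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .species import SpeciesRegistry, default_registry, thod

__all__ = [
    "PeriodDefinition",
    "ExtractionFit",
    "PeriodPerformance",
    "InsufficientDataError",
    "fit_extraction_rate",
    "washout_rate",
    "production_summary",
    "summarize_periods",
    "ethanol_substrate_ratio",
    "gas_cod_rate",
    "upflow_velocity",
    "MCC_SPECIES",
]

#: Lumped "MCC" means the even medium chains C6 + C8 (COD basis) unless the
#: caller explicitly includes n-heptanoate.
MCC_SPECIES = ("n-caproate", "n-caprylate")

_CH4_COD = thod(1, 4, 0)  # 64 g COD/mol
_H2_COD = thod(0, 2, 0)  # 16 g COD/mol


class InsufficientDataError(ValueError):
    """Raised when too few samples exist to fit or average a quantity."""


@dataclass
class PeriodDefinition:
    """Hydraulics and loading of one operating period.

    Working volume ``volume_l`` and flows are per-period because semi-
    continuous feeding and effluent handling changed the effective volume
    between phases.  ``hrt_d * q_feed_l_d`` is cross-checked against the
    working volume (warning beyond 10% disagreement).
    """

    period_id: str
    t_start: float
    t_end: float
    volume_l: float
    hrt_d: float
    olr_gcod_l_d: float
    q_feed_l_d: float
    q_effluent_l_d: float
    q_recycle_l_d: float
    ethanol_cod_fraction: Optional[float] = None
    inner_diameter_m: float = 0.12
    phase: Optional[str] = None

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError(f"{self.period_id}: t_end must exceed t_start")
        for name in ("volume_l", "hrt_d", "q_feed_l_d", "q_effluent_l_d", "q_recycle_l_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.period_id}: {name} must be nonnegative")
        if self.hrt_d > 0 and self.q_feed_l_d > 0 and self.volume_l > 0:
            implied = self.hrt_d * self.q_feed_l_d
            if abs(implied - self.volume_l) / self.volume_l > 0.10:
                warnings.warn(
                    f"{self.period_id}: HRT*Q_feed = {implied:.2f} L disagrees with "
                    f"working volume {self.volume_l:.2f} L by more than 10%",
                    stacklevel=2,
                )

    @property
    def duration_d(self) -> float:
        return self.t_end - self.t_start


@dataclass
class ExtractionFit:
    """OLS slope of cumulative trap amount vs time: the extraction rate M.

    ``ci95_halfwidth`` uses the t distribution with n-2 degrees of freedom.
    A negative slope is physically impossible for an accumulating trap and
    is returned as-is with ``negative_slope=True`` rather than clamped.
    """

    species: Optional[str]
    slope: float
    slope_se: float
    intercept: float
    n_points: int
    ci95_halfwidth: float
    negative_slope: bool = False

    def ci95(self) -> tuple[float, float]:
        return (self.slope - self.ci95_halfwidth, self.slope + self.ci95_halfwidth)


def fit_extraction_rate(
    times: Sequence[float],
    cumulative_amounts: Sequence[float],
    species: Optional[str] = None,
) -> ExtractionFit:
    """Fit the extraction rate (g COD/d) from the alkaline-trap time series.

    Ordinary least squares of cumulative amount (g COD) on time (d); the
    slope is the period extraction rate and its standard error feeds the
    95% confidence interval.  Requires at least 2 samples with strictly
    increasing times; a standard error is only defined for n >= 3.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(cumulative_amounts, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and amounts must be 1-D and equal length")
    if t.size < 2:
        raise InsufficientDataError(
            f"need >= 2 samples to fit an extraction rate, got {t.size}"
        )
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    res = stats.linregress(t, y)
    n = int(t.size)
    if n >= 3 and math.isfinite(res.stderr):
        se = float(res.stderr)
        halfwidth = float(stats.t.ppf(0.975, n - 2) * se)
    else:
        se = float("nan")
        halfwidth = float("nan")
    return ExtractionFit(
        species=species,
        slope=float(res.slope),
        slope_se=se,
        intercept=float(res.intercept),
        n_points=n,
        ci95_halfwidth=halfwidth,
        negative_slope=bool(res.slope < 0),
    )


def washout_rate(mean_broth_concentration: float, q_effluent_l_d: float) -> float:
    """Washout rate (g COD/d): average broth concentration x effluent flow."""
    if mean_broth_concentration < 0:
        raise ValueError("negative broth concentration")
    if q_effluent_l_d < 0:
        raise ValueError("negative effluent flow")
    return mean_broth_concentration * q_effluent_l_d


def ethanol_substrate_ratio(ethanol_cod_fraction: float) -> float:
    """Ethanol-to-non-ethanol substrate ratio (COD basis) from the ethanol COD fraction."""
    if not 0.0 <= ethanol_cod_fraction < 1.0:
        raise ValueError("ethanol COD fraction must lie in [0, 1)")
    return ethanol_cod_fraction / (1.0 - ethanol_cod_fraction)


def gas_cod_rate(ch4_mol_d: float, h2_mol_d: float, volume_l: float) -> float:
    """Volumetric COD rate (g COD/L-d) of the reduced gases CH4 and H2.

    Uses the ThOD factors 64 (CH4) and 16 (H2) g COD/mol.
    """
    if ch4_mol_d < 0 or h2_mol_d < 0:
        raise ValueError("gas rates must be nonnegative")
    if volume_l <= 0:
        raise ValueError("working volume must be positive")
    return (_CH4_COD * ch4_mol_d + _H2_COD * h2_mol_d) / volume_l


def upflow_velocity(q_l_d: float, inner_diameter_m: float) -> float:
    """Upflow hydraulic velocity (m/h) through the reactor column.

    Volumetric flow (L/d -> m3/d) over the column cross-section, converted
    from m/d to m/h.
    """
    if q_l_d < 0:
        raise ValueError("flow must be nonnegative")
    if inner_diameter_m <= 0:
        raise ValueError("diameter must be positive")
    area_m2 = math.pi * (inner_diameter_m / 2.0) ** 2
    return (q_l_d / 1000.0) / area_m2 / 24.0


@dataclass
class PeriodPerformance:
    """All COD-basis performance figures for one operating period.

    Rates are g COD/d, productivities g COD/L-d, fluxes g COD/m2-d;
    yield and specificities are fractions.  ``production[s] ==
    extraction[s] + washout[s]`` holds exactly by construction.
    """

    period_id: str
    extraction: dict[str, float]
    washout: dict[str, float]
    production: dict[str, float]
    productivity: dict[str, float]
    flux: dict[str, float]
    mcc_production: float
    mcc_productivity: float
    mcc_flux: float
    mcc_yield: Optional[float]
    specificity: dict[str, float]
    product_ratio_c8_c6: Optional[float]
    gas_cod_rate: Optional[float] = None
    t_start: float = 0.0
    t_end: float = 0.0
    olr_gcod_l_d: float = float("nan")
    hrt_d: float = float("nan")
    q_recycle_l_d: float = float("nan")
    phase: Optional[str] = None
    missing_fits: list[str] = field(default_factory=list)
    missing_broth: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _mean_broth_concentrations(
    broth_series: pd.DataFrame,
    period: PeriodDefinition,
    include_boundaries: bool = True,
    exclude_transition_days: float = 0.0,
) -> dict[str, float]:
    df = broth_series
    lo = period.t_start + exclude_transition_days
    hi = period.t_end - exclude_transition_days
    if include_boundaries:
        mask = (df["time_d"] >= lo) & (df["time_d"] <= hi)
    else:
        mask = (df["time_d"] > lo) & (df["time_d"] < hi)
    window = df.loc[mask & (df["location"] == "broth")]
    return window.groupby("species")["value"].mean().to_dict()


def production_summary(
    period: PeriodDefinition,
    fits: Mapping[str, ExtractionFit],
    broth_series: pd.DataFrame,
    *,
    a_transfer_m2: float = 1.4,
    registry: Optional[SpeciesRegistry] = None,
    mcc_species: Sequence[str] = MCC_SPECIES,
    gas_rate: Optional[float] = None,
    exclude_transition_days: float = 0.0,
) -> PeriodPerformance:
    """Assemble the full period mass balance from fits and broth data.

    Parameters
    ----------
    period:
        Operating-period hydraulics (provides V, OLR, Q_effluent, window).
    fits:
        Per-species :class:`ExtractionFit` (keys resolve in the registry).
        Products seen in the broth but lacking a fit get extraction 0 and
        are listed in ``missing_fits`` (never silently dropped).
    broth_series:
        Long-format frame with columns ``time_d, location, species, value``
        where value is g COD/L for broth rows.
    a_transfer_m2:
        Forward-contactor membrane area for the flux normalisation.
    gas_rate:
        Optional reduced-gas COD rate (g COD/L-d), carried through verbatim.
    exclude_transition_days:
        Shrink the averaging window at both ends (default: none; boundary
        samples are included).
    """
    if period.volume_l <= 0:
        raise ValueError(f"{period.period_id}: working volume must be positive")
    reg = registry or default_registry()

    means = _mean_broth_concentrations(
        broth_series, period, exclude_transition_days=exclude_transition_days
    )
    means = {reg.canonical_name(s): v for s, v in means.items()}
    fits = {reg.canonical_name(s): f for s, f in fits.items()}

    ethanol = reg.canonical_name("ethanol")
    products = sorted(
        (set(fits) | set(means)) - {ethanol},
        key=lambda s: reg.get(s).carbon_number,
    )

    extraction: dict[str, float] = {}
    washout: dict[str, float] = {}
    production: dict[str, float] = {}
    missing_fits, missing_broth, warns = [], [], []
    for s in products:
        fit = fits.get(s)
        if fit is None:
            missing_fits.append(s)
            ext = 0.0
        else:
            ext = fit.slope
            if fit.negative_slope:
                warns.append(f"{s}: negative extraction slope {fit.slope:.4g} g COD/d")
        if s in means:
            wo = washout_rate(means[s], period.q_effluent_l_d)
        else:
            missing_broth.append(s)
            wo = 0.0
        extraction[s] = ext
        washout[s] = wo
        production[s] = ext + wo

    productivity = {s: production[s] / period.volume_l for s in products}
    flux = {s: production[s] / a_transfer_m2 for s in products}

    mcc = [reg.canonical_name(s) for s in mcc_species]
    mcc_production = sum(production.get(s, 0.0) for s in mcc)
    mcc_productivity = mcc_production / period.volume_l
    mcc_flux = mcc_production / a_transfer_m2

    if period.olr_gcod_l_d > 0:
        mcc_yield = mcc_productivity / period.olr_gcod_l_d
    elif mcc_productivity == 0:
        mcc_yield = None
    else:
        raise ZeroDivisionError(
            f"{period.period_id}: yield undefined at zero OLR with nonzero production"
        )

    total_production = sum(production.values())
    specificity = {
        s: (production[s] / total_production if total_production > 0 else float("nan"))
        for s in products
    }

    c6 = reg.canonical_name("n-caproate")
    c8 = reg.canonical_name("n-caprylate")
    if production.get(c6, 0.0) > 0:
        ratio = production.get(c8, 0.0) / production[c6]
    else:
        ratio = None
        if production.get(c8, 0.0) > 0:
            warns.append("C8:C6 ratio undefined (no n-caproate production)")

    return PeriodPerformance(
        period_id=period.period_id,
        extraction=extraction,
        washout=washout,
        production=production,
        productivity=productivity,
        flux=flux,
        mcc_production=mcc_production,
        mcc_productivity=mcc_productivity,
        mcc_flux=mcc_flux,
        mcc_yield=mcc_yield,
        specificity=specificity,
        product_ratio_c8_c6=ratio,
        gas_cod_rate=gas_rate,
        t_start=period.t_start,
        t_end=period.t_end,
        olr_gcod_l_d=period.olr_gcod_l_d,
        hrt_d=period.hrt_d,
        q_recycle_l_d=period.q_recycle_l_d,
        phase=period.phase,
        missing_fits=missing_fits,
        missing_broth=missing_broth,
        warnings=warns,
    )


def summarize_periods(
    timeseries: pd.DataFrame,
    periods: Sequence[PeriodDefinition],
    *,
    a_transfer_m2: float = 1.4,
    registry: Optional[SpeciesRegistry] = None,
    exclude_transition_days: float = 0.0,
) -> list[PeriodPerformance]:
    """Run the full per-period accounting over a normalised time series.

    For every period, fits each species' extraction rate from its
    extract_solution rows inside the window, then assembles the mass balance
    with :func:`production_summary`.  Species with fewer than 2 trap samples
    in a window simply have no fit there (they appear in ``missing_fits``).
    """
    reg = registry or default_registry()
    results = []
    for period in periods:
        window = timeseries[
            (timeseries["time_d"] >= period.t_start)
            & (timeseries["time_d"] <= period.t_end)
        ]
        trap = window[window["location"] == "extract_solution"]
        fits: dict[str, ExtractionFit] = {}
        for species, grp in trap.groupby("species"):
            grp = grp.sort_values("time_d")
            if len(grp) < 2:
                continue
            fits[str(species)] = fit_extraction_rate(
                grp["time_d"].to_numpy(), grp["value"].to_numpy(), str(species)
            )
        results.append(
            production_summary(
                period,
                fits,
                window,
                a_transfer_m2=a_transfer_m2,
                registry=reg,
                exclude_transition_days=exclude_transition_days,
            )
        )
    return results
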