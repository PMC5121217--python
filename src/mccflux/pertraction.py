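"""Membrane-pertraction mass-transfer layer.

The in-line extraction system pumps bioreactor broth through the shell side
of a hollow-fiber forward membrane contactor.  The extraction rate of
undissociated medium-chain carboxylic acids (MCCAs) follows

    M = k * A_transfer * dC

with M in g COD/d, membrane area A_transfer in m2, the undissociated-MCCA
concentration gradient dC in g COD/L and the overall mass transfer
coefficient k in mm/d (the unit identity L m^-2 d^-1 == mm/d makes the
equation numerically consistent without conversion factors).  k rises
linearly with the broth-recycle superficial velocity u (m/d) through the
contactor shell; fitting that line on per-period (u, k) points gives a
correlation that predicts extraction — and hence total MCC production flux —
for other reactor/contactor configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rates import fit_extraction_rate, PeriodDefinition
from .species import SpeciesRegistry, default_registry, undissociated_fraction

__all__ = [
    "ContactorGeometry",
    "KUPoint",
    "KUModel",
    "StudyRecord",
    "PUBLISHED_KU_MODEL",
    "UndefinedCoefficientError",
    "SingularFitError",
    "IncompleteRecordError",
    "superficial_velocity",
    "mass_transfer_coefficient",
    "gradient_approximation",
    "fit_ku",
    "predict_k",
    "predict_washout",
    "predict_flux",
    "predict_flux_table",
    "r_squared",
    "estimate_ku_from_timeseries",
]


class UndefinedCoefficientError(ZeroDivisionError):
    """Raised when k is requested at a zero concentration gradient."""


class SingularFitError(ValueError):
    """Raised when a k-u fit is attempted on degenerate velocities."""


class IncompleteRecordError(ValueError):
    """Raised when a cross-study record is missing required fields."""


@dataclass(frozen=True)
class ContactorGeometry:
    """Hollow-fiber contactor geometry: membrane area and shell cross-section.

    Defaults are the 2.5x8 module used here (A_transfer 1.4 m2,
    A_cross 1.56e-3 m2).
    """

    a_transfer_m2: float = 1.4
    a_cross_m2: float = 1.56e-3

    def __post_init__(self) -> None:
        if self.a_transfer_m2 <= 0 or self.a_cross_m2 <= 0:
            raise ValueError("contactor areas must be positive")


@dataclass(frozen=True)
class KUPoint:
    """One (superficial velocity, mass transfer coefficient) observation."""

    u_m_d: float
    k_mm_d: float
    period_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.u_m_d < 0 or self.k_mm_d < 0:
            raise ValueError("u and k must be nonnegative")


@dataclass(frozen=True)
class KUModel:
    """Linear correlation k = slope * u + intercept (k mm/d, u m/d)."""

    slope: float
    intercept: float
    r_squared: Optional[float] = None
    n_points: int = 0
    slope_se: Optional[float] = None
    intercept_se: Optional[float] = None
    u_min: Optional[float] = None
    u_max: Optional[float] = None

    def extrapolates(self, u: float) -> bool:
        """True when u lies outside the fitted velocity range."""
        if self.u_min is None or self.u_max is None:
            return False
        return u < self.u_min or u > self.u_max


#: The correlation fitted on Periods 2-5 of this system, shipped as the
#: default prediction model when no local fit exists.
PUBLISHED_KU_MODEL = KUModel(slope=0.24, intercept=1.31)


def superficial_velocity(q_recycle_l_d: float, a_cross_m2: float = 1.56e-3) -> float:
    """Broth-recycle superficial velocity (m/d) through the contactor shell."""
    if q_recycle_l_d < 0:
        raise ValueError("recycle flow must be nonnegative")
    if a_cross_m2 <= 0:
        raise ValueError("cross-sectional area must be positive")
    return (q_recycle_l_d / 1000.0) / a_cross_m2


def mass_transfer_coefficient(
    m_gcod_d: float, a_transfer_m2: float, delta_c_gcod_l: float
) -> float:
    """Overall mass transfer coefficient k (mm/d) from the extraction rate.

    k = M / (A_transfer * dC).  Dimensionally M/(A*dC) is L m^-2 d^-1,
    which equals mm/d exactly (1 L/m2 = 1 mm), so no numeric conversion is
    applied.
    """
    if a_transfer_m2 <= 0:
        raise ValueError("membrane area must be positive")
    if delta_c_gcod_l < 0:
        raise ValueError("concentration gradient must be nonnegative")
    if delta_c_gcod_l == 0:
        raise UndefinedCoefficientError(
            "mass transfer coefficient undefined at zero concentration gradient"
        )
    return m_gcod_d / (a_transfer_m2 * delta_c_gcod_l)


def gradient_approximation(
    c_broth_undiss: float, c_extract_undiss: float = 0.0, broth_only: bool = False
) -> float:
    """Undissociated-MCCA gradient across the forward membrane (g COD/L).

    Exact difference by default.  With ``broth_only=True`` the trap-side
    term is dropped — the alkaline extraction solution (pH 9) holds a
    negligible undissociated concentration, so the gradient is approximated
    by the broth concentration alone.
    """
    if c_broth_undiss < 0 or c_extract_undiss < 0:
        raise ValueError("concentrations must be nonnegative")
    if broth_only:
        return c_broth_undiss
    return c_broth_undiss - c_extract_undiss


def fit_ku(points: Iterable[KUPoint]) -> KUModel:
    """Unweighted OLS of k on u over per-period observations."""
    pts = list(points)
    if len(pts) < 2:
        raise SingularFitError("need >= 2 points to fit the k-u line")
    u = np.array([p.u_m_d for p in pts], dtype=float)
    k = np.array([p.k_mm_d for p in pts], dtype=float)
    if np.ptp(u) == 0:
        raise SingularFitError("all superficial velocities identical; fit is singular")
    res = stats.linregress(u, k)
    return KUModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(pts),
        slope_se=float(res.stderr) if len(pts) > 2 else None,
        intercept_se=float(res.intercept_stderr) if len(pts) > 2 else None,
        u_min=float(u.min()),
        u_max=float(u.max()),
    )


def predict_k(model: KUModel, u_m_d: float) -> float:
    """Evaluate the k-u line at a superficial velocity, floored at zero."""
    if u_m_d < 0:
        raise ValueError("superficial velocity must be nonnegative")
    return max(0.0, model.slope * u_m_d + model.intercept)


def predict_washout(volume_l: float, c_mcc_gcod_l: float, hrt_d: float) -> float:
    """Washout rate (g COD/d) = V * C_MCC / HRT."""
    if hrt_d <= 0:
        raise ValueError("HRT must be positive")
    if volume_l < 0 or c_mcc_gcod_l < 0:
        raise ValueError("volume and concentration must be nonnegative")
    return volume_l * c_mcc_gcod_l / hrt_d


@dataclass(frozen=True)
class StudyRecord:
    """Cross-study inputs for the flux prediction (one reactor/contactor).

    Fields follow the comparison exercise: recycle superficial velocity,
    membrane area, undissociated MCCA broth concentration (the gradient
    approximation), plus V, total MCC broth concentration and HRT for the
    washout term.  ``observed_flux`` is optional.
    """

    label: str
    u_m_d: float
    a_transfer_m2: float
    c_mcca_undiss_gcod_l: float
    volume_l: float
    c_mcc_broth_gcod_l: float
    hrt_d: float
    observed_flux: Optional[float] = None

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                if v < 0:
                    raise ValueError(f"{self.label}: {f.name} must be nonnegative")


_REQUIRED_STUDY_FIELDS = (
    "u_m_d",
    "a_transfer_m2",
    "c_mcca_undiss_gcod_l",
    "volume_l",
    "c_mcc_broth_gcod_l",
    "hrt_d",
)


def predict_flux(model: KUModel, study: StudyRecord) -> float:
    """Predicted MCC production flux (g COD/m2-d) for one study.

    Extraction M = k(u) * A_transfer * C_MCCA_undiss plus the washout term
    V*C_MCC/HRT, normalised by the study's own membrane area.
    """
    missing = [
        f
        for f in _REQUIRED_STUDY_FIELDS
        if getattr(study, f) is None or not math.isfinite(getattr(study, f))
    ]
    if missing:
        raise IncompleteRecordError(
            f"{study.label}: missing field(s) {', '.join(missing)}"
        )
    k = predict_k(model, study.u_m_d)  # mm/d == L m^-2 d^-1
    extraction = k * study.a_transfer_m2 * study.c_mcca_undiss_gcod_l
    washout = predict_washout(study.volume_l, study.c_mcc_broth_gcod_l, study.hrt_d)
    return (extraction + washout) / study.a_transfer_m2


def predict_flux_table(
    model: KUModel, studies: Sequence[StudyRecord]
) -> pd.DataFrame:
    """Batch flux prediction with residuals and an extrapolation flag."""
    rows = []
    for s in studies:
        pred = predict_flux(model, s)
        rows.append(
            {
                "label": s.label,
                "u_m_d": s.u_m_d,
                "predicted_flux": pred,
                "observed_flux": s.observed_flux,
                "residual": (s.observed_flux - pred) if s.observed_flux is not None else None,
                "extrapolated": model.extrapolates(s.u_m_d),
            }
        )
    return pd.DataFrame(rows)


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination between observed and predicted values.

    Convention: the squared Pearson correlation of the two vectors (a
    constant prediction therefore scores 0, not negative).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D and equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 pairs")
    if np.std(obs) == 0 or np.std(pred) == 0:
        return 0.0
    r, _ = stats.pearsonr(obs, pred)
    return float(r**2)


def estimate_ku_from_timeseries(
    timeseries: pd.DataFrame,
    periods: Sequence[PeriodDefinition],
    *,
    geometry: ContactorGeometry = ContactorGeometry(),
    ph: float = 5.2,
    registry: Optional[SpeciesRegistry] = None,
    mcc_species: Sequence[str] = ("n-caproate", "n-caprylate"),
) -> tuple[KUModel, list[KUPoint], dict[str, object]]:
    """Recover the k-u correlation from raw broth/trap time series.

    Per period: (1) fit the lumped-MCCA extraction rate as the OLS slope of
    the summed C6+C8 cumulative trap amounts; (2) estimate the gradient as
    the period-mean broth concentration of undissociated MCCAs (broth-only
    approximation); (3) k = M/(A*dC); then fit the k-u line across periods.

    Returns the fitted model, the per-period points, and diagnostics
    (per-period extraction fits and mean gradients).
    """
    reg = registry or default_registry()
    mcc = [reg.canonical_name(s) for s in mcc_species]
    points: list[KUPoint] = []
    diag: dict[str, object] = {"extraction_fits": {}, "mean_gradient": {}}
    for period in periods:
        window = timeseries[
            (timeseries["time_d"] >= period.t_start)
            & (timeseries["time_d"] <= period.t_end)
        ]
        trap = window[
            (window["location"] == "extract_solution")
            & (window["species"].isin(mcc))
        ]
        lumped = (
            trap.pivot_table(index="time_d", columns="species", values="value")
            .sum(axis=1)
            .sort_index()
        )
        fit = fit_extraction_rate(lumped.index.to_numpy(), lumped.to_numpy(), "MCCA")
        broth = window[(window["location"] == "broth") & (window["species"].isin(mcc))]
        undiss = broth.assign(
            undiss=lambda d: d.apply(
                lambda row: row["value"]
                * undissociated_fraction(ph, reg.get(row["species"]).pka),
                axis=1,
            )
        )
        mean_undiss = float(
            undiss.pivot_table(index="time_d", columns="species", values="undiss")
            .sum(axis=1)
            .mean()
        )
        dc = gradient_approximation(mean_undiss, broth_only=True)
        k = mass_transfer_coefficient(fit.slope, geometry.a_transfer_m2, dc)
        u = superficial_velocity(period.q_recycle_l_d, geometry.a_cross_m2)
        points.append(KUPoint(u_m_d=u, k_mm_d=k, period_id=period.period_id))
        diag["extraction_fits"][period.period_id] = fit
        diag["mean_gradient"][period.period_id] = dc
    model = fit_ku(points)
    return model, points, diag
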