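"""Retinol isotope dilution equations and model-derived coefficients.

The RID family of equations predicts vitamin A total body stores (TBS)
from a single plasma specific-activity (SA) measurement after an oral
labeled dose:

* the original liver-reserves equation,
  ``TLR = F * dose * S * a * (H:D - 1)``, with literature coefficients;
* its modified form, ``TBS = Fa * S / SA_p``, whose time-varying
  coefficients Fa(t) (fraction of the dose in stores) and S(t)
  (plasma-to-store SA ratio) are read off a compartmental model solution:

  ``Fa(t)  = F6(t) + F7(t)``
  ``S(t)   = [F5(t)/M5] / [(F6+F7)(t)/(M6+M7)]``
  ``FaS(t) = [F5(t)/M5] * (M6+M7)``

  so that ``FaS = Fa * S`` identically and ``FaS / SA_p`` recovers
  ``M6+M7`` exactly when a subject's own coefficients are used.

  where F(I) is the fraction of the dose in compartment I and M(I) its
  tracee mass.  The long-time plateau of S(t) is
  ``S_eq = R(5,6) / [R(5,4) + R(5,6)]`` with R(I,J) the steady-state mass
  flux to I from J: the higher the dietary inflow relative to recycling
  from stores, the farther below 1 the plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .kinetics import SteadyStateMasses, TracerTrajectory
from .parameters import KineticParameters

__all__ = [
    "OlsonInputs",
    "RIDCoefficientCurve",
    "TBSPrediction",
    "EARLIEST_VALIDATED_DAY",
    "olson_tlr",
    "modified_tbs",
    "coefficients_from_model",
    "s_equilibrium",
    "predict_tbs",
    "tbs_ratio",
]

#: Earliest sampling day for which the single-sample prediction is
#: considered validated (the dose must first mix with stores).
EARLIEST_VALIDATED_DAY = 4.0


@dataclass(frozen=True)
class OlsonInputs:
    """Inputs to the original total-liver-reserves equation.

    ``f_abs_retained`` is the fraction of the dose absorbed and retained
    (F), ``a_catabolism`` the correction for post-absorption catabolic
    loss (a), ``s_ratio`` the plasma/liver SA ratio (S), and ``h_to_d``
    the post-mixing hydrogen-to-deuterium ratio, i.e. the reciprocal of
    the tracer-to-tracee ratio.
    """

    f_abs_retained: float
    a_catabolism: float
    s_ratio: float
    dose: float
    h_to_d: float

    def __post_init__(self) -> None:
        for name in ("f_abs_retained", "a_catabolism", "s_ratio", "dose", "h_to_d"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")


@dataclass(frozen=True)
class TBSPrediction:
    """A single-subject TBS prediction from one plasma SA measurement."""

    subject_id: str
    time: float
    sa_p: float
    tbs: float
    coefficient_source: str = "individual"


@dataclass
class RIDCoefficientCurve:
    """Time courses of the RID coefficients for one parameter set.

    ``s`` is NaN wherever no tracer has reached stores yet.  ``s_eq`` is
    the closed-form equilibrium plasma/store SA ratio (NaN if it was not
    derivable from the inputs at hand).
    """

    times: np.ndarray
    fa: np.ndarray
    s: np.ndarray
    fas: np.ndarray
    s_eq: float = float("nan")
    _fas_interp: PchipInterpolator | None = field(
        default=None, repr=False, compare=False
    )

    def fas_at(self, time: float) -> float:
        """Monotone cubic interpolation of FaS at an arbitrary time."""
        if not self.times[0] <= time <= self.times[-1]:
            raise ValueError(
                f"time {time} outside curve range "
                f"[{self.times[0]}, {self.times[-1]}]"
            )
        if self._fas_interp is None:
            self._fas_interp = PchipInterpolator(self.times, self.fas)
        return float(self._fas_interp(time))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_d": self.times, "fa": self.fa, "s": self.s, "fas": self.fas}
        )


def olson_tlr(inputs: OlsonInputs) -> float:
    """Total liver reserves from the original isotope-dilution equation.

    The ``- 1`` term corrects for the dose's own contribution to stores;
    an H:D ratio at or below 1 means the dose has not yet been diluted by
    body vitamin A and yields a flagged non-positive result.
    """
    if inputs.h_to_d <= 1.0:
        warnings.warn(
            "h_to_d <= 1: the dose is not yet diluted by endogenous "
            "vitamin A; the returned liver reserve is non-positive",
            stacklevel=2,
        )
    return (
        inputs.f_abs_retained
        * inputs.dose
        * inputs.s_ratio
        * inputs.a_catabolism
        * (inputs.h_to_d - 1.0)
    )


def modified_tbs(fa: float, s: float, sa_p: float) -> float:
    """Total body stores from the modified equation, ``Fa * S / SA_p``."""
    if not sa_p > 0.0:
        raise ValueError(f"sa_p must be > 0, got {sa_p!r}")
    return fa * s / sa_p


def coefficients_from_model(
    traj: TracerTrajectory,
    masses: SteadyStateMasses,
    params: KineticParameters | None = None,
) -> RIDCoefficientCurve:
    """Evaluate Fa(t), S(t) and FaS(t) from a model solution.

    ``traj`` and ``masses`` must come from the same parameter set.  When
    ``params`` is supplied, the closed-form equilibrium ratio is attached
    as ``s_eq``.
    """
    if not masses.m_5 > 0.0 or not masses.tbs > 0.0:
        raise ZeroDivisionError("tracee masses must be positive to form SA ratios")
    fa = traj.f_6 + traj.f_7
    sa_p = traj.f_5 / masses.m_5
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(fa > 0.0, sa_p / (fa / masses.tbs), np.nan)
    # Computed independently of fa and s; fas == fa * s is an identity
    # that tests verify rather than impose.
    fas = sa_p * masses.tbs
    s_eq = s_equilibrium(params, masses) if params is not None else float("nan")
    return RIDCoefficientCurve(times=traj.times, fa=fa, s=s, fas=fas, s_eq=s_eq)


def s_equilibrium(params: KineticParameters, masses: SteadyStateMasses) -> float:
    """Closed-form equilibrium plasma/store SA ratio.

    ``R(5,6)/[R(5,4) + R(5,6)]`` with R(5,4) the absorbed dietary inflow
    and R(5,6) the recycling flux from the large store.  With zero intake
    both fluxes vanish with the stores, and the ratio tends to 1
    (isotopic equilibrium); that limit is returned exactly when
    ``dietary_intake = 0`` but the store is non-empty only notionally, so
    a fully empty system raises instead.
    """
    r_5_4 = params.absorption_efficiency * params.dietary_intake
    r_5_6 = params.l_5_6 * masses.m_6
    if r_5_4 + r_5_6 == 0.0:
        if params.dietary_intake == 0.0:
            return 1.0
        raise ZeroDivisionError("both plasma inflows are zero; S_eq undefined")
    return r_5_6 / (r_5_4 + r_5_6)


def predict_tbs(
    curve: RIDCoefficientCurve,
    time: float,
    sa_p: float,
    *,
    subject_id: str = "",
    coefficient_source: str = "individual",
) -> TBSPrediction:
    """Predict one subject's TBS from plasma SA using a coefficient curve.

    Interpolates the composite coefficient FaS at the sampling time and
    returns ``FaS / SA_p``.  Sampling before day 4 is allowed but flagged:
    the dose may not yet have mixed with stores, and the single-sample
    equation is only validated later.
    """
    if not sa_p > 0.0:
        raise ValueError(f"sa_p must be > 0, got {sa_p!r}")
    if time < EARLIEST_VALIDATED_DAY:
        warnings.warn(
            f"sampling time {time} d is before day "
            f"{EARLIEST_VALIDATED_DAY:g}; the dose may not have mixed with "
            "stores and the prediction is outside the validated window",
            stacklevel=2,
        )
    fas = curve.fas_at(time)
    return TBSPrediction(
        subject_id=subject_id,
        time=float(time),
        sa_p=float(sa_p),
        tbs=fas / sa_p,
        coefficient_source=coefficient_source,
    )


def tbs_ratio(
    derived: tuple[float, float], individual: tuple[float, float]
) -> float:
    """Ratio of derived-coefficient TBS to the subject's true TBS.

    Equals ``(Fa_d * S_d) / (Fa_i * S_i)``; the measured plasma SA cancels
    because both predictions divide by the same quantity.
    """
    fa_d, s_d = derived
    fa_i, s_i = individual
    for value in (fa_d, s_d, fa_i, s_i):
        if not value > 0.0:
            raise ValueError("all coefficient values must be positive")
    return (fa_d * s_d) / (fa_i * s_i)
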