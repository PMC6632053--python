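"""Cellular dose-response analysis: normalization, EC50 fitting, censoring,
and the cell/target potency ratio.

Raw plate readouts are normalized to percent-of-maximum using assay-defined
controls: the p53 reporter signal is scaled to the activity induced by a
saturating reference activator, and cytotoxic LDH release is scaled to the
release induced by a lytic peptide.  Normalized curves are fit with a
four-parameter logistic (4PL) on log10 dose.  Compounds showing no
activity up to the highest tested dose are reported as censored bounds
(">50" at the standard 50 uM ceiling), and censoring propagates into the
cell/target ratio EC50[nM] / Kd[nM] — the library's proxy for membrane
permeability (lower ratio = the cellular potency tracks the biochemical
affinity more closely).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import lmfit
import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "CENSOR_MAX_UM",
    "CensoredValue",
    "DoseResponseCurve",
    "PotencyResult",
    "normalize_reporter",
    "normalize_ldh",
    "logistic4",
    "fit_ec50",
    "cell_target_ratio",
    "round_half_up",
]

#: highest tested dose in the cellular assays (uM); inactive entries print ">50"
CENSOR_MAX_UM = 50.0
#: minimum fitted dynamic range (percentage points) to call a compound active
MIN_ACTIVE_RANGE_PCT = 20.0


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up (5 -> 5, 4.5 -> 5)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CensoredValue:
    """A potency known only as a lower-bounded value, rendered '>bound'."""

    bound: float
    direction: str = "greater"
    unit: str = "uM"

    def __post_init__(self) -> None:
        if self.direction != "greater":
            raise ValueError("only '>' censoring is supported")

    def __str__(self) -> str:
        b = self.bound
        return f">{int(b)}" if float(b).is_integer() else f">{b:g}"


@dataclass(frozen=True)
class DoseResponseCurve:
    """Doses (uM, increasing) with responses, plus assay metadata.

    ``response`` holds the raw instrument signal before normalization or
    percent-of-max afterwards; ``fit_ec50`` expects the normalized form.
    """

    dose: NDArray[np.float64]
    response: NDArray[np.float64]
    assay: str = "p53_reporter"
    serum_pct: float = 0.0
    incubation_h: float = 16.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "dose", np.asarray(self.dose, dtype=float))
        object.__setattr__(self, "response", np.asarray(self.response, dtype=float))
        if self.dose.shape != self.response.shape:
            raise ValueError("dose and response must have equal length")
        if np.any(self.dose <= 0):
            raise ValueError("doses must be > 0")
        if self.assay not in ("p53_reporter", "ldh", "counterscreen"):
            raise ValueError(f"unknown assay {self.assay!r}")


@dataclass(frozen=True)
class PotencyResult:
    """EC50 (uM, possibly censored) with 4PL shape parameters.

    A censored result carries no hill/top/bottom claims (they are None).
    """

    ec50: Union[float, CensoredValue]
    hill: Optional[float]
    top: Optional[float]
    bottom: Optional[float]
    converged: bool

    def __post_init__(self) -> None:
        if self.is_censored and any(
            v is not None for v in (self.hill, self.top, self.bottom)
        ):
            raise ValueError("censored results carry no shape parameters")

    @property
    def is_censored(self) -> bool:
        return isinstance(self.ec50, CensoredValue)


def _normalize(raw: ArrayLike, max_control: float, background: float, what: str):
    raw_arr = np.asarray(raw, dtype=float)
    span = max_control - background
    if span <= 0:
        raise ValueError(
            f"degenerate {what} controls: max_control={max_control} <= background={background}"
        )
    out = 100.0 * (raw_arr - background) / span
    if np.any(out < 0):
        warnings.warn(
            f"{int(np.sum(out < 0))} normalized {what} value(s) below 0% "
            "(reported as-is, not clipped)",
            UserWarning,
            stacklevel=3,
        )
    return out


def normalize_reporter(raw: ArrayLike, max_control: float, background: float):
    """Percent-of-max p53 reporter activity.

    100% is the beta-lactamase signal induced by the saturating reference
    activator; values may exceed 100 and negative values are preserved
    (with a warning), never clipped.
    """
    return _normalize(raw, max_control, background, "reporter")


def normalize_ldh(raw: ArrayLike, lytic_control: float, background: float):
    """Percent-of-max LDH release, with 100% defined by the lytic peptide
    control.  Same affine contract as :func:`normalize_reporter`."""
    return _normalize(raw, lytic_control, background, "LDH")


def logistic4(
    dose: ArrayLike, bottom: float, top: float, ec50: float, hill: float
):
    """Four-parameter logistic on log10 dose (Hill model)."""
    d = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (np.log10(ec50) - np.log10(d))))


def fit_ec50(
    curve: DoseResponseCurve, max_tested: float = CENSOR_MAX_UM
) -> PotencyResult:
    """Fit a 4PL to a normalized dose-response curve.

    Returns a censored ``">max_tested"`` result when the fitted EC50
    exceeds the highest tested dose, when the fitted dynamic range falls
    below the activity criterion (top - bottom < 20 percentage points),
    or when the fit fails to converge.
    """
    if len(curve.dose) < 5:
        raise ValueError("need >= 5 doses")
    dose, resp = curve.dose, curve.response

    params = lmfit.Parameters()
    params.add("bottom", value=0.0)
    params.add("top", value=float(np.max(resp)))
    half = 0.5 * (float(np.max(resp)) + float(np.min(resp)))
    above = dose[resp >= half]
    ec50_init = float(above[0]) if above.size else float(np.median(dose))
    params.add("log_ec50", value=math.log10(max(ec50_init, 1e-6)), min=-6, max=6)
    params.add("hill", value=1.0, min=0.05, max=10.0)

    def residual(p: lmfit.Parameters):
        return (
            logistic4(dose, p["bottom"].value, p["top"].value,
                      10.0 ** p["log_ec50"].value, p["hill"].value)
            - resp
        )

    censored = PotencyResult(
        ec50=CensoredValue(max_tested), hill=None, top=None, bottom=None,
        converged=False,
    )
    try:
        out = lmfit.minimize(residual, params, method="leastsq")
    except Exception:
        return censored
    if not out.success:
        return censored
    ec50 = 10.0 ** out.params["log_ec50"].value
    top = float(out.params["top"].value)
    bottom = float(out.params["bottom"].value)
    if ec50 > max_tested or (top - bottom) < MIN_ACTIVE_RANGE_PCT:
        return PotencyResult(
            ec50=CensoredValue(max_tested), hill=None, top=None, bottom=None,
            converged=True,
        )
    return PotencyResult(
        ec50=float(ec50), hill=float(out.params["hill"].value),
        top=top, bottom=bottom, converged=True,
    )


def cell_target_ratio(
    ec50_uM: Union[float, CensoredValue], kd_nM: float
) -> Union[int, CensoredValue]:
    """Cell/target ratio: cellular EC50 over biochemical Kd, same units.

    ratio = 1000 * EC50[uM] / Kd[nM], rounded half-up to the nearest
    integer.  A censored EC50 ">X" propagates to a censored ratio
    ">round(1000*X/Kd)".

    >>> cell_target_ratio(0.54, 18.6)
    29
    >>> str(cell_target_ratio(CensoredValue(50), 6485))
    '>8'
    """
    if kd_nM <= 0:
        raise ValueError("Kd must be > 0")
    if isinstance(ec50_uM, CensoredValue):
        return CensoredValue(
            bound=float(round_half_up(1000.0 * ec50_uM.bound / kd_nM)), unit="fold"
        )
    return round_half_up(1000.0 * float(ec50_uM) / kd_nM)
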