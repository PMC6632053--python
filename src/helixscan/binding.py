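"""Fluorescence-anisotropy binding models for one-site protein-ligand systems.

Two equilibrium models drive the MDM2 binding assay:

*Direct 1:1 titration.*  Protein P is titrated against a fixed
concentration of fluorescent tracer L*.  The bound-tracer fraction comes
from the quadratic mass balance and the measured anisotropy is the linear
map ``r = r0 + (rb - r0) * frac_bound``.

*Competitive displacement.*  An unlabeled competitor L is titrated
against the preformed P:L* complex.  The coupled equilibria

    P + L* <-> PL*   (Kd1)        P + L <-> PL   (Kd2)

reduce to a cubic in free protein whose physically meaningful root has
the exact trigonometric closed form (the Wang solution).  With

    d = Kd1 + Kd2 + Lst + Lt - Pt
    e = (Lt - Pt)*Kd1 + (Lst - Pt)*Kd2 + Kd1*Kd2
    f = -Kd1*Kd2*Pt
    theta = arccos[ (-2 d^3 + 9 d e - 27 f) / (2 sqrt((d^2 - 3 e)^3)) ]

the free-protein concentration is ``(2*sqrt(d^2-3e)*cos(theta/3) - d)/3``
and the bound-tracer fraction is

    frac = (2*sqrt(d^2-3e)*cos(theta/3) - d)
           / (3*Kd1 + 2*sqrt(d^2-3e)*cos(theta/3) - d).

An independent bracketed root-finding solver on the same mass balances
(:func:`solve_equilibrium_numeric`) serves as the oracle certifying the
closed form.

All concentrations are nM throughout; unit conversion happens at I/O.
The assay constants default to the calibrated tracer Kd1 = 13.0 nM with
50 nM tracer and 250 nM protein; validity requires Pt > Lst so that
little free tracer remains at baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import lmfit
import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import brentq

__all__ = [
    "TRACER_KD1_NM",
    "TRACER_LST_NM",
    "ASSAY_PT_NM",
    "DirectBindingParams",
    "CompetitionParams",
    "CompetitionIntermediates",
    "TitrationCurve",
    "FitResult",
    "EquilibriumDomainError",
    "frac_bound_direct",
    "anisotropy_direct",
    "frac_bound_competition",
    "anisotropy_competition",
    "solve_equilibrium_numeric",
    "fit_direct",
    "fit_competition",
]

#: calibrated apparent Kd of the FAM-labeled 12/1 tracer peptide (nM)
TRACER_KD1_NM = 13.0
#: tracer concentration held fixed in competition assays (nM)
TRACER_LST_NM = 50.0
#: MDM2 concentration held fixed in competition assays (nM)
ASSAY_PT_NM = 250.0

_ARCCOS_CLAMP = 1e-9


class EquilibriumDomainError(ValueError):
    """Arccos argument out of [-1, 1] beyond round-off; carries intermediates."""

    def __init__(self, message: str, intermediates: "CompetitionIntermediates"):
        super().__init__(message)
        self.intermediates = intermediates


@dataclass(frozen=True)
class DirectBindingParams:
    """Parameters of the direct 1:1 anisotropy model (concentrations nM)."""

    r0: float
    rb: float
    Kd: float
    Lt: float
    Pt: float

    def __post_init__(self) -> None:
        if self.Kd < 0:
            raise ValueError("Kd must be >= 0")
        if self.Lt <= 0:
            raise ValueError("Lt must be > 0")
        if self.Pt < 0:
            raise ValueError("Pt must be >= 0")


@dataclass(frozen=True)
class CompetitionParams:
    """Parameters of the two-ligand competition model (concentrations nM).

    ``Pt > Lst`` is the assay validity condition: with protein in excess
    of tracer, essentially no free tracer is present at baseline.  The
    equilibrium model itself is defined for any non-negative inputs, so
    violation is exposed via :attr:`assay_valid` (and rejected by the
    fitting routines) rather than by construction.
    """

    Kd1: float
    Kd2: float
    Lst: float
    Lt: float
    Pt: float

    def __post_init__(self) -> None:
        for name in ("Kd1", "Kd2", "Lst", "Lt", "Pt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def assay_valid(self) -> bool:
        return self.Pt > self.Lst


@dataclass(frozen=True)
class CompetitionIntermediates:
    """Cubic coefficients and arccos angle of the closed-form solution."""

    d: float
    e: float
    f: float
    theta: float


@dataclass(frozen=True)
class TitrationCurve:
    """Titrant concentrations (nM) and measured anisotropies, optionally
    with a replicate label per point (replicates are pooled when fitting)."""

    x: NDArray[np.float64]
    r: NDArray[np.float64]
    replicate_id: Optional[NDArray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "r", np.asarray(self.r, dtype=float))
        if self.x.shape != self.r.shape:
            raise ValueError("x and r must have equal length")
        if np.any(self.x < 0):
            raise ValueError("titrant concentrations must be >= 0")
        if self.replicate_id is not None:
            rep = np.asarray(self.replicate_id)
            if rep.shape != self.x.shape:
                raise ValueError("replicate_id must match x in length")
            object.__setattr__(self, "replicate_id", rep)

    def __len__(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class FitResult:
    """Least-squares fit output: point estimates, standard errors,
    convergence status, pooled residual norm and diagnostic flags."""

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    converged: bool
    residual_norm: float
    n_points: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.converged:
            if not all(math.isfinite(v) for v in self.estimates.values()):
                raise ValueError("converged fit must carry finite estimates")
            if not math.isfinite(self.residual_norm):
                raise ValueError("converged fit must carry finite residual norm")


# ---------------------------------------------------------------------------
# forward models


def frac_bound_direct(Kd: float, Lt: float, Pt: ArrayLike) -> NDArray[np.float64] | float:
    """Bound-tracer fraction [PL]/Lt of the 1:1 model (quadratic root).

    Vectorized over ``Pt``.  Continuous in all arguments; exactly 0 at
    Pt = 0 and -> 1 as Kd -> 0 with Pt >= Lt.
    """
    if Lt <= 0:
        raise ValueError("Lt must be > 0")
    if Kd < 0:
        raise ValueError("Kd must be >= 0")
    Pt_arr = np.asarray(Pt, dtype=float)
    if np.any(Pt_arr < 0):
        raise ValueError("Pt must be >= 0")
    s = Kd + Lt + Pt_arr
    disc = np.maximum(s * s - 4.0 * Lt * Pt_arr, 0.0)
    bound = 0.5 * (s - np.sqrt(disc))
    frac = np.clip(bound / Lt, 0.0, 1.0)
    return float(frac) if np.isscalar(Pt) or frac.ndim == 0 else frac


def anisotropy_direct(p: DirectBindingParams) -> float:
    """Anisotropy of the direct titration: r0 + (rb - r0) * frac_bound."""
    return p.r0 + (p.rb - p.r0) * frac_bound_direct(p.Kd, p.Lt, p.Pt)


def _competition_intermediates(
    Kd1: float, Kd2: float, Lst: float, Lt: NDArray[np.float64], Pt: float
):
    d = Kd1 + Kd2 + Lst + Lt - Pt
    e = (Lt - Pt) * Kd1 + (Lst - Pt) * Kd2 + Kd1 * Kd2
    f = -Kd1 * Kd2 * Pt
    return d, e, f


def _free_protein_single_ligand(Kd: float, Lt: float, Pt) -> np.ndarray:
    """Free protein of the one-ligand quadratic equilibrium (vectorized Pt)."""
    Pt_arr = np.asarray(Pt, dtype=float)
    s = Kd + Lt + Pt_arr
    bound = 0.5 * (s - np.sqrt(np.maximum(s * s - 4.0 * Lt * Pt_arr, 0.0)))
    return Pt_arr - bound


def _frac_weak_competitor(
    Kd1: float, Kd2: float, Lst: float, Lt: np.ndarray, Pt: float
) -> np.ndarray:
    """Asymptotic evaluation for a weakly occupying competitor.

    When Lt/(Kd2 + Pt + Lt) is tiny the competitor sequesters a
    negligible protein fraction and the trigonometric expression cancels
    below double precision; the same equilibrium is then evaluated by
    iterating the single-ligand quadratic with the competitor as a
    perturbation of the protein total (contraction factor equals the
    occupancy, so four sweeps reach ~1e-12 relative).
    """
    pf = _free_protein_single_ligand(Kd1, Lst, Pt)
    for _ in range(4):
        pt_eff = Pt - Lt * pf / (Kd2 + pf)
        pf = _free_protein_single_ligand(Kd1, Lst, pt_eff)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(pf > 0, pf / (Kd1 + pf), 0.0)


def frac_bound_competition(p: CompetitionParams, Lt: Optional[ArrayLike] = None):
    """Bound-tracer fraction from the exact cubic closed form.

    ``Lt`` overrides ``p.Lt`` (vectorized) so a whole displacement curve
    can be evaluated from one parameter set.  Certified against
    :func:`solve_equilibrium_numeric` to <= 1e-6 relative error.
    """
    Lt_arr = np.asarray(p.Lt if Lt is None else Lt, dtype=float)
    scalar = Lt_arr.ndim == 0
    Lt_arr = np.atleast_1d(Lt_arr)
    if np.any(Lt_arr < 0):
        raise ValueError("Lt must be >= 0")

    # weak-occupancy regime (incl. Lt = 0 and Kd2 -> inf): the trig form
    # is ill-conditioned there, the quadratic reduction is exact
    weak = Lt_arr / (p.Kd2 + p.Pt + Lt_arr) < 1e-3
    if np.all(weak) and p.Kd1 > 0 and p.Kd2 > 0:
        frac = np.clip(_frac_weak_competitor(p.Kd1, p.Kd2, p.Lst, Lt_arr, p.Pt), 0.0, 1.0)
        return float(frac[0]) if scalar else frac

    d, e, f = _competition_intermediates(p.Kd1, p.Kd2, p.Lst, Lt_arr, p.Pt)
    q = d * d - 3.0 * e
    if np.any(q < 0):
        i = int(np.argmin(q))
        raise EquilibriumDomainError(
            f"d^2 - 3e = {q[i]:.3g} < 0",
            CompetitionIntermediates(float(d[i]), float(e[i]), float(f[i]), math.nan),
        )
    sqrt_q = np.sqrt(q)
    denom = 2.0 * sqrt_q**3
    num = -2.0 * d**3 + 9.0 * d * e - 27.0 * f
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 1.0)
    bad = (np.abs(arg) > 1.0 + _ARCCOS_CLAMP) | ~np.isfinite(arg)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise EquilibriumDomainError(
            f"arccos argument {arg[i]:.6g} outside [-1, 1]",
            CompetitionIntermediates(float(d[i]), float(e[i]), float(f[i]), math.nan),
        )
    theta = np.arccos(np.clip(arg, -1.0, 1.0))
    u = 2.0 * sqrt_q * np.cos(theta / 3.0) - d  # = 3 * [P]free
    u = np.maximum(u, 0.0)
    pf = u / 3.0
    # The trigonometric root cancels catastrophically when [P]free << d;
    # two Newton steps on the cubic Pf^3 + d Pf^2 + e Pf + f restore full
    # relative accuracy (the cubic is well conditioned near its root).
    if p.Kd1 > 0 and p.Kd2 > 0:
        for _ in range(2):
            g = ((pf + d) * pf + e) * pf + f
            dg = (3.0 * pf + 2.0 * d) * pf + e
            step = np.where(dg != 0, g / np.where(dg != 0, dg, 1.0), 0.0)
            pf = np.maximum(pf - step, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(pf > 0, pf / (p.Kd1 + pf), 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    return float(frac[0]) if scalar else frac


def anisotropy_competition(
    r0: float, rb: float, p: CompetitionParams, Lt: Optional[ArrayLike] = None
):
    """Anisotropy of the competition titration: r0 + (rb - r0) * frac."""
    return r0 + (rb - r0) * frac_bound_competition(p, Lt=Lt)


def competition_intermediates(p: CompetitionParams) -> CompetitionIntermediates:
    """Expose the cubic coefficients d, e, f and angle theta for diagnostics."""
    d, e, f = _competition_intermediates(
        p.Kd1, p.Kd2, p.Lst, np.asarray(p.Lt, dtype=float), p.Pt
    )
    q = d * d - 3.0 * e
    arg = (-2.0 * d**3 + 9.0 * d * e - 27.0 * f) / (2.0 * math.sqrt(q**3))
    theta = math.acos(min(1.0, max(-1.0, arg)))
    return CompetitionIntermediates(float(d), float(e), float(f), theta)


# ---------------------------------------------------------------------------
# independent numerical oracle


def solve_equilibrium_numeric(p: CompetitionParams) -> tuple[float, float]:
    """Solve the two-ligand mass balances by bracketed root-finding.

    Finds free protein Pf in [0, Pt] such that

        Pf * (1 + Lst/(Kd1+Pf) + Lt/(Kd2+Pf)) = Pt

    (monotone increasing in Pf, so the bracket cannot fail) and returns
    (bound tracer, bound competitor) in nM.  This solver shares no code
    with the closed form and certifies it.
    """
    if p.Pt == 0:
        return 0.0, 0.0
    if p.Kd1 <= 0 or p.Kd2 <= 0:
        raise ValueError("numerical oracle requires Kd1, Kd2 > 0")

    def g(pf: float) -> float:
        return pf * (1.0 + p.Lst / (p.Kd1 + pf) + p.Lt / (p.Kd2 + pf)) - p.Pt

    pf = brentq(g, 0.0, p.Pt, xtol=1e-300, rtol=8.9e-16, maxiter=500)
    bound_tracer = p.Lst * pf / (p.Kd1 + pf)
    bound_comp = p.Lt * pf / (p.Kd2 + pf)
    residual = abs(pf + bound_tracer + bound_comp - p.Pt)
    if residual > 1e-9 * p.Pt:
        raise RuntimeError(
            f"mass-balance residual {residual:.3g} exceeds tolerance for {p}"
        )
    return bound_tracer, bound_comp


# ---------------------------------------------------------------------------
# fitting


def _stderr_from(params: lmfit.Parameters, name: str) -> float:
    par = params.get(name)
    if par is None or par.stderr is None:
        return math.nan
    return float(par.stderr)


def _kd_initial_guess(x: np.ndarray, r: np.ndarray) -> float:
    """Titrant concentration at the half-range anisotropy (log interpolation)."""
    if not np.all(np.isfinite(r)):
        return max(float(np.median(x[x > 0])) if np.any(x > 0) else 1.0, 1e-3)
    lo, hi = float(np.min(r)), float(np.max(r))
    if hi - lo <= 0:
        return max(float(np.median(x[x > 0])) if np.any(x > 0) else 1.0, 1e-3)
    half = 0.5 * (lo + hi)
    order = np.argsort(x)
    xs, rs = x[order], r[order]
    crossing = np.nonzero(np.diff(np.sign(rs - half)))[0]
    if crossing.size:
        i = int(crossing[0])
        x0, x1 = max(xs[i], 1e-6), max(xs[i + 1], 1e-6)
        r0_, r1_ = rs[i], rs[i + 1]
        t = 0.0 if r1_ == r0_ else (half - r0_) / (r1_ - r0_)
        return float(10 ** (np.log10(x0) + t * (np.log10(x1) - np.log10(x0))))
    return max(float(np.median(xs[xs > 0])) if np.any(xs > 0) else 1.0, 1e-3)


def _run_ls_fit(
    residual, log10_kd0: float, r0_init: float, rb_init: float,
    fixed_r0: Optional[float], fixed_rb: Optional[float], n: int,
    kd_name: str,
) -> FitResult:
    """Multi-start local least squares over (log10 Kd, r0, rb)."""
    best = None
    for offset in (-1.5, 0.0, 1.5):  # 3 decades around the heuristic start
        params = lmfit.Parameters()
        params.add("log10_kd", value=log10_kd0 + offset, min=-6.0, max=9.0)
        params.add("r0", value=r0_init, vary=fixed_r0 is None)
        params.add("rb", value=rb_init, vary=fixed_rb is None)
        if fixed_r0 is not None:
            params["r0"].value = fixed_r0
        if fixed_rb is not None:
            params["rb"].value = fixed_rb
        try:
            out = lmfit.minimize(residual, params, method="leastsq")
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None or not best.success:
        return FitResult(
            estimates={}, standard_errors={}, converged=False,
            residual_norm=math.nan, n_points=n,
        )
    kd = 10.0 ** best.params["log10_kd"].value
    se_log = _stderr_from(best.params, "log10_kd")
    estimates = {
        kd_name: kd,
        "r0": float(best.params["r0"].value),
        "rb": float(best.params["rb"].value),
    }
    ses = {
        kd_name: kd * math.log(10.0) * se_log,  # delta method on log10 scale
        "r0": _stderr_from(best.params, "r0"),
        "rb": _stderr_from(best.params, "rb"),
    }
    flags = []
    if estimates["rb"] < estimates["r0"]:
        flags.append("rb_below_r0")
    return FitResult(
        estimates=estimates,
        standard_errors=ses,
        converged=True,
        residual_norm=float(math.sqrt(best.chisqr)),
        n_points=n,
        flags=tuple(flags),
    )


def fit_direct(
    curve: TitrationCurve,
    Lt: float = TRACER_LST_NM,
    fixed_r0: Optional[float] = None,
    fixed_rb: Optional[float] = None,
) -> FitResult:
    """Fit the direct 1:1 model to a protein titration of the tracer.

    Free parameters are (Kd, r0, rb); Kd is positive by log10
    parameterization, r0/rb may be held fixed.  Replicate points are
    pooled.  Non-convergence yields ``converged=False``, never raises.
    """
    if len(curve) < 5:
        raise ValueError("need >= 5 titration points")
    x, r = curve.x, curve.r

    def residual(params: lmfit.Parameters):
        kd = 10.0 ** params["log10_kd"].value
        frac = frac_bound_direct(kd, Lt, x)
        model = params["r0"].value + (params["rb"].value - params["r0"].value) * frac
        return model - r

    kd0 = _kd_initial_guess(x, r)
    result = _run_ls_fit(
        residual, math.log10(kd0), float(np.min(r)), float(np.max(r)),
        fixed_r0, fixed_rb, len(curve), "Kd",
    )
    if result.converged and float(np.max(r)) - float(np.min(r)) < 1e-12:
        # zero dynamic range: Kd unidentifiable
        ses = dict(result.standard_errors)
        ses["Kd"] = math.inf
        result = FitResult(
            result.estimates, ses, True, result.residual_norm,
            result.n_points, result.flags + ("no_dynamic_range",),
        )
    return result


def fit_competition(
    curve: TitrationCurve,
    Kd1: float = TRACER_KD1_NM,
    Lst: float = TRACER_LST_NM,
    Pt: float = ASSAY_PT_NM,
    fixed_r0: Optional[float] = None,
    fixed_rb: Optional[float] = None,
    free_tracer_r0: Optional[float] = None,
) -> FitResult:
    """Fit the competition model for the apparent Kd2 of an unlabeled ligand.

    ``curve.x`` holds competitor concentrations (nM); the assay constants
    Kd1/Lst/Pt are held fixed at the calibrated values.  If
    ``free_tracer_r0`` (anisotropy of tracer alone) is supplied and the
    final titration baseline falls below it, the diagnostic flag
    ``baseline_below_free_tracer`` is set — the assay's signature of an
    unintended ligand-tracer interaction.
    """
    if Pt <= Lst:
        raise ValueError("validity condition Pt > Lst violated")
    if len(curve) < 5:
        raise ValueError("need >= 5 titration points")
    x, r = curve.x, curve.r

    def residual(params: lmfit.Parameters):
        kd2 = 10.0 ** params["log10_kd"].value
        p = CompetitionParams(Kd1=Kd1, Kd2=kd2, Lst=Lst, Lt=0.0, Pt=Pt)
        frac = frac_bound_competition(p, Lt=x)
        model = params["r0"].value + (params["rb"].value - params["r0"].value) * frac
        return model - r

    kd0 = _kd_initial_guess(x, r)
    result = _run_ls_fit(
        residual, math.log10(kd0), float(np.min(r)), float(np.max(r)),
        fixed_r0, fixed_rb, len(curve), "Kd2",
    )
    if free_tracer_r0 is not None and result.converged:
        tail = float(r[np.argmax(x)])
        if tail < free_tracer_r0 or result.estimates["r0"] < free_tracer_r0:
            result = FitResult(
                result.estimates, result.standard_errors, result.converged,
                result.residual_norm, result.n_points,
                result.flags + ("baseline_below_free_tracer",),
            )
    return result
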