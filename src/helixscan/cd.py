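"""Circular-dichroism helicity analysis.

Raw far-UV CD ellipticity (millidegrees) is converted to mean residue
ellipticity

    MRE(lambda) = theta_mdeg(lambda) / (10 * C * l * n)

with molar peptide concentration C, pathlength l in cm and n residues.
Fractional alpha-helicity is then estimated by either of two transparent
estimators:

* ``single_wavelength_222`` — the classic two-state formula on the
  222 nm band,

      f = (MRE222 - theta_coil) / (theta_helix_inf * (1 - k/n) - theta_coil)

  with the Luo-Baldwin-style constants theta_helix_inf = -39500
  deg cm^2 dmol^-1, chain-length correction k = 2.57, and
  theta_coil = -3000 (all overridable).

* ``basis_nnls`` — a non-negative least-squares decomposition of the
  whole spectrum onto helix/coil (optionally sheet) reference shapes,
  constrained to sum to one; the helix coefficient is reported.

The reference shapes are synthetic literature-shaped basis curves
(Gaussian bands at the canonical 193/208/222 nm helix and ~198 nm coil
positions), anchored at 222 nm to the same constants as the two-state
formula so the two estimators agree on idealized spectra.  Neither
estimator replicates proprietary neural-network deconvolution; printed
library helicities are treated as input data downstream, not as
reproduction targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.optimize import nnls

__all__ = [
    "HelixConstants",
    "CDSpectrum",
    "MRESpectrum",
    "HelicityEstimate",
    "ellipticity_to_mre",
    "helicity_single_wavelength",
    "helicity_basis_fit",
    "reference_basis",
]


@dataclass(frozen=True)
class HelixConstants:
    """Two-state helix-coil constants (deg cm^2 dmol^-1 per residue)."""

    theta_helix_inf: float = -39500.0
    k: float = 2.57
    theta_coil: float = -3000.0

    def theta_helix(self, n_residues: int) -> float:
        """Finite-length 222 nm MRE of a fully helical n-residue chain."""
        return self.theta_helix_inf * (1.0 - self.k / n_residues)


@dataclass(frozen=True)
class CDSpectrum:
    """Raw ellipticity (mdeg) over wavelength (nm) with sample metadata."""

    wavelength: NDArray[np.float64]
    ellipticity_mdeg: NDArray[np.float64]
    conc_M: float
    path_cm: float
    n_residues: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelength", np.asarray(self.wavelength, dtype=float))
        object.__setattr__(
            self, "ellipticity_mdeg", np.asarray(self.ellipticity_mdeg, dtype=float)
        )
        if self.wavelength.shape != self.ellipticity_mdeg.shape:
            raise ValueError("wavelength and ellipticity must have equal length")
        dw = np.diff(self.wavelength)
        if not (np.all(dw > 0) or np.all(dw < 0)):
            raise ValueError("wavelengths must be strictly monotone")
        if self.conc_M <= 0 or self.path_cm <= 0:
            raise ValueError("concentration and pathlength must be > 0")
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")


@dataclass(frozen=True)
class MRESpectrum:
    """Mean residue ellipticity (deg cm^2 dmol^-1 per residue)."""

    wavelength: NDArray[np.float64]
    mre: NDArray[np.float64]

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelength", np.asarray(self.wavelength, dtype=float))
        object.__setattr__(self, "mre", np.asarray(self.mre, dtype=float))
        if self.wavelength.shape != self.mre.shape:
            raise ValueError("wavelength and mre must have equal length")

    def at(self, wavelength_nm: float, tol_nm: float = 1.0) -> float:
        """MRE at the nearest sampled wavelength within ``tol_nm``."""
        i = int(np.argmin(np.abs(self.wavelength - wavelength_nm)))
        if abs(self.wavelength[i] - wavelength_nm) > tol_nm:
            raise ValueError(
                f"{wavelength_nm} nm not covered (nearest {self.wavelength[i]} nm)"
            )
        return float(self.mre[i])


@dataclass(frozen=True)
class HelicityEstimate:
    """Fractional helicity with provenance; clipping preserved as a flag."""

    fraction_helix: float
    method: str
    mre_222: float
    out_of_range: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_helix <= 1.0:
            raise ValueError("fraction_helix must lie in [0, 1] after clipping")


def ellipticity_to_mre(s: CDSpectrum) -> MRESpectrum:
    """Convert mdeg to mean residue ellipticity.

    MRE = theta / (10 * C[M] * l[cm] * n_residues); linear in theta and
    inversely proportional to concentration, pathlength and chain length.
    """
    denom = 10.0 * s.conc_M * s.path_cm * s.n_residues
    return MRESpectrum(wavelength=s.wavelength, mre=s.ellipticity_mdeg / denom)


def helicity_single_wavelength(
    m: MRESpectrum,
    n_residues: int,
    constants: HelixConstants = HelixConstants(),
) -> HelicityEstimate:
    """Two-state helicity from the 222 nm mean residue ellipticity."""
    mre222 = m.at(222.0)
    theta_h = constants.theta_helix(n_residues)
    frac = (mre222 - constants.theta_coil) / (theta_h - constants.theta_coil)
    clipped = min(1.0, max(0.0, frac))
    return HelicityEstimate(
        fraction_helix=clipped,
        method="single_wavelength_222",
        mre_222=mre222,
        out_of_range=not math.isclose(frac, clipped, abs_tol=1e-12),
    )


# ---------------------------------------------------------------------------
# reference basis shapes

# Gaussian band parameters (center nm, width nm, relative amplitude) for
# synthetic literature-shaped helix / coil / sheet far-UV CD curves.
_HELIX_BANDS = ((193.0, 6.5, 85000.0), (208.0, 7.5, -34000.0), (222.0, 11.0, -36000.0))
_COIL_BANDS = ((198.0, 8.0, -42000.0), (222.0, 20.0, -2800.0))
_SHEET_BANDS = ((196.0, 7.0, 32000.0), (218.0, 10.0, -15000.0))


def _band_sum(wl: np.ndarray, bands) -> np.ndarray:
    out = np.zeros_like(wl, dtype=float)
    for center, width, amp in bands:
        out += amp * np.exp(-(((wl - center) / width) ** 2))
    return out


def reference_basis(
    wavelengths: ArrayLike,
    n_residues: int = 14,
    constants: HelixConstants = HelixConstants(),
    include_sheet: bool = False,
) -> dict[str, NDArray[np.float64]]:
    """Synthetic helix/coil (and optional sheet) MRE basis spectra.

    The helix and coil shapes are rescaled so their 222 nm values equal
    ``constants.theta_helix(n_residues)`` and ``constants.theta_coil``
    respectively, making the basis decomposition consistent with the
    single-wavelength estimator.
    """
    wl = np.asarray(wavelengths, dtype=float)

    def _anchored(bands, target_222: float) -> np.ndarray:
        raw = _band_sum(wl, bands)
        raw222 = _band_sum(np.array([222.0]), bands)[0]
        return raw * (target_222 / raw222)

    basis = {
        "helix": _anchored(_HELIX_BANDS, constants.theta_helix(n_residues)),
        "coil": _anchored(_COIL_BANDS, constants.theta_coil),
    }
    if include_sheet:
        basis["sheet"] = _band_sum(wl, _SHEET_BANDS)
    return basis


def helicity_basis_fit(
    m: MRESpectrum,
    basis: Optional[dict[str, ArrayLike]] = None,
    n_residues: int = 14,
    constants: HelixConstants = HelixConstants(),
) -> HelicityEstimate:
    """Helicity from a sum-to-one non-negative decomposition of the spectrum.

    ``basis`` maps component names (must include ``helix``) to MRE arrays
    on the spectrum's own wavelength grid; by default the packaged
    helix/coil reference shapes are used.  The constraint sum(c) = 1 is
    imposed by a heavily weighted augmentation row in the NNLS system.
    """
    if basis is None:
        basis = reference_basis(m.wavelength, n_residues, constants)
    if "helix" not in basis:
        raise ValueError("basis must include a 'helix' component")
    names = list(basis)
    B = np.column_stack([np.asarray(basis[k], dtype=float) for k in names])
    if B.shape[0] != m.wavelength.size:
        raise ValueError("basis spectra must match the spectrum's wavelength grid")
    if np.linalg.matrix_rank(B) < B.shape[1]:
        raise ValueError("rank-deficient basis")
    scale = float(np.abs(B).max())
    weight = 1e4 * scale  # enforces sum-to-one to ~1e-4 relative
    A = np.vstack([B, weight * np.ones((1, B.shape[1]))])
    y = np.concatenate([m.mre, [weight]])
    coef, _ = nnls(A, y)
    total = coef.sum()
    if total <= 0:
        raise ValueError("degenerate NNLS solution (all-zero coefficients)")
    frac = coef[names.index("helix")] / total
    clipped = min(1.0, max(0.0, float(frac)))
    return HelicityEstimate(
        fraction_helix=clipped,
        method="basis_nnls",
        mre_222=m.at(222.0),
        out_of_range=not math.isclose(frac, clipped, abs_tol=1e-12),
    )
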