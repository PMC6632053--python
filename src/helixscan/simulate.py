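"""Synthetic-data generators with known ground truth for every input class.

Each generator emulates one instrument readout of the stapled-peptide
pipeline — anisotropy titrations, cellular dose-response curves, far-UV
CD spectra, proteolytic-stability decays, and whole library tables with
a planted lipophilicity -> permeability law — so every analysis stage
can be exercised against a planted truth with no external data.

Reproducibility: one global seed in :class:`GeneratorConfig`; each
generator call derives an independent substream from (seed, stream
label), so adding a call never shifts the draws of earlier ones, and the
same seed and config always reproduce the same bits.

Defaults mirror the assay conditions of the study the pipeline models:
50 nM tracer with Kd1 = 13.0 nM and 250 nM protein for competition
titrations, triplicate titrations with anisotropy noise SD 0.005, a
50 uM dose ceiling, 1 mM peptide in a 0.2 cm cuvette for CD, libraries
of 50 peptides with cell/target ratios spanning roughly 1-1000.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .binding import (
    ASSAY_PT_NM,
    TRACER_KD1_NM,
    TRACER_LST_NM,
    CompetitionParams,
    DirectBindingParams,
    TitrationCurve,
    anisotropy_competition,
    frac_bound_direct,
)
from .cd import CDSpectrum, HelixConstants, reference_basis
from .dose_response import DoseResponseCurve, logistic4
from .library import LibraryTable

__all__ = [
    "GeneratorConfig",
    "gen_direct_titration",
    "gen_competition_titration",
    "gen_dose_response",
    "gen_cd_spectrum",
    "gen_stability_timecourse",
    "gen_library",
    "fixtures_tables_1_2",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Global seed plus per-channel noise SDs.

    sigma_r       anisotropy units (typical replicate scatter 0.005)
    sigma_response  percentage points on normalized cellular readouts
    sigma_mdeg    millidegrees on raw CD ellipticity
    """

    seed: int = 0
    sigma_r: float = 0.005
    sigma_response: float = 5.0
    sigma_mdeg: float = 0.0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        for name in ("sigma_r", "sigma_response", "sigma_mdeg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent substream keyed by (seed, stream label)."""
        label = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence([self.seed, label]))


def _default_pt_grid() -> np.ndarray:
    return np.geomspace(1.0, 1e4, 12)


def gen_direct_titration(
    Kd: float = TRACER_KD1_NM,
    r0: float = 0.05,
    rb: float = 0.25,
    Lt: float = TRACER_LST_NM,
    pt_grid: Optional[Sequence[float]] = None,
    cfg: GeneratorConfig = GeneratorConfig(),
) -> tuple[TitrationCurve, dict]:
    """Protein titration of the tracer: r(Pt) plus Gaussian noise.

    Returns the pooled replicate curve and a truth record.
    """
    pt = np.asarray(pt_grid if pt_grid is not None else _default_pt_grid(), dtype=float)
    frac = frac_bound_direct(Kd, Lt, pt)
    clean = r0 + (rb - r0) * frac
    rng = cfg.rng("direct_titration")
    xs, rs, reps = [], [], []
    for rep in range(cfg.n_replicates):
        noise = rng.normal(0.0, cfg.sigma_r, size=pt.size) if cfg.sigma_r > 0 else 0.0
        xs.append(pt)
        rs.append(clean + noise)
        reps.append(np.full(pt.size, rep))
    curve = TitrationCurve(
        x=np.concatenate(xs), r=np.concatenate(rs), replicate_id=np.concatenate(reps)
    )
    truth = dict(Kd=Kd, r0=r0, rb=rb, Lt=Lt, seed=cfg.seed, sigma_r=cfg.sigma_r)
    return curve, truth


def gen_competition_titration(
    Kd2: float,
    r0: float = 0.05,
    rb: float = 0.25,
    Kd1: float = TRACER_KD1_NM,
    Lst: float = TRACER_LST_NM,
    Pt: float = ASSAY_PT_NM,
    lt_grid: Optional[Sequence[float]] = None,
    cfg: GeneratorConfig = GeneratorConfig(),
) -> tuple[TitrationCurve, dict]:
    """Competitor titration against the preformed protein-tracer complex."""
    lt = np.asarray(
        lt_grid if lt_grid is not None else np.geomspace(1.0, 5e4, 12), dtype=float
    )
    p = CompetitionParams(Kd1=Kd1, Kd2=Kd2, Lst=Lst, Lt=0.0, Pt=Pt)
    clean = anisotropy_competition(r0, rb, p, Lt=lt)
    rng = cfg.rng("competition_titration")
    xs, rs, reps = [], [], []
    for rep in range(cfg.n_replicates):
        noise = rng.normal(0.0, cfg.sigma_r, size=lt.size) if cfg.sigma_r > 0 else 0.0
        xs.append(lt)
        rs.append(clean + noise)
        reps.append(np.full(lt.size, rep))
    curve = TitrationCurve(
        x=np.concatenate(xs), r=np.concatenate(rs), replicate_id=np.concatenate(reps)
    )
    truth = dict(
        Kd2=Kd2, Kd1=Kd1, Lst=Lst, Pt=Pt, r0=r0, rb=rb,
        seed=cfg.seed, sigma_r=cfg.sigma_r,
    )
    return curve, truth


def gen_dose_response(
    ec50_uM: float = 0.54,
    hill: float = 1.5,
    top: float = 100.0,
    bottom: float = 0.0,
    dose_grid: Optional[Sequence[float]] = None,
    assay: str = "p53_reporter",
    cfg: GeneratorConfig = GeneratorConfig(),
) -> tuple[DoseResponseCurve, dict]:
    """Normalized 4PL dose-response curve plus noise.

    A censored scenario arises naturally when the planted EC50 exceeds
    the top of the dose grid.
    """
    dose = np.asarray(
        dose_grid if dose_grid is not None else np.geomspace(0.01, 50.0, 10),
        dtype=float,
    )
    clean = logistic4(dose, bottom, top, ec50_uM, hill)
    rng = cfg.rng("dose_response")
    noise = (
        rng.normal(0.0, cfg.sigma_response, size=dose.size)
        if cfg.sigma_response > 0
        else 0.0
    )
    curve = DoseResponseCurve(dose=dose, response=clean + noise, assay=assay)
    truth = dict(
        ec50_uM=ec50_uM, hill=hill, top=top, bottom=bottom,
        seed=cfg.seed, sigma_response=cfg.sigma_response,
    )
    return curve, truth


def gen_cd_spectrum(
    fraction_helix: float,
    n_residues: int = 14,
    conc_M: float = 1e-3,
    path_cm: float = 0.2,
    wavelengths: Optional[Sequence[float]] = None,
    constants: HelixConstants = HelixConstants(),
    cfg: GeneratorConfig = GeneratorConfig(),
) -> tuple[CDSpectrum, dict]:
    """Far-UV CD spectrum of a two-state helix/coil mixture.

    MRE(lambda) = f * helix(lambda) + (1-f) * coil(lambda) with the
    packaged reference shapes, back-converted to raw millidegrees at the
    stated concentration, pathlength and residue count, plus noise.
    """
    if not 0.0 <= fraction_helix <= 1.0:
        raise ValueError("fraction_helix must lie in [0, 1]")
    wl = np.asarray(
        wavelengths if wavelengths is not None else np.arange(190.0, 301.0, 1.0),
        dtype=float,
    )
    basis = reference_basis(wl, n_residues, constants)
    mre = fraction_helix * basis["helix"] + (1.0 - fraction_helix) * basis["coil"]
    mdeg = mre * 10.0 * conc_M * path_cm * n_residues
    rng = cfg.rng("cd_spectrum")
    noise = rng.normal(0.0, cfg.sigma_mdeg, size=wl.size) if cfg.sigma_mdeg > 0 else 0.0
    spectrum = CDSpectrum(
        wavelength=wl, ellipticity_mdeg=mdeg + noise,
        conc_M=conc_M, path_cm=path_cm, n_residues=n_residues,
    )
    truth = dict(
        fraction_helix=fraction_helix, n_residues=n_residues,
        conc_M=conc_M, path_cm=path_cm, seed=cfg.seed, sigma_mdeg=cfg.sigma_mdeg,
    )
    return spectrum, truth


def gen_stability_timecourse(
    half_life_h: float = 10.0,
    time_grid_h: Sequence[float] = (0.0, 1.0, 2.0, 4.0, 22.0),
    amount_0: float = 1000.0,
    cfg: GeneratorConfig = GeneratorConfig(),
) -> tuple[np.ndarray, np.ndarray, dict]:
    """First-order decay sampled on the standard homogenate time grid."""
    t = np.asarray(time_grid_h, dtype=float)
    raw = amount_0 * 0.5 ** (t / half_life_h)
    truth = dict(half_life_h=half_life_h, amount_0=amount_0, seed=cfg.seed)
    return t, raw, truth


# ---------------------------------------------------------------------------
# library generator

_SUBSTITUTABLE = "ATSERQLKVYFWNH"


def _synthetic_notation(rng: np.random.Generator) -> str:
    """A parseable stapled notation: random core with R8/S5 at 4/11."""
    core = [rng.choice(list(_SUBSTITUTABLE)) for _ in range(11)]
    core[3] = "[R8]"
    core[10] = "[S5]"
    return "Ac-" + "".join(core) + "SAA-amide"


def gen_library(
    n_peptides: int = 50,
    intercept: float = 2.75,
    slope: float = -0.5,
    sigma_log10_ratio: float = 0.5,
    logd_mean: float = 2.5,
    logd_sd: float = 1.0,
    kd_log10_mean: float = 1.5,
    kd_log10_sd: float = 0.5,
    nd_rate: float = 0.05,
    censor_uM: float = 50.0,
    cfg: GeneratorConfig = GeneratorConfig(),
) -> tuple[LibraryTable, dict]:
    """Library with a planted lipophilicity law
    log10(ratio) = intercept + slope * logD + eps, eps ~ N(0, sigma).

    EC50/Kd pairs are back-solved to be exactly consistent with each
    peptide's ratio; EC50s above ``censor_uM`` are stored as censored
    bounds and helicity goes missing ("ND") at ``nd_rate``.  Defaults
    plant expected R^2 = Var(slope*logD)/(Var + sigma^2) = 0.5 on a
    50-peptide library with ratios spanning roughly 1-1000.
    """
    if n_peptides < 3:
        raise ValueError("need >= 3 peptides")
    rng = cfg.rng("library")
    logd = rng.normal(logd_mean, logd_sd, size=n_peptides)
    eps = rng.normal(0.0, sigma_log10_ratio, size=n_peptides)
    log10_ratio = intercept + slope * logd + eps
    ratio = 10.0**log10_ratio
    kd_nM = 10.0 ** rng.normal(kd_log10_mean, kd_log10_sd, size=n_peptides)
    ec50_uM = ratio * kd_nM / 1000.0
    helicity = np.clip(rng.normal(40.0, 8.0, size=n_peptides), 5.0, 80.0)
    nd_mask = rng.random(n_peptides) < nd_rate
    alogp = logd + rng.normal(0.3, 0.2, size=n_peptides)  # correlated descriptor

    # parent sits exactly on the planted law so sigma = 0 yields R^2 = 1
    parent_ratio = 10.0 ** (intercept + slope * logd_mean)
    records = []
    records.append(
        dict(
            name="SYN-PARENT", series="synthetic",
            notation=_synthetic_notation(rng),
            helicity_pct=40.0, ec50_uM=parent_ratio * 20.0 / 1000.0,
            ec50_censored=False, kd_nM=20.0,
            ratio_printed=np.nan, logd=logd_mean, alogp=logd_mean + 0.3,
            parent_name="",
        )
    )
    for i in range(n_peptides):
        censored = ec50_uM[i] > censor_uM
        records.append(
            dict(
                name=f"SYN-{i + 1:03d}", series="synthetic",
                notation=_synthetic_notation(rng),
                helicity_pct=np.nan if nd_mask[i] else float(helicity[i]),
                ec50_uM=float(censor_uM if censored else ec50_uM[i]),
                ec50_censored=bool(censored),
                kd_nM=float(kd_nM[i]), ratio_printed=np.nan,
                logd=float(logd[i]), alogp=float(alogp[i]),
                parent_name="SYN-PARENT",
            )
        )
    table = LibraryTable.from_records(records)
    expected_r2 = (slope**2 * logd_sd**2) / (slope**2 * logd_sd**2 + sigma_log10_ratio**2)
    truth = dict(
        intercept=intercept, slope=slope, sigma_log10_ratio=sigma_log10_ratio,
        logd=logd, ratio=ratio, expected_r_squared=expected_r2,
        n_censored=int(nd_mask.size and np.sum(ec50_uM > censor_uM)),
        seed=cfg.seed,
    )
    return table, truth


def fixtures_tables_1_2() -> LibraryTable:
    """The packaged transcription of the printed 50-peptide library.

    Sentinels survive verbatim: "ND" helicity becomes NaN, EC50 ">50"
    becomes a censored bound, and the printed ratio column is carried for
    lint comparison against the recomputation.
    """
    with resources.files("helixscan.data").joinpath("tables_mdm2.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        raw = pd.read_csv(fh, dtype=str, keep_default_na=False)
    records = []
    for _, row in raw.iterrows():
        ec50_txt = row["ec50_uM"]
        censored = ec50_txt.startswith(">")
        records.append(
            dict(
                name=row["name"],
                series=f"table{row['table']}{row['section'] if row['table'] == '1' else ''}",
                notation=row["notation"],
                helicity_pct=np.nan if row["helicity_pct"] == "ND" else float(row["helicity_pct"]),
                ec50_uM=float(ec50_txt.lstrip(">")),
                ec50_censored=censored,
                kd_nM=float(row["kd_nM"]),
                ratio_printed=row["ratio_printed"],
                logd=np.nan, alogp=np.nan,
                parent_name=row["parent_name"],
            )
        )
    return LibraryTable.from_records(records)
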