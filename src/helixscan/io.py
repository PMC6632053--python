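"""CSV dialects for titrations, dose-response curves, CD spectra and
library tables.

All files are plain headered CSV.  The only sentinel dialects are "ND"
for a missing helicity and a ">" prefix for a censored value; both
survive round-trips verbatim.  CD spectra carry their sample metadata
as leading ``# key=value`` comment lines before the header.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .binding import TitrationCurve
from .cd import CDSpectrum
from .dose_response import DoseResponseCurve
from .library import LibraryTable

__all__ = [
    "read_titration_csv", "write_titration_csv",
    "read_dose_response_csv", "write_dose_response_csv",
    "read_cd_csv", "write_cd_csv",
    "read_library_csv", "write_library_csv",
]

PathLike = Union[str, Path]


def read_titration_csv(path: PathLike) -> TitrationCurve:
    """Columns: conc_nM, anisotropy, replicate (optional)."""
    df = pd.read_csv(path)
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return TitrationCurve(
        x=df["conc_nM"].to_numpy(float),
        r=df["anisotropy"].to_numpy(float),
        replicate_id=rep,
    )


def write_titration_csv(curve: TitrationCurve, path: PathLike) -> None:
    data = {"conc_nM": curve.x, "anisotropy": curve.r}
    if curve.replicate_id is not None:
        data["replicate"] = curve.replicate_id
    pd.DataFrame(data).to_csv(path, index=False)


def read_dose_response_csv(path: PathLike) -> DoseResponseCurve:
    """Columns: dose_uM, signal, assay, serum_pct, incubation_h."""
    df = pd.read_csv(path)
    return DoseResponseCurve(
        dose=df["dose_uM"].to_numpy(float),
        response=df["signal"].to_numpy(float),
        assay=str(df["assay"].iloc[0]) if "assay" in df.columns else "p53_reporter",
        serum_pct=float(df["serum_pct"].iloc[0]) if "serum_pct" in df.columns else 0.0,
        incubation_h=float(df["incubation_h"].iloc[0]) if "incubation_h" in df.columns else 16.0,
    )


def write_dose_response_csv(curve: DoseResponseCurve, path: PathLike) -> None:
    pd.DataFrame(
        {
            "dose_uM": curve.dose,
            "signal": curve.response,
            "assay": curve.assay,
            "serum_pct": curve.serum_pct,
            "incubation_h": curve.incubation_h,
        }
    ).to_csv(path, index=False)


def read_cd_csv(path: PathLike) -> CDSpectrum:
    """Leading '# key=value' metadata (conc_M, path_cm, n_residues), then
    columns wavelength_nm, ellipticity_mdeg."""
    meta: dict[str, float] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    n_meta = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_meta += 1
        key, _, value = line.lstrip("# ").partition("=")
        meta[key.strip()] = float(value)
    df = pd.read_csv(path, skiprows=n_meta)
    try:
        return CDSpectrum(
            wavelength=df["wavelength_nm"].to_numpy(float),
            ellipticity_mdeg=df["ellipticity_mdeg"].to_numpy(float),
            conc_M=meta["conc_M"],
            path_cm=meta["path_cm"],
            n_residues=int(meta["n_residues"]),
        )
    except KeyError as exc:
        raise ValueError(f"CD file {path} missing metadata/column {exc}") from exc


def write_cd_csv(s: CDSpectrum, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# conc_M={s.conc_M}\n# path_cm={s.path_cm}\n# n_residues={s.n_residues}\n")
        pd.DataFrame(
            {"wavelength_nm": s.wavelength, "ellipticity_mdeg": s.ellipticity_mdeg}
        ).to_csv(fh, index=False)


def read_library_csv(path: PathLike) -> LibraryTable:
    """Library dialect: name, notation, series, helicity_pct (float or
    "ND"), ec50_uM (float or ">50"), kd_nM, ratio_printed, logd, alogp,
    parent_name; header required."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"name", "notation", "series", "helicity_pct", "ec50_uM", "kd_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"library CSV missing columns {sorted(missing)}")

    def _float(txt: str) -> float:
        return math.nan if txt in ("", "ND") else float(txt)

    records = []
    for _, row in df.iterrows():
        ec50_txt = row["ec50_uM"]
        censored = ec50_txt.startswith(">")
        records.append(
            dict(
                name=row["name"],
                series=row["series"],
                notation=row["notation"],
                helicity_pct=_float(row["helicity_pct"]),
                ec50_uM=_float(ec50_txt.lstrip(">")),
                ec50_censored=censored,
                kd_nM=_float(row["kd_nM"]),
                ratio_printed=row.get("ratio_printed", "") or np.nan,
                logd=_float(row.get("logd", "")),
                alogp=_float(row.get("alogp", "")),
                parent_name=row.get("parent_name", ""),
            )
        )
    return LibraryTable.from_records(records)


def write_library_csv(table: LibraryTable, path: PathLike) -> None:
    out = table.df.copy()
    ec50 = []
    for _, row in out.iterrows():
        if pd.isna(row["ec50_uM"]):
            ec50.append("")
        elif bool(row["ec50_censored"]):
            v = row["ec50_uM"]
            ec50.append(f">{int(v)}" if float(v).is_integer() else f">{v:g}")
        else:
            ec50.append(f"{row['ec50_uM']:g}")
    out["ec50_uM"] = ec50
    out["helicity_pct"] = [
        "ND" if pd.isna(v) else f"{v:g}" for v in out["helicity_pct"]
    ]
    out.drop(columns=["ec50_censored"]).to_csv(path, index=False)
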