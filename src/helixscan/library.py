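"""Library-level SAR analytics over a table of stapled-peptide records.

A :class:`LibraryTable` joins, per peptide: sequence notation, percent
helicity (possibly "ND"), cellular EC50 in uM (possibly censored ">50"),
MDM2 Kd in nM, the printed cell/target ratio where available, series
labels, parent linkage and lipophilicity descriptors (HPLC-LogD and
ALogP, consumed as inputs).  On top of it sit the scan summaries
(fold-change of Kd versus parent), the aggregation conventions
(geometric means for potencies, arithmetic for helicity), proteolytic
stability normalization, a ratio lint that recomputes every printed
ratio without forcing agreement, and the lipophilicity ~ log10(ratio)
regression used to argue that lipophilicity drives cellular uptake.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import stats

from .dose_response import CensoredValue, cell_target_ratio

__all__ = [
    "LibraryTable",
    "ScanSummary",
    "RegressionResult",
    "StabilityTimecourse",
    "fold_change_vs_parent",
    "series_helicity_summary",
    "aggregate_potency",
    "normalize_stability",
    "recompute_ratio",
    "lint_ratios",
    "correlate_lipophilicity",
]

_COLUMNS = [
    "name", "series", "notation", "helicity_pct", "ec50_uM", "ec50_censored",
    "kd_nM", "ratio_printed", "logd", "alogp", "parent_name",
]


@dataclass(frozen=True)
class LibraryTable:
    """A peptide library as a validated pandas DataFrame.

    Sentinels survive verbatim at I/O: helicity "ND" becomes NaN in
    ``helicity_pct``, a censored EC50 ">50" is stored as the bound 50.0
    with ``ec50_censored=True``.  Every non-parent row must reference an
    existing parent row.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"library table missing columns {missing}")
        if self.df["name"].duplicated().any():
            dup = self.df.loc[self.df["name"].duplicated(), "name"].tolist()
            raise ValueError(f"duplicate peptide names {dup}")
        names = set(self.df["name"])
        parents = self.df["parent_name"].dropna()
        parents = parents[parents != ""]
        unknown = sorted(set(parents) - names)
        if unknown:
            raise ValueError(f"parent_name references unknown rows {unknown}")
        kd = self.df["kd_nM"].dropna()
        if (kd <= 0).any():
            raise ValueError("kd_nM must be > 0 where present")
        object.__setattr__(self, "df", self.df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)

    def row(self, name: str) -> pd.Series:
        hit = self.df[self.df["name"] == name]
        if hit.empty:
            raise KeyError(name)
        return hit.iloc[0]

    def ec50(self, name: str) -> Union[float, CensoredValue]:
        r = self.row(name)
        if bool(r["ec50_censored"]):
            return CensoredValue(float(r["ec50_uM"]))
        return float(r["ec50_uM"])

    @staticmethod
    def from_records(records: Iterable[dict]) -> "LibraryTable":
        df = pd.DataFrame.from_records(list(records))
        for col in _COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df["ec50_censored"] = df["ec50_censored"].fillna(False).astype(bool)
        return LibraryTable(df[_COLUMNS])


@dataclass(frozen=True)
class ScanSummary:
    """Per-position Kd fold-changes versus parent plus series helicity stats."""

    fold_changes: pd.Series  # indexed by peptide name; NaN where Kd missing
    helicity_mean: float
    helicity_min: float
    helicity_max: float
    n_helicity: int
    n_censored_ec50: int


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least-squares summary for the lipophilicity correlation."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    x_name: str
    y_name: str
    n_censored_excluded: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared out of [0, 1]")
        if self.n_points < 3:
            raise ValueError("need >= 3 points")


@dataclass(frozen=True)
class StabilityTimecourse:
    """Percent compound remaining, normalized to the 0 h measurement."""

    time_h: NDArray[np.float64]
    remaining_pct: NDArray[np.float64]

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_h", np.asarray(self.time_h, dtype=float))
        object.__setattr__(
            self, "remaining_pct", np.asarray(self.remaining_pct, dtype=float)
        )
        if self.time_h.shape != self.remaining_pct.shape:
            raise ValueError("time and remaining series must have equal length")
        i0 = int(np.argmin(np.abs(self.time_h)))
        if self.time_h[i0] != 0 or not math.isclose(self.remaining_pct[i0], 100.0):
            raise ValueError("timecourse must contain t=0 normalized to 100%")


def fold_change_vs_parent(
    table: LibraryTable, name: str, parent: Optional[str] = None
) -> float:
    """Kd fold-change of a variant over its parent (>1 = weaker binding).

    Missing Kd on either side yields NaN, never an exception.
    """
    row = table.row(name)
    parent_name = parent or row["parent_name"]
    if not parent_name or (isinstance(parent_name, float) and math.isnan(parent_name)):
        raise ValueError(f"{name} has no parent reference")
    kd = row["kd_nM"]
    kd_parent = table.row(parent_name)["kd_nM"]
    if pd.isna(kd) or pd.isna(kd_parent):
        return math.nan
    return float(kd) / float(kd_parent)


def series_helicity_summary(
    table: LibraryTable, series: str
) -> tuple[float, float, float, int]:
    """(arithmetic mean, min, max, n) helicity over a series, excluding "ND".

    CD-derived values are averaged arithmetically, unlike potencies.
    """
    sub = table.df[table.df["series"] == series]["helicity_pct"].dropna()
    if sub.empty:
        raise ValueError(f"series {series!r} has no measurable helicity entries")
    return float(sub.mean()), float(sub.min()), float(sub.max()), int(sub.size)


def aggregate_potency(
    values: Sequence[float], kind: Literal["binding", "cellular", "helicity"]
) -> float:
    """Replicate aggregation convention: geometric mean for binding and
    cellular potencies, arithmetic mean for helicity."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values to aggregate")
    if kind in ("binding", "cellular"):
        if np.any(arr <= 0):
            raise ValueError("geometric mean requires positive values")
        return float(stats.gmean(arr))
    if kind == "helicity":
        return float(arr.mean())
    raise ValueError(f"unknown kind {kind!r}")


def normalize_stability(time_h: Sequence[float], raw: Sequence[float]) -> StabilityTimecourse:
    """Normalize a homogenate-stability timecourse to its 0 h amount."""
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(raw, dtype=float)
    if t.shape != y.shape:
        raise ValueError("time and raw series must have equal length")
    at0 = np.nonzero(t == 0)[0]
    if at0.size == 0:
        raise ValueError("timecourse lacks a t=0 measurement")
    y0 = y[at0[0]]
    if not y0 > 0:
        raise ValueError("t=0 amount must be > 0")
    return StabilityTimecourse(time_h=t, remaining_pct=100.0 * y / y0)


def recompute_ratio(table: LibraryTable, name: str) -> Union[int, CensoredValue]:
    """Cell/target ratio recomputed from the row's EC50 and Kd."""
    row = table.row(name)
    return cell_target_ratio(table.ec50(name), float(row["kd_nM"]))


def lint_ratios(table: LibraryTable) -> pd.DataFrame:
    """Recompute every row's ratio and report, without forcing agreement.

    Returns a DataFrame (name, ratio_printed, ratio_recomputed, match);
    rows whose printed ratio disagrees with the recomputation — typically
    because the authors rounded from unrounded instrument values — are
    surfaced for audit, never silently corrected.
    """
    records = []
    for _, row in table.df.iterrows():
        printed = row["ratio_printed"]
        if pd.isna(row["kd_nM"]) or pd.isna(row["ec50_uM"]):
            continue
        recomputed = recompute_ratio(table, row["name"])
        recomputed_str = str(recomputed)
        printed_str = None if pd.isna(printed) else str(printed)
        records.append(
            dict(
                name=row["name"],
                ratio_printed=printed_str,
                ratio_recomputed=recomputed_str,
                match=(printed_str is not None and printed_str == recomputed_str),
            )
        )
    return pd.DataFrame.from_records(records)


def correlate_lipophilicity(
    table: LibraryTable,
    x: Literal["logd", "alogp"] = "logd",
    y_transform: Literal["log10_ratio", "ratio"] = "log10_ratio",
) -> RegressionResult:
    """OLS of the (transformed) cell/target ratio on a lipophilicity axis.

    Ratios are recomputed from EC50/Kd; censored rows are excluded and
    counted.  The default log10 transform keeps 777-fold outliers from
    dominating the fit (ratios span ~2-800); raw-ratio mode is retained
    for comparison.  R^2 is the squared Pearson correlation; a constant
    response is reported as R^2 = 0 with ``degenerate=True``.
    """
    if x not in ("logd", "alogp"):
        raise ValueError(f"unknown lipophilicity axis {x!r}")
    xs, ys = [], []
    n_censored = 0
    for _, row in table.df.iterrows():
        xv = row[x]
        if pd.isna(xv) or pd.isna(row["kd_nM"]) or pd.isna(row["ec50_uM"]):
            continue
        if bool(row["ec50_censored"]):
            n_censored += 1
            continue
        ratio = 1000.0 * float(row["ec50_uM"]) / float(row["kd_nM"])
        ys.append(math.log10(ratio) if y_transform == "log10_ratio" else ratio)
        xs.append(float(xv))
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} usable rows (need >= 3)")
    x_arr, y_arr = np.asarray(xs), np.asarray(ys)
    y_name = "log10(cell/target ratio)" if y_transform == "log10_ratio" else "cell/target ratio"
    if np.ptp(y_arr) == 0 or np.ptp(x_arr) == 0:
        return RegressionResult(
            slope=0.0, intercept=float(np.mean(y_arr)), r_squared=0.0,
            n_points=len(xs), x_name=x, y_name=y_name,
            n_censored_excluded=n_censored, degenerate=True,
        )
    fit = stats.linregress(x_arr, y_arr)
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2), n_points=len(xs),
        x_name=x, y_name=y_name, n_censored_excluded=n_censored,
    )


def scan_summary(
    table: LibraryTable, series: str, parent: str
) -> ScanSummary:
    """Summarize a substitution scan: Kd fold-changes vs the shared parent
    plus the series' helicity statistics and censored-entry count."""
    sub = table.df[table.df["series"] == series]
    if sub.empty:
        raise ValueError(f"empty series {series!r}")
    fc = {}
    for _, row in sub.iterrows():
        if row["name"] == parent:
            continue
        fc[row["name"]] = fold_change_vs_parent(table, row["name"], parent=parent)
    mean, lo, hi, n = series_helicity_summary(table, series)
    return ScanSummary(
        fold_changes=pd.Series(fc, dtype=float),
        helicity_mean=mean, helicity_min=lo, helicity_max=hi,
        n_helicity=n,
        n_censored_ec50=int(sub["ec50_censored"].fillna(False).astype(bool).sum()),
    )
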