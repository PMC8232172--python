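"""Clinical response curves, day-12 summaries and the parameter screen.

Each treatment cycle records a short longitudinal series (3-6 monitoring
visits) for estrogen level (pg/mL), endometrium thickness (mm) and lead
follicle size (mm).  A straight line fitted by ordinary least squares gives
a single per-cycle response rate (the slope, units/day) and a day-12 value
-- the observed measurement when day 12 was monitored, otherwise the fitted
prediction.  Day-12 values, slopes and the static embryology scores
(spindle presence, zona pellucida birefringence, pronuclear pattern, donor
age) form one row per cycle; all pairwise Pearson correlations of those
columns make up the clinical-parameter screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClinicalSeries",
    "CurveFit",
    "fit_response_curve",
    "clinical_parameter_table",
    "pairwise_clinical_correlation",
    "read_clinical_long",
    "series_from_long",
]

LONGITUDINAL_PARAMETERS = ("estrogen", "endometrium", "lead_follicle")
STATIC_FIELDS = ("spindle_presence", "zona_birefringence", "pronuclear_pattern", "age")
DAY12 = 12


@dataclass
class ClinicalSeries:
    """One cycle's longitudinal observations for one clinical parameter."""

    cycle_id: str
    parameter: str
    days: list[int]
    values: list[float]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.values):
            raise ValueError("days and values length mismatch")
        if len(self.days) < 2:
            raise ValueError(
                f"cycle {self.cycle_id!r} parameter {self.parameter!r}: "
                ">=2 observations required for fitting"
            )
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError(f"days must be strictly increasing, got {self.days}")


@dataclass
class CurveFit:
    """OLS line summary: slope (units/day), intercept, day-12 value."""

    slope: float
    intercept: float
    day12_value: float
    day12_source: str  # "observed" | "predicted"
    residual_sd: float

    def predict(self, day: float) -> float:
        return self.intercept + self.slope * day


def fit_response_curve(s: ClinicalSeries) -> CurveFit:
    """Fit value = intercept + slope * day by ordinary least squares.

    The day-12 value is the observed one when day 12 was monitored,
    otherwise the line's prediction at day 12.  ``residual_sd`` uses the
    n-2 denominator (0 for an exact two-point fit).
    """
    days = np.asarray(s.days, dtype=float)
    values = np.asarray(s.values, dtype=float)
    if len(np.unique(days)) < 2:
        raise ValueError("all observation days identical; slope undefined")
    slope, intercept = np.polyfit(days, values, deg=1)
    resid = values - (intercept + slope * days)
    n = len(days)
    residual_sd = float(np.sqrt((resid**2).sum() / (n - 2))) if n > 2 else 0.0
    if DAY12 in s.days:
        day12 = float(values[s.days.index(DAY12)])
        source = "observed"
    else:
        day12 = float(intercept + slope * DAY12)
        source = "predicted"
    return CurveFit(
        slope=float(slope),
        intercept=float(intercept),
        day12_value=day12,
        day12_source=source,
        residual_sd=residual_sd,
    )


def read_clinical_long(path: str | Path) -> pd.DataFrame:
    """Read the long-format clinical TSV (cycle_id, parameter, day, value)."""
    df = pd.read_csv(path, sep="\t", dtype={"cycle_id": str, "parameter": str})
    missing = {"cycle_id", "parameter", "day", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    return df


def series_from_long(long: pd.DataFrame) -> list[ClinicalSeries]:
    out = []
    for (cycle, param), grp in long.groupby(["cycle_id", "parameter"], sort=False):
        grp = grp.sort_values("day")
        out.append(
            ClinicalSeries(
                cycle_id=str(cycle),
                parameter=str(param),
                days=[int(d) for d in grp["day"]],
                values=[float(v) for v in grp["value"]],
            )
        )
    return out


def clinical_parameter_table(
    series: list[ClinicalSeries],
    static: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per cycle: day-12 value and slope per longitudinal parameter.

    Static embryology/donor columns are appended when supplied (indexed by
    ``cycle_id``).  A cycle missing any longitudinal parameter is an error.
    """
    fits: dict[str, dict[str, CurveFit]] = {}
    for s in series:
        fits.setdefault(s.cycle_id, {})[s.parameter] = fit_response_curve(s)
    rows = []
    for cycle in fits:
        row: dict = {"cycle_id": cycle}
        for param in LONGITUDINAL_PARAMETERS:
            if param not in fits[cycle]:
                raise ValueError(f"cycle {cycle!r} is missing the {param!r} series")
            fit = fits[cycle][param]
            row[f"{param}_day12"] = fit.day12_value
            row[f"{param}_slope"] = fit.slope
        rows.append(row)
    table = pd.DataFrame(rows).set_index("cycle_id")
    if static is not None:
        st = static.set_index("cycle_id") if "cycle_id" in static.columns else static
        missing = set(table.index) - set(st.index)
        if missing:
            raise ValueError(f"static table missing cycle(s): {sorted(missing)}")
        table = table.join(st.loc[table.index])
    return table


def pairwise_clinical_correlation(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """All-pairs Pearson correlation of the clinical-parameter columns.

    Zero-variance columns are excluded before testing.  Returns the r
    matrix, the p matrix and the count of unordered pairs significant at
    ``p < alpha`` (out of C(k, 2) pairs).
    """
    num = table.select_dtypes(include=[np.number])
    if len(num) < 4:
        raise ValueError(f"need >=4 cycles, got {len(num)}")
    keep = [c for c in num.columns if num[c].nunique() > 1]
    num = num[keep]
    k = num.shape[1]
    r_mat = pd.DataFrame(np.eye(k), index=keep, columns=keep)
    p_mat = pd.DataFrame(np.zeros((k, k)), index=keep, columns=keep)
    n_sig = 0
    for i in range(k):
        for j in range(i + 1, k):
            r, p = stats.pearsonr(num.iloc[:, i], num.iloc[:, j])
            r_mat.iloc[i, j] = r_mat.iloc[j, i] = r
            p_mat.iloc[i, j] = p_mat.iloc[j, i] = p
            if p < alpha:
                n_sig += 1
    return r_mat, p_mat, n_sig
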