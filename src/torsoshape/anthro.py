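"""Traditional body-measure table: ingestion, normalisation, correlations.

The measure table carries one row per participant: id, sex code (-1 female,
+1 male), stature (cm), weight (kg) and 34 torso measures (girths, widths,
depths, lengths; cm).  Torso measures are first normalised by body height
(making them unitless proportions comparable across statures) and then
converted column-wise into z-scores.  The pipeline order is enforced by a
stage flag: raw -> height_normalised -> z_scored.

Association analyses follow the conventions used throughout this package:
Pearson product-moment correlations with two-sided p-values (t distribution,
n - 2 df), R^2 = r^2 as effect size, significance at alpha = 0.001 (large
samples), and Welch two-sample t-tests for male/female differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_DEFAULT = 0.001
STAGES = ("raw", "height_normalised", "z_scored")
ID_COLUMNS = ("participant", "sex", "height_cm", "weight_kg")


@dataclass(frozen=True)
class MeasureTable:
    """Body-measure table plus its processing stage."""

    data: pd.DataFrame
    measure_columns: tuple[str, ...]
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        missing = [c for c in self.measure_columns if c not in self.data.columns]
        if missing:
            raise ValueError(f"measure columns missing from table: {missing}")
        if self.stage == "raw":
            vals = self.data[list(self.measure_columns)].to_numpy(dtype=float)
            if not np.all(vals > 0):
                raise ValueError("raw measures must all be positive")

    @property
    def measures(self) -> pd.DataFrame:
        return self.data[list(self.measure_columns)]


def measure_table_from_frame(df: pd.DataFrame,
                             measure_columns=None) -> MeasureTable:
    """Wrap a flat cohort frame; measure columns default to everything
    except the id/sex/height/weight bookkeeping columns."""
    if measure_columns is None:
        skip = set(ID_COLUMNS)
        measure_columns = tuple(c for c in df.columns if c not in skip
                                and np.issubdtype(df[c].dtype, np.number))
    return MeasureTable(data=df.copy(), measure_columns=tuple(measure_columns),
                        stage="raw")


def normalise_by_height(table: MeasureTable,
                        height_column: str = "height_cm") -> MeasureTable:
    """Divide every torso measure by the participant's body height."""
    if table.stage != "raw":
        raise ValueError("height normalisation applies to the raw stage only")
    heights = table.data[height_column].to_numpy(dtype=float)
    if np.any(heights <= 0):
        raise ValueError("non-positive body height")
    df = table.data.copy()
    for c in table.measure_columns:
        df[c] = df[c].to_numpy(dtype=float) / heights
    return replace(table, data=df, stage="height_normalised")


def to_zscores(table: MeasureTable) -> MeasureTable:
    """Column-wise (x - mean) / SD with the sample (n - 1) SD convention."""
    if table.stage != "height_normalised":
        raise ValueError("z-scoring applies after height normalisation")
    if len(table.data) < 3:
        raise ValueError("need at least 3 participants for z-scores")
    df = table.data.copy()
    for c in table.measure_columns:
        x = df[c].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd <= 0:
            raise ValueError(f"zero-variance column {c!r}")
        df[c] = (x - x.mean()) / sd
    return replace(table, data=df, stage="z_scored")


def zscore_columns(df: pd.DataFrame, by_sex: pd.Series | None = None
                   ) -> pd.DataFrame:
    """Plain column z-scoring of a numeric frame; with ``by_sex`` the
    centring/scaling is done within each sex stratum separately (used to
    re-centre shape-PC scores per sex)."""
    out = df.copy().astype(float)
    if by_sex is None:
        groups = [np.ones(len(df), dtype=bool)]
    else:
        codes = np.asarray(by_sex)
        groups = [codes == v for v in np.unique(codes)]
    for g in groups:
        sub = out.loc[g]
        sd = sub.std(ddof=1)
        if (sd <= 0).any():
            raise ValueError("zero-variance column within a stratum")
        out.loc[g] = (sub - sub.mean()) / sd
    return out


def correlation_analysis(A: pd.DataFrame, B: pd.DataFrame,
                         alpha: float = ALPHA_DEFAULT) -> pd.DataFrame:
    """Pairwise Pearson correlations between the columns of A and B.

    Returns a long-format frame (var_a, var_b, r, R2, p, significant) with
    two-sided p-values from the t distribution with n - 2 df.
    """
    if len(A) != len(B):
        raise ValueError("A and B must have equal row counts")
    n = len(A)
    if n < 4:
        raise ValueError("need at least 4 rows for correlation analysis")
    Xa = A.to_numpy(dtype=float)
    Xb = B.to_numpy(dtype=float)
    for X, lab in ((Xa, "A"), (Xb, "B")):
        if np.any(X.std(axis=0) <= 0):
            raise ValueError(f"zero-variance column in {lab}")
    Za = (Xa - Xa.mean(axis=0)) / Xa.std(axis=0)
    Zb = (Xb - Xb.mean(axis=0)) / Xb.std(axis=0)
    r = Za.T @ Zb / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    rows = []
    for i, ca in enumerate(A.columns):
        for j, cb in enumerate(B.columns):
            rows.append({"var_a": ca, "var_b": cb, "r": r[i, j],
                         "R2": r[i, j] ** 2, "p": p[i, j],
                         "significant": bool(p[i, j] < alpha)})
    return pd.DataFrame(rows)


def group_difference_tests(df: pd.DataFrame, sex: pd.Series | np.ndarray,
                           alpha: float = ALPHA_DEFAULT) -> pd.DataFrame:
    """Welch two-sample t-test per column between the sexes."""
    codes = np.asarray(sex)
    male = df.loc[codes == 1]
    female = df.loc[codes == -1]
    if len(male) < 2 or len(female) < 2:
        raise ValueError("both sexes need at least 2 participants")
    rows = []
    for c in df.columns:
        a = male[c].to_numpy(dtype=float)
        b = female[c].to_numpy(dtype=float)
        if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
            # degenerate Welch case: no within-group variability
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"variable": c, "t": float(t), "p": float(p),
                     "significant": bool(p < alpha)})
    return pd.DataFrame(rows)
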