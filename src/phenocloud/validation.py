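"""Field-truth geometry formulas and agreement statistics.

Ground-truth crown geometry is derived from two tape-measured crown
diameters and the measured height, under the conventional geometric
idealization for olive crowns: the projected crown is a circle whose
diameter is the mean of the two measured diameters,

    area = pi * ((D1 + D2) / 4)**2,

and the crown is a cone,

    volume = area * height / 3.

Agreement between estimated and observed traits is summarized by the R^2
of an ordinary least-squares fit (estimated ~ observed), the RMSE of the
residuals about the 1:1 identity line (switchable to residuals about the
fitted line), the nRMSE (RMSE as a percentage of the observed mean), and
the bias, (mean_est - mean_obs) / mean_obs * 100, whose sign flags over-
or underestimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionStats",
    "SummaryStats",
    "FieldMeasurement",
    "field_crown_area",
    "field_crown_volume",
    "bias_percent",
    "regression_stats",
    "summarize",
    "match_trees",
    "read_field_csv",
]


@dataclass
class RegressionStats:
    """OLS agreement statistics between observed and estimated values.

    ``rmse`` follows the ``rmse_about`` switch of :func:`regression_stats`
    (identity-line residuals by default); ``rmse_fit`` is always the RMSE
    about the fitted line.  ``nrmse`` is ``rmse`` as a percentage of the
    observed mean.
    """

    r_squared: float
    rmse: float
    nrmse: float
    n: int
    slope: float
    intercept: float
    rmse_fit: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


@dataclass
class SummaryStats:
    """Min/max/range/mean/sd summary of one trait over a tree population."""

    minimum: float
    maximum: float
    range: float
    average: float
    standard_deviation: float
    n: int


@dataclass
class FieldMeasurement:
    """One manually measured tree: height plus two crown diameters.

    ``d1`` is the widest crown length through the centre; ``d2`` the
    width perpendicular to it.  The area formula is symmetric in the two,
    so recording them swapped is harmless.
    """

    tree_id: int
    measured_height: Optional[float] = None
    d1: Optional[float] = None
    d2: Optional[float] = None


def field_crown_area(d1: float, d2: float) -> float:
    """Projected crown area (m^2) from two diameters: pi*((d1+d2)/4)^2."""
    if d1 <= 0 or d2 <= 0:
        raise ValueError(f"crown diameters must be positive, got {d1}, {d2}")
    return math.pi * ((d1 + d2) / 4.0) ** 2


def field_crown_volume(area: float, height: float) -> float:
    """Cone crown volume (m^3): area * height / 3."""
    if area < 0 or height < 0:
        raise ValueError(f"area and height must be >= 0, got {area}, {height}")
    return area * height / 3.0


def bias_percent(estimated_mean: float, observed_mean: float) -> float:
    """(ym - xm) / xm * 100; negative means underestimation."""
    if observed_mean == 0:
        raise ValueError("observed mean is zero; bias undefined")
    return (estimated_mean - observed_mean) / observed_mean * 100.0


def regression_stats(observed: Sequence[float], estimated: Sequence[float],
                     rmse_about: str = "identity") -> RegressionStats:
    """OLS of estimated on observed plus RMSE/nRMSE.

    ``rmse_about="identity"`` (default) measures residuals from the 1:1
    line, matching how scatter plots against the 1:1 line are read;
    ``"fit"`` measures them about the regression line instead.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    est = np.asarray(estimated, dtype=float).ravel()
    if obs.shape != est.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {est.shape}")
    if obs.size < 3:
        raise ValueError(f"need >= 3 pairs, got {obs.size}")
    if rmse_about not in ("identity", "fit"):
        raise ValueError(f"rmse_about must be 'identity' or 'fit', got {rmse_about!r}")
    fit = stats.linregress(obs, est)
    rmse_identity = float(np.sqrt(np.mean((est - obs) ** 2)))
    pred = fit.intercept + fit.slope * obs
    rmse_fit = float(np.sqrt(np.mean((est - pred) ** 2)))
    rmse = rmse_identity if rmse_about == "identity" else rmse_fit
    mean_obs = float(np.mean(obs))
    nrmse = rmse / mean_obs * 100.0 if mean_obs != 0 else float("nan")
    return RegressionStats(
        r_squared=min(float(fit.rvalue) ** 2, 1.0),
        rmse=rmse,
        nrmse=nrmse,
        n=int(obs.size),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        rmse_fit=rmse_fit,
    )


def summarize(values: Sequence[float]) -> SummaryStats:
    """Min, max, range, mean and sample (n-1) standard deviation.

    For a single value the standard deviation is reported as 0.0 by
    convention rather than NaN.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sequence")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return SummaryStats(
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        range=float(arr.max() - arr.min()),
        average=float(arr.mean()),
        standard_deviation=sd,
        n=int(arr.size),
    )


def match_trees(records, field, max_distance: float = 2.0, by: str = "auto"):
    """Pair detected trees with field-measured trees.

    ``by="auto"``: pair by tree id when the two tables share ids, else by
    location.  ``by="id"`` / ``by="location"`` force the mode.  Location
    pairing is greedy one-to-one nearest neighbour within
    ``max_distance`` metres (closest pairs first).  Detected component
    labels are assigned in raster-scan order and need not correspond to
    planting order, so location pairing is the right mode whenever the
    detected ids did not come from a seed table.

    Parameters
    ----------
    records
        Sequence of :class:`phenocloud.traits.TreeRecord` or a DataFrame
        with at least ``tree_id, x, y`` columns.
    field
        Sequence of :class:`FieldMeasurement` or a DataFrame with a
        ``tree_id`` column and optionally ``x, y``.

    Returns
    -------
    (pairs, unmatched_records, unmatched_field)
        ``pairs`` is a DataFrame with the record columns prefixed ``est_``
        and field columns prefixed ``obs_``.
    """
    rec_df = _as_dataframe(records)
    fld_df = _as_dataframe(field)
    if rec_df.empty or fld_df.empty:
        raise ValueError("both record and field tables must be non-empty")

    if by not in ("auto", "id", "location"):
        raise ValueError(f"by must be auto, id or location, got {by!r}")
    shared = set(rec_df["tree_id"]) & set(fld_df["tree_id"])
    if by == "location":
        shared = set()
    elif by == "id" and not shared:
        raise ValueError("by='id' but the tables share no tree ids")
    pairs = []
    if shared:
        for tid in sorted(shared):
            pairs.append((tid, tid))
        unmatched_rec = sorted(set(rec_df["tree_id"]) - shared)
        unmatched_fld = sorted(set(fld_df["tree_id"]) - shared)
    else:
        if not {"x", "y"} <= set(fld_df.columns):
            raise ValueError("no shared ids and field table has no x,y columns")
        from scipy.spatial.distance import cdist

        d = cdist(rec_df[["x", "y"]].to_numpy(), fld_df[["x", "y"]].to_numpy())
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        used_r, used_f = set(), set()
        for i, j in order:
            if d[i, j] > max_distance:
                break
            if i in used_r or j in used_f:
                continue
            used_r.add(i)
            used_f.add(j)
            pairs.append((rec_df["tree_id"].iloc[i], fld_df["tree_id"].iloc[j]))
        unmatched_rec = sorted(rec_df["tree_id"].iloc[i] for i in range(len(rec_df)) if i not in used_r)
        unmatched_fld = sorted(fld_df["tree_id"].iloc[j] for j in range(len(fld_df)) if j not in used_f)

    rows = []
    rec_idx = rec_df.set_index("tree_id")
    fld_idx = fld_df.set_index("tree_id")
    for rid, fid in pairs:
        row = {"est_tree_id": rid, "obs_tree_id": fid}
        row.update({f"est_{c}": rec_idx.loc[rid, c] for c in rec_idx.columns})
        row.update({f"obs_{c}": fld_idx.loc[fid, c] for c in fld_idx.columns})
        rows.append(row)
    return pd.DataFrame(rows), unmatched_rec, unmatched_fld


def _as_dataframe(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj.copy()
    rows = []
    for item in obj:
        if hasattr(item, "__dataclass_fields__"):
            from dataclasses import asdict

            rows.append(asdict(item))
        else:
            rows.append(dict(item))
    df = pd.DataFrame(rows)
    if "centroid" in df.columns:
        df["x"] = [c[0] for c in df["centroid"]]
        df["y"] = [c[1] for c in df["centroid"]]
        df = df.drop(columns=["centroid"])
    return df


def read_field_csv(path) -> pd.DataFrame:
    """Field measurement CSV: tree_id, height_m, d1_m, d2_m (x,y optional)."""
    df = pd.read_csv(path)
    required = {"tree_id", "height_m"}
    if not required <= set(df.columns):
        raise ValueError(f"field CSV must have columns {sorted(required)}")
    return df
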