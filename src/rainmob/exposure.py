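"""Rainfall-anomaly exposure: 12-month sums and their empirical percentile.

For each unique (site, interview date) pair, rainfall over the 365 days
preceding the interview is summed, and ranked against the same 365-day
window shifted back by 1..29 whole calendar years. The rank, mapped through
the plotting position (rank - 1) / 29 with midranks for ties, is the
exposure percentile: 0 = driest year on record at that site, 1 = wettest,
0.5 = the pooled 30-year median.

Windows are half-open and end the day before the interview, so the
interview day itself is excluded; year-shifted anchors use calendar
arithmetic (Feb 29 clamps to Feb 28). Missing rainfall days are never
imputed — a window that is not fully covered raises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grid import RainGrid

N_HISTORY = 29
_EARTH_R_KM = 6371.0


@dataclass(frozen=True)
class CellWeights:
    """Grid cells contributing to a site's series, with weights summing to 1."""

    ilat: np.ndarray
    ilon: np.ndarray
    weights: np.ndarray


def _haversine_km(lon1, lat1, lon2, lat2):
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    a = np.sin((lat2 - lat1) / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    return 2 * _EARTH_R_KM * np.arcsin(np.sqrt(a))


def link_site_to_cell(site, grid: RainGrid, method: str = "nearest") -> CellWeights:
    """Link a site to grid cell(s).

    ``nearest``: the single cell whose center minimizes great-circle
    distance. ``bilinear``: the four surrounding cells with planar
    fractional-position weights.
    """
    lon, lat = float(site["lon"]), float(site["lat"])
    if not grid.contains(lon, lat):
        raise ValueError(f"site not covered: ({lon}, {lat}) outside grid bounding box")

    if method == "nearest":
        d = _haversine_km(lon, lat, grid.lon_axis[:, None].T, grid.lat_axis[:, None])
        ilat, ilon = np.unravel_index(int(np.argmin(d)), d.shape)
        return CellWeights(np.array([ilat]), np.array([ilon]), np.array([1.0]))
    if method == "bilinear":
        fx = np.clip((lon - grid.lon_axis[0]) / max(grid.lon_spacing, 1e-300), 0, grid.lon_axis.size - 1)
        fy = np.clip((lat - grid.lat_axis[0]) / max(grid.lat_spacing, 1e-300), 0, grid.lat_axis.size - 1)
        x0 = min(int(np.floor(fx)), grid.lon_axis.size - 2) if grid.lon_axis.size > 1 else 0
        y0 = min(int(np.floor(fy)), grid.lat_axis.size - 2) if grid.lat_axis.size > 1 else 0
        tx, ty = fx - x0, fy - y0
        if grid.lon_axis.size == 1:
            tx = 0.0
        if grid.lat_axis.size == 1:
            ty = 0.0
        ilat = np.array([y0, y0, min(y0 + 1, grid.lat_axis.size - 1), min(y0 + 1, grid.lat_axis.size - 1)])
        ilon = np.array([x0, min(x0 + 1, grid.lon_axis.size - 1), x0, min(x0 + 1, grid.lon_axis.size - 1)])
        w = np.array([(1 - tx) * (1 - ty), tx * (1 - ty), (1 - tx) * ty, tx * ty])
        keep = w > 0
        if not keep.any():
            keep[0] = True
            w[0] = 1.0
        return CellWeights(ilat[keep], ilon[keep], w[keep] / w[keep].sum())
    raise ValueError(f"unknown linkage method: {method!r}")


def window_sum(grid: RainGrid, cells: CellWeights, end_date, n_days: int = 365) -> float:
    """Rainfall (mm) over the half-open window [end_date - n_days, end_date)."""
    i_end = grid.day_index(end_date)
    i_start = i_end - n_days
    if i_start < 0 or i_end > grid.n_days:
        raise ValueError(
            f"insufficient history: window [{i_start}, {i_end}) outside grid of {grid.n_days} days"
        )
    total = 0.0
    for a, o, w in zip(cells.ilat, cells.ilon, cells.weights):
        total += w * float(grid.values[a, o, i_start:i_end].sum())
    return total


def empirical_percentile(current: float, historical, convention: str = "midrank") -> float:
    """Percentile of the current annual sum within the pooled 30-value record.

    ``midrank`` (default): pool the 30 values, rank ascending with ties
    given the mean of their tied ranks, return (rank - 1) / 29 — so a
    record minimum maps to 0, a record maximum to 1, and the pooled median
    to 0.5. ``hazen`` ((rank - 0.5) / 30) and ``weibull`` (rank / 31) are
    alternative plotting positions.
    """
    historical = np.asarray(historical, dtype=float)
    if historical.size != N_HISTORY:
        raise ValueError(f"need exactly {N_HISTORY} historical values, got {historical.size}")
    if not (np.isfinite(historical).all() and np.isfinite(current)):
        raise ValueError("non-finite rainfall sum")
    pool = np.concatenate([[float(current)], historical])
    rank = rankdata(pool, method="average")[0]
    if convention == "midrank":
        return float((rank - 1.0) / (pool.size - 1.0))
    if convention == "hazen":
        return float((rank - 0.5) / pool.size)
    if convention == "weibull":
        return float(rank / (pool.size + 1.0))
    raise ValueError(f"unknown percentile convention: {convention!r}")


def _shift_years(date: pd.Timestamp, k: int) -> pd.Timestamp:
    return date - pd.DateOffset(years=k)  # clamps Feb 29 -> Feb 28


def site_exposure(
    grid: RainGrid,
    cells: CellWeights,
    anchor_date,
    convention: str = "midrank",
) -> tuple[float, np.ndarray, float]:
    """(current 12-month sum, 29 historical sums, percentile) at one anchor date."""
    anchor = pd.Timestamp(anchor_date)
    current = window_sum(grid, cells, anchor)
    historical = np.array(
        [window_sum(grid, cells, _shift_years(anchor, k)) for k in range(1, N_HISTORY + 1)]
    )
    return current, historical, empirical_percentile(current, historical, convention)


def build_exposure_table(
    grid: RainGrid,
    sites: pd.DataFrame,
    respondents: pd.DataFrame,
    method: str = "nearest",
    convention: str = "midrank",
) -> pd.DataFrame:
    """One exposure record per unique (site_id, interview date) pair.

    Respondents join back on that key; duplicate pairs are computed once.
    Raises if any pair lacks the full 30-year lookback, listing offenders.
    """
    pairs = (
        respondents[["site_id", "interview_date"]]
        .drop_duplicates()
        .sort_values(["site_id", "interview_date"])
        .reset_index(drop=True)
    )
    unknown = set(pairs["site_id"]) - set(sites["site_id"])
    if unknown:
        raise ValueError(f"respondents reference unknown sites: {sorted(unknown)[:5]}")

    site_rows = sites.set_index("site_id")
    links = {sid: link_site_to_cell(site_rows.loc[sid], grid, method) for sid in pairs["site_id"].unique()}

    bad = []
    for _, row in pairs.iterrows():
        earliest = _shift_years(pd.Timestamp(row["interview_date"]), N_HISTORY) - pd.Timedelta(days=365)
        if grid.day_index(earliest) < 0 or grid.day_index(row["interview_date"]) > grid.n_days:
            bad.append((row["site_id"], str(pd.Timestamp(row["interview_date"]).date())))
    if bad:
        raise ValueError(f"insufficient 30-year lookback for pairs: {bad[:10]}")

    records = []
    for _, row in pairs.iterrows():
        cur, hist, pct = site_exposure(grid, links[row["site_id"]], row["interview_date"], convention)
        rec = {
            "site_id": row["site_id"],
            "anchor_date": pd.Timestamp(row["interview_date"]),
            "annual_sum_mm": cur,
            "percentile": pct,
        }
        rec.update({f"hist_sum_mm_{k:02d}": hist[k - 1] for k in range(1, N_HISTORY + 1)})
        records.append(rec)
    return pd.DataFrame.from_records(records)


def assemble_analysis_frame(
    sites: pd.DataFrame, respondents: pd.DataFrame, exposure: pd.DataFrame
) -> pd.DataFrame:
    """Join respondents to site attributes and exposure percentiles."""
    df = respondents.merge(
        sites[["site_id", "country"]].assign(urban_site=sites["urban"]), on="site_id", how="left"
    )
    if "urban" not in respondents.columns:
        df["urban"] = df["urban_site"]
    df = df.drop(columns=["urban_site"])
    df = df.merge(
        exposure[["site_id", "anchor_date", "annual_sum_mm", "percentile"]],
        left_on=["site_id", "interview_date"],
        right_on=["site_id", "anchor_date"],
        how="left",
    ).drop(columns=["anchor_date"])
    if df["percentile"].isna().any():
        n = int(df["percentile"].isna().sum())
        raise ValueError(f"{n} respondents have no matching exposure record")
    return df
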