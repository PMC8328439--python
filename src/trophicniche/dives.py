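"""Foraging-area estimation from dive records.

Likely foraging dives are the faster U-shaped dives of each individual:
flat-bottomed profiles (high time-allocation-at-depth, TAD) with an
above-threshold vertical descent speed. Their surface positions, projected
to a local azimuthal equal-area plane, feed a 2-D Gaussian kernel density
whose 50/75/95% mass contours delimit the foraging areas.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from skimage import measure

__all__ = [
    "DIVE_COLUMNS",
    "read_dive_table",
    "compute_tad",
    "descent_speed",
    "select_faster_u",
    "kernel_contours",
    "ForagingContours",
    "LocalEqualArea",
    "contours_to_geojson",
]

EARTH_RADIUS_M = 6_371_000.0
INTERMEDIATE_COLS = [f"depth_p{p}" for p in range(10, 100, 10)]
DIVE_COLUMNS = [
    "individual",
    "start_time",
    "max_depth_m",
    "duration_s",
    "percent_area",
    *INTERMEDIATE_COLS,
    "lon",
    "lat",
]
MIN_DEPTH_M = 1.5  # tag recording threshold


def read_dive_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["start_time"])
    missing = set(DIVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dive table missing columns: {sorted(missing)}")
    if (df["duration_s"] <= 0).any():
        raise ValueError("dive durations must be positive")
    if (df["max_depth_m"] <= MIN_DEPTH_M).any():
        raise ValueError(f"max depth must exceed the {MIN_DEPTH_M} m threshold")
    inter = df[INTERMEDIATE_COLS].to_numpy(float)
    if np.nanmax(inter - df["max_depth_m"].to_numpy(float)[:, None]) > 1e-9:
        raise ValueError("intermediate depths cannot exceed the maximum depth")
    return df


def compute_tad(dive) -> float:
    """Time-allocation-at-depth of one dive record (0..1).

    Returns the tag-provided percent-area when present; otherwise the proxy
    mean(nine intermediate depths) / max depth (flagged with a warning).
    """
    pa = dive.get("percent_area", None)
    if pa is not None and np.isfinite(pa):
        return float(pa)
    inter = np.array([dive[c] for c in INTERMEDIATE_COLS], dtype=float)
    if not np.isfinite(inter).all():
        raise ValueError("neither percent_area nor nine intermediate depths available")
    warnings.warn("percent_area missing; using intermediate-depth proxy TAD",
                  stacklevel=2)
    return float(inter.mean() / dive["max_depth_m"])


def descent_speed(dive) -> float:
    """Vertical descent speed (m/s): first intermediate depth over the
    first 10% of the dive duration."""
    duration = float(dive["duration_s"])
    if duration <= 0:
        raise ValueError("dive duration must be positive")
    d1 = float(dive["depth_p10"])
    if not np.isfinite(d1):
        raise ValueError("first intermediate depth missing")
    return d1 / (0.1 * duration)


def _tad_column(dives: pd.DataFrame) -> np.ndarray:
    pa = dives["percent_area"].to_numpy(float)
    if np.isfinite(pa).all():
        return pa
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.array([compute_tad(row) for _, row in dives.iterrows()])


def select_faster_u(
    dives: pd.DataFrame,
    tad_threshold: float = 0.9,
    speed_quantile: float = 0.5,
) -> pd.DataFrame:
    """Select each individual's faster U-shaped dives.

    U-shaped: TAD >= ``tad_threshold``. Faster: descent speed strictly above
    the individual's ``speed_quantile`` quantile (default: median) computed
    over that individual's U-shaped dives. Selection is strictly
    per-individual. Returns the selected rows with tad/speed columns added.
    """
    out = dives.copy()
    out["tad"] = _tad_column(out)
    out["descent_speed"] = out["depth_p10"].to_numpy(float) / (
        0.1 * out["duration_s"].to_numpy(float)
    )
    selected = []
    for _, block in out.groupby("individual", sort=True):
        u_dives = block[block["tad"] >= tad_threshold]
        if u_dives.empty:
            continue
        cutoff = u_dives["descent_speed"].quantile(speed_quantile)
        selected.append(u_dives[u_dives["descent_speed"] > cutoff])
    if not selected:
        warnings.warn("no dive passed the faster-U selection", stacklevel=2)
        return out.iloc[0:0]
    return pd.concat(selected, ignore_index=True)


class LocalEqualArea:
    """Lambert azimuthal equal-area projection centered on the data centroid
    (preserves the area semantics of density contours)."""

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = np.radians(lon0)
        self.lat0 = np.radians(lat0)

    @classmethod
    def for_points(cls, lon, lat) -> "LocalEqualArea":
        return cls(float(np.mean(lon)), float(np.mean(lat)))

    def forward(self, lon, lat):
        """Degrees -> meters on the projection plane."""
        lam = np.radians(np.asarray(lon, dtype=float)) - self.lon0
        phi = np.radians(np.asarray(lat, dtype=float))
        denom = 1.0 + np.sin(self.lat0) * np.sin(phi) + np.cos(self.lat0) * np.cos(phi) * np.cos(lam)
        k = np.sqrt(2.0 / denom)
        x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(lam)
        y = EARTH_RADIUS_M * k * (
            np.cos(self.lat0) * np.sin(phi) - np.sin(self.lat0) * np.cos(phi) * np.cos(lam)
        )
        return x, y

    def inverse(self, x, y):
        """Meters -> degrees."""
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_M
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_M
        rho = np.hypot(x, y)
        rho_safe = np.where(rho == 0, 1.0, rho)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, -1.0, 1.0))
        phi = np.arcsin(
            np.cos(c) * np.sin(self.lat0) + y * np.sin(c) * np.cos(self.lat0) / rho_safe
        )
        lam = self.lon0 + np.arctan2(
            x * np.sin(c),
            rho_safe * np.cos(self.lat0) * np.cos(c) - y * np.sin(self.lat0) * np.sin(c),
        )
        phi = np.where(rho == 0, self.lat0, phi)
        lam = np.where(rho == 0, self.lon0, lam)
        return np.degrees(lam), np.degrees(phi)


@dataclass
class ForagingContours:
    individual: str
    levels: tuple[float, ...]
    grid_x: np.ndarray  # meters, projection plane
    grid_y: np.ndarray
    density: np.ndarray  # (ny, nx), integrates to ~1 over the plane
    thresholds: dict[float, float]  # level -> density cutoff
    contours_lonlat: dict[float, list[np.ndarray]]  # level -> rings (lon, lat)
    n_dives: int
    projection: LocalEqualArea | None = None

    def density_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.grid_x, self.grid_y)
        return pd.DataFrame(
            {"x_m": xx.ravel(), "y_m": yy.ravel(), "density": self.density.ravel()}
        )


def _mass_threshold(density: np.ndarray, cell_area: float, mass: float) -> float:
    """Density cutoff whose superlevel set holds ``mass`` probability."""
    flat = np.sort(density.ravel())[::-1]
    cum = np.cumsum(flat) * cell_area
    idx = int(np.searchsorted(cum, mass))
    idx = min(idx, flat.size - 1)
    return float(flat[idx])


def kernel_contours(
    dives: pd.DataFrame,
    levels: tuple[float, ...] = (0.5, 0.75, 0.95),
    bw_method: str | float = "scott",
    grid_size: int = 200,
    pad_bw: float = 3.0,
    min_dives: int = 10,
) -> ForagingContours:
    """Kernel-density foraging contours for one individual's selected dives.

    Positions are projected to a local equal-area plane, a 2-D Gaussian KDE
    (normal-reference bandwidth by default) is evaluated on a grid, and for
    each level the density cutoff enclosing that probability mass defines
    the contour. Cutoffs decrease with level, so contour regions are nested
    by construction.
    """
    if dives["individual"].nunique() > 1:
        raise ValueError("kernel_contours expects dives of a single individual")
    individual = str(dives["individual"].iloc[0]) if len(dives) else ""
    n = len(dives)
    if n < min_dives:
        warnings.warn(
            f"only {n} selected dives (< {min_dives}); contours may be unstable",
            stacklevel=2,
        )
    lon = dives["lon"].to_numpy(float)
    lat = dives["lat"].to_numpy(float)
    proj = LocalEqualArea.for_points(lon, lat)
    x, y = proj.forward(lon, lat)
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("all dive positions identical; kernel density undefined")
    kde = gaussian_kde(np.vstack([x, y]), bw_method=bw_method)
    bw = np.sqrt(np.diag(kde.covariance))
    gx = np.linspace(x.min() - pad_bw * bw[0], x.max() + pad_bw * bw[0], grid_size)
    gy = np.linspace(y.min() - pad_bw * bw[1], y.max() + pad_bw * bw[1], grid_size)
    xx, yy = np.meshgrid(gx, gy)
    density = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid_size, grid_size)
    cell_area = (gx[1] - gx[0]) * (gy[1] - gy[0])

    thresholds: dict[float, float] = {}
    contours: dict[float, list[np.ndarray]] = {}
    for level in sorted(levels):
        cutoff = _mass_threshold(density, cell_area, level)
        thresholds[level] = cutoff
        rings = []
        for ring in measure.find_contours(density, cutoff):
            # ring is (row, col) = (y-index, x-index) in fractional cells
            rx = np.interp(ring[:, 1], np.arange(grid_size), gx)
            ry = np.interp(ring[:, 0], np.arange(grid_size), gy)
            rlon, rlat = proj.inverse(rx, ry)
            rings.append(np.column_stack([rlon, rlat]))
        contours[level] = rings
    return ForagingContours(
        individual=individual,
        levels=tuple(sorted(levels)),
        grid_x=gx,
        grid_y=gy,
        density=density,
        thresholds=thresholds,
        contours_lonlat=contours,
        n_dives=n,
        projection=proj,
    )


def contours_to_geojson(result: ForagingContours) -> str:
    """GeoJSON FeatureCollection of the contour rings (WGS84 lon/lat)."""
    features = []
    for level, rings in result.contours_lonlat.items():
        for ring in rings:
            coords = ring.tolist()
            if coords and coords[0] != coords[-1]:
                coords.append(coords[0])
            features.append(
                {
                    "type": "Feature",
                    "properties": {
                        "individual": result.individual,
                        "level": level,
                        "n_dives": result.n_dives,
                    },
                    "geometry": {"type": "Polygon", "coordinates": [coords]},
                }
            )
    return json.dumps({"type": "FeatureCollection", "features": features})
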