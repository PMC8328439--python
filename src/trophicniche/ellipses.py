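"""Standard-ellipse isotopic niches: areas, overlap, probability grids.

A niche ellipse is the set of points whose squared Mahalanobis distance to
the center is at most the chi-square(2 df) quantile at confidence p. Its
area is ``pi * q_p * sqrt(det(cov))``. Overlap between two ellipses is
computed by polygonal approximation (default 360 boundary vertices) and
polygon clipping via shapely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from shapely.geometry import Polygon

__all__ = [
    "Ellipse",
    "EllipseSet",
    "ProbabilityGrid",
    "TefSpec",
    "ellipse_from_points",
    "ellipse_area",
    "ellipse_polygon",
    "ellipse_overlap",
    "ellipse_sets_from_predictions",
    "summarize_overlap",
    "membership_grid",
    "prey_overlay",
]


@dataclass(frozen=True)
class Ellipse:
    center: np.ndarray  # (d13C, d15N) in per mil
    cov: np.ndarray  # 2x2, per mil squared
    p: float = 0.95

    def __post_init__(self):
        cov = np.asarray(self.cov, dtype=float)
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("covariance must be positive definite")
        if not 0 < self.p < 1:
            raise ValueError("confidence level must be in (0, 1)")

    @property
    def radius2(self) -> float:
        """Squared Mahalanobis radius of the boundary."""
        return float(chi2.ppf(self.p, df=2))

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points) - self.center
        quad = np.einsum("ij,jk,ik->i", pts, np.linalg.inv(self.cov), pts)
        return quad <= self.radius2


@dataclass
class EllipseSet:
    """Per-posterior-draw ellipses of one species, paired by draw index."""

    species: str
    ellipses: list[Ellipse]
    draw_idx: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.ellipses)

    def __getitem__(self, j: int) -> Ellipse:
        return self.ellipses[j]


@dataclass
class TefSpec:
    """Prey-to-consumer trophic enrichment (mean shift and SD, per mil)."""

    d13c_shift: float = 2.4
    d13c_sd: float = 1.3
    d15n_shift: float = 2.6
    d15n_sd: float = 1.2

    def __post_init__(self):
        values = (self.d13c_shift, self.d13c_sd, self.d15n_shift, self.d15n_sd)
        if not np.isfinite(values).all():
            raise ValueError("TEF values must be finite")

    @property
    def shift(self) -> np.ndarray:
        return np.array([self.d13c_shift, self.d15n_shift])


def ellipse_from_points(points: np.ndarray, p: float = 0.95) -> Ellipse:
    """Standard ellipse of a point cloud: sample mean center, sample
    covariance shape, boundary at the chi-square(2) quantile of ``p``."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 bivariate points")
    cov = np.cov(pts.T, ddof=1)
    if np.linalg.eigvalsh(cov).min() <= 1e-12 * max(1.0, np.trace(cov)):
        raise ValueError("points are (nearly) collinear; ellipse undefined")
    return Ellipse(center=pts.mean(axis=0), cov=cov, p=p)


def ellipse_area(e: Ellipse) -> float:
    """Area in per-mil squared: pi * q_p * sqrt(det cov)."""
    return float(np.pi * e.radius2 * np.sqrt(np.linalg.det(e.cov)))


def ellipse_polygon(e: Ellipse, vertices: int = 360) -> Polygon:
    """Polygonal approximation of the ellipse boundary."""
    if vertices < 8:
        raise ValueError("too few boundary vertices")
    theta = np.linspace(0, 2 * np.pi, vertices, endpoint=False)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    L = np.linalg.cholesky(e.cov)
    boundary = e.center + np.sqrt(e.radius2) * circle @ L.T
    return Polygon(boundary)


def ellipse_overlap(ea: Ellipse, eb: Ellipse, vertices: int = 360) -> dict:
    """Intersection area and overlap proportions of two ellipses.

    Returns overlap area, proportion of the union, and the nested
    proportions inter/area_a and inter/area_b.
    """
    pa, pb = ellipse_polygon(ea, vertices), ellipse_polygon(eb, vertices)
    inter = pa.intersection(pb).area
    area_a, area_b = ellipse_area(ea), ellipse_area(eb)
    union = area_a + area_b - inter
    return {
        "area_a": area_a,
        "area_b": area_b,
        "overlap_area": inter,
        "prop_union": inter / union if union > 0 else 0.0,
        "prop_a_in_b": inter / area_a if area_a > 0 else 0.0,
        "prop_b_in_a": inter / area_b if area_b > 0 else 0.0,
    }


def ellipse_sets_from_predictions(
    species: str, points: np.ndarray, draw_idx=None, p: float = 0.95
) -> EllipseSet:
    """Fit one standard ellipse per posterior-predictive point set.

    ``points`` is (n_draws, m, 2) from the posterior predictive of new
    individuals; each slice yields one ellipse.
    """
    ellipses = [ellipse_from_points(points[j], p=p) for j in range(points.shape[0])]
    return EllipseSet(species=species, ellipses=ellipses,
                      draw_idx=None if draw_idx is None else np.asarray(draw_idx))


def summarize_overlap(set_a: EllipseSet, set_b: EllipseSet, vertices: int = 360) -> dict:
    """Paired-draw overlap summary between two ellipse sets.

    Per draw j the areas and overlap proportions are computed on the j-th
    ellipse of each set; reported are medians, CI95 bounds, and exceedance
    probabilities P(area_b > area_a), P(a-in-b > b-in-a).
    """
    if len(set_a) != len(set_b):
        raise ValueError("ellipse sets must be paired by draw (equal lengths)")
    keys = ["area_a", "area_b", "overlap_area", "prop_union", "prop_a_in_b", "prop_b_in_a"]
    per_draw = {key: np.empty(len(set_a)) for key in keys}
    for j in range(len(set_a)):
        res = ellipse_overlap(set_a[j], set_b[j], vertices=vertices)
        for key in keys:
            per_draw[key][j] = res[key]
    out = {"species_a": set_a.species, "species_b": set_b.species, "n_draws": len(set_a)}
    for key in keys:
        lo, med, hi = np.percentile(per_draw[key], [2.5, 50, 97.5])
        out[key] = {"median": float(med), "lo": float(lo), "hi": float(hi)}
    out["p_area_b_larger"] = float((per_draw["area_b"] > per_draw["area_a"]).mean())
    out["p_a_more_nested"] = float(
        (per_draw["prop_a_in_b"] > per_draw["prop_b_in_a"]).mean()
    )
    return out


@dataclass
class ProbabilityGrid:
    """Membership probabilities on a d13C x d15N grid."""

    x: np.ndarray  # d13C cell centers
    y: np.ndarray  # d15N cell centers
    membership: dict[str, np.ndarray]  # species -> (ny, nx) in [0, 1]
    joint: np.ndarray | None = None  # (ny, nx) overlap probability

    def lookup(self, species: str, point) -> float:
        """Membership probability at the grid cell nearest to ``point``."""
        ix = int(np.clip(np.searchsorted(self.x, point[0]), 0, len(self.x) - 1))
        iy = int(np.clip(np.searchsorted(self.y, point[1]), 0, len(self.y) - 1))
        return float(self.membership[species][iy, ix])

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        data = {"d13C": xx.ravel(), "d15N": yy.ravel()}
        for sp, grid in self.membership.items():
            data[f"p_{sp}"] = grid.ravel()
        if self.joint is not None:
            data["p_overlap"] = self.joint.ravel()
        return pd.DataFrame(data)


def _grid_axes(sets, n_cells, pad):
    centers = np.concatenate([[e.center for e in s.ellipses] for s in sets])
    radii = np.concatenate(
        [[np.sqrt(e.radius2 * np.linalg.eigvalsh(e.cov).max()) for e in s.ellipses]
         for s in sets]
    )
    lo = centers.min(axis=0) - radii.max() - pad
    hi = centers.max(axis=0) + radii.max() + pad
    return np.linspace(lo[0], hi[0], n_cells), np.linspace(lo[1], hi[1], n_cells)


def membership_grid(
    sets: list[EllipseSet],
    n_cells: int = 200,
    pad: float = 2.0,
    joint: bool = True,
    joint_rule: str = "paired",
) -> ProbabilityGrid:
    """Fraction of each species' ellipses containing each grid cell center.

    The joint overlap probability uses the per-draw AND rule by default
    (cell inside both species' ellipses of the same draw j);
    ``joint_rule='product'`` multiplies the marginal memberships instead.
    """
    if n_cells < 50:
        warnings.warn("membership grid coarser than 50x50 cells", stacklevel=2)
    x, y = _grid_axes(sets, n_cells, pad)
    xx, yy = np.meshgrid(x, y)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = {}
    for s in sets:
        flags = np.zeros((len(s), pts.shape[0]), dtype=bool)
        for j, e in enumerate(s.ellipses):
            flags[j] = e.contains(pts)
        inside[s.species] = flags
    membership = {
        sp: flags.mean(axis=0).reshape(n_cells, n_cells) for sp, flags in inside.items()
    }
    joint_grid = None
    if joint and len(sets) == 2:
        fa, fb = (inside[s.species] for s in sets)
        if joint_rule == "paired":
            if fa.shape[0] != fb.shape[0]:
                raise ValueError("paired joint rule needs equally sized sets")
            joint_grid = (fa & fb).mean(axis=0).reshape(n_cells, n_cells)
        elif joint_rule == "product":
            joint_grid = (fa.mean(axis=0) * fb.mean(axis=0)).reshape(n_cells, n_cells)
        else:
            raise ValueError(f"unknown joint rule {joint_rule!r}")
    return ProbabilityGrid(x=x, y=y, membership=membership, joint=joint_grid)


def prey_overlay(
    prey: pd.DataFrame,
    grid: ProbabilityGrid,
    tef: TefSpec | None = None,
    bands: tuple[float, ...] = (0.25, 0.75),
    jitter_mc: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Evaluate TEF-shifted prey values against species membership grids.

    ``prey`` needs columns prey, d13C, d15N. Each prey mean is shifted by
    the TEF and looked up in every species grid; probabilities are binned
    into bands (default low < 0.25 <= mid < 0.75 <= high). With
    ``jitter_mc > 0`` the TEF uncertainty is propagated by Monte-Carlo
    jitter and the mean membership over draws is reported.
    """
    tef = tef or TefSpec()
    rng = np.random.default_rng(seed)
    labels = ["low", "mid", "high"][: len(bands) + 1]
    rows = []
    for rec in prey.itertuples(index=False):
        base = np.array([rec.d13C, rec.d15N]) + tef.shift
        for sp in grid.membership:
            if jitter_mc:
                jitters = rng.normal(
                    0.0, [tef.d13c_sd, tef.d15n_sd], size=(jitter_mc, 2)
                )
                prob = float(
                    np.mean([grid.lookup(sp, base + j) for j in jitters])
                )
            else:
                prob = grid.lookup(sp, base)
            band = labels[int(np.digitize(prob, bands))]
            rows.append(
                {
                    "prey": rec.prey,
                    "species": sp,
                    "d13C_shifted": base[0],
                    "d15N_shifted": base[1],
                    "membership": prob,
                    "band": band,
                }
            )
    return pd.DataFrame(rows)
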