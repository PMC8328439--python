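"""Synthetic scat, whisker-isotope, and dive datasets with known truth.

Every generator is seeded explicitly (no global random state) and writes
tables matching the reader schemas of the downstream modules, so the whole
pipeline is testable without any deposited data.

Scat synthesis draws a per-scat composition from a Dirichlet around a
cluster archetype (mean x concentration parameterization) and then emits
hard-part records through a single invertible toy allometry per functional
group, so that reconstructed mass proportions round-trip to the drawn
composition (within a bounded flatfish-threshold discretization error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diet import FUNCTIONAL_GROUPS, AllometryModel, AllometryTable

__all__ = [
    "DietSimConfig",
    "SpeciesIsotopeTruth",
    "IsotopeSimConfig",
    "DiveSimConfig",
    "toy_allometry_table",
    "toy_allometry_frame",
    "simulate_scats",
    "simulate_whiskers",
    "simulate_dives",
]

# one generator taxon per functional group; flatfish share one taxon and are
# split by the 200-mm threshold downstream
_GROUP_TAXA = {
    "benthic flatfish": ("Pleuronectes platessa/Platichthys flesus", "otolith length"),
    "benthic non-flatfish": ("Callionymus lyra", "otolith length"),
    "demersal fish": ("Merlangius merlangus", "otolith length"),
    "pelagic fish": ("Clupea harengus", "otolith length"),
    "pelagic squids": ("Loligo spp.", "lower rostral length"),
}

_TOY_MODELS = {
    "Pleuronectes platessa/Platichthys flesus": AllometryModel(
        "otolith length", "linear", 100.0, 0.0, "power", 1.0e-5, 3.0
    ),
    "Callionymus lyra": AllometryModel(
        "otolith length", "linear", 50.0, 0.0, "power", 2.0e-3, 2.0
    ),
    "Merlangius merlangus": AllometryModel(
        "otolith length", "linear", 80.0, 0.0, "power", 5.0e-6, 3.0
    ),
    "Clupea harengus": AllometryModel(
        "otolith length", "linear", 60.0, 0.0, "power", 8.0e-6, 3.0
    ),
    "Loligo spp.": AllometryModel(
        "lower rostral length", "linear", 90.0, 0.0, "power", 2.0e-4, 2.5
    ),
}

# mass of a 200-mm flatfish under the toy model: boundary between the small
# and large chunking strategies
_FLATFISH_TAXON = "Pleuronectes platessa/Platichthys flesus"
_LARGE_FLATFISH_MIN_MASS = _TOY_MODELS[_FLATFISH_TAXON].mass_g(200.0)  # 80 g
_SMALL_FLATFISH_CHUNK_G = 20.0
_LARGE_FLATFISH_CHUNK_G = 200.0


def toy_allometry_table() -> AllometryTable:
    return AllometryTable(dict(_TOY_MODELS))


def toy_allometry_frame() -> pd.DataFrame:
    rows = []
    for taxon, m in _TOY_MODELS.items():
        rows.append(
            {
                "taxon": taxon,
                "measurement_kind": m.measurement_kind,
                "length_form": m.length_form,
                "length_a": m.length_a,
                "length_b": m.length_b,
                "mass_form": m.mass_form,
                "mass_a": m.mass_a,
                "mass_b": m.mass_b,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DietSimConfig:
    """Scat simulation: archetypes are (label, 6-group mean composition,
    Dirichlet concentration); each species draws archetypes with its own
    weights. ``concentration=inf`` collapses to the archetype mean."""

    n_scats_per_species: dict[str, int]
    cluster_archetypes: list[tuple[str, np.ndarray, float]]
    species_cluster_weights: dict[str, np.ndarray]
    parts_per_scat: tuple[int, int] = (1, 3)  # individuals per non-flatfish group
    total_mass_g: float = 10_000.0
    start_date: str = "2002-04-01"
    seed: int = 0

    def __post_init__(self):
        if not self.n_scats_per_species or any(
            n <= 0 for n in self.n_scats_per_species.values()
        ):
            raise ValueError("each species needs a positive scat count")
        for label, mean, conc in self.cluster_archetypes:
            mean = np.asarray(mean, dtype=float)
            if mean.shape != (len(FUNCTIONAL_GROUPS),) or (mean < 0).any():
                raise ValueError(f"archetype {label!r}: mean must be 6 non-negative values")
            if abs(mean.sum() - 1.0) > 1e-9:
                raise ValueError(f"archetype {label!r}: mean must sum to 1")
            if not conc > 0:
                raise ValueError(f"archetype {label!r}: concentration must be > 0")
        for sp, w in self.species_cluster_weights.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (len(self.cluster_archetypes),) or (w < 0).any():
                raise ValueError(f"species {sp!r}: one weight per archetype required")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"species {sp!r}: weights must sum to 1")


def _dirichlet_around(mean: np.ndarray, conc: float, rng) -> np.ndarray:
    if math.isinf(conc):
        return mean.copy()
    out = np.zeros_like(mean)
    pos = mean > 0
    out[pos] = rng.dirichlet(mean[pos] * conc)
    return out


def _flatfish_chunks(mass: float, large: bool) -> list[float]:
    """Split a flatfish group mass into per-individual masses landing on the
    requested side of the 200-mm threshold (exactly achievable except for
    large-flatfish masses below the 200-mm individual mass)."""
    if mass <= 0:
        return []
    if large:
        n = max(1, int(mass // _LARGE_FLATFISH_CHUNK_G))
        return [mass / n] * n
    n = max(1, math.ceil(mass / _SMALL_FLATFISH_CHUNK_G))
    return [mass / n] * n


def _emit_fish(rows, scat_id, species, date, taxon, kind, masses, model):
    for mass in masses:
        meas = model.invert_mass(mass)
        for _ in range(2):  # one otolith pair per individual
            rows.append(
                {
                    "scat_id": scat_id,
                    "species": species,
                    "date": date,
                    "taxon": taxon,
                    "structure": "otolith",
                    "structure_class": "paired",
                    "measurable": True,
                    "measurement_mm": meas,
                    "measurement_kind": kind,
                }
            )


def _emit_squid(rows, scat_id, species, date, taxon, kind, masses, model):
    for mass in masses:
        meas = model.invert_mass(mass)
        rows.append(
            {
                "scat_id": scat_id,
                "species": species,
                "date": date,
                "taxon": taxon,
                "structure": "lower beak",
                "structure_class": "lower_beak",
                "measurable": True,
                "measurement_mm": meas,
                "measurement_kind": kind,
            }
        )
        rows.append(
            {
                "scat_id": scat_id,
                "species": species,
                "date": date,
                "taxon": taxon,
                "structure": "upper beak",
                "structure_class": "upper_beak",
                "measurable": False,
                "measurement_mm": np.nan,
                "measurement_kind": "",
            }
        )


def simulate_scats(config: DietSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a hard-part table plus ground truth.

    Returns ``(parts, truth)``: ``parts`` matches the scat reader schema;
    ``truth`` has one row per scat with the archetype label and the drawn
    composition per functional group.
    """
    rng = np.random.default_rng(config.seed)
    models = toy_allometry_table()
    labels = [label for label, _, _ in config.cluster_archetypes]
    start = pd.Timestamp(config.start_date)
    part_rows: list[dict] = []
    truth_rows: list[dict] = []
    scat_no = 0
    for species in sorted(config.n_scats_per_species):
        n_scats = config.n_scats_per_species[species]
        weights = np.asarray(config.species_cluster_weights[species], dtype=float)
        for _ in range(n_scats):
            scat_no += 1
            scat_id = f"scat{scat_no:05d}"
            date = (start + pd.Timedelta(days=int(rng.integers(0, 365)))).date().isoformat()
            a_idx = int(rng.choice(len(labels), p=weights))
            label, mean, conc = config.cluster_archetypes[a_idx]
            comp = _dirichlet_around(np.asarray(mean, dtype=float), conc, rng)
            group_mass = comp * config.total_mass_g
            for gi, group in enumerate(FUNCTIONAL_GROUPS):
                mass = group_mass[gi]
                if mass <= 0:
                    continue
                if group in ("small benthic flatfish", "large benthic flatfish"):
                    taxon, kind = _GROUP_TAXA["benthic flatfish"]
                    masses = _flatfish_chunks(mass, large=group == "large benthic flatfish")
                    _emit_fish(part_rows, scat_id, species, date, taxon, kind,
                               masses, models[taxon])
                elif group == "pelagic squids":
                    taxon, kind = _GROUP_TAXA[group]
                    n_ind = int(rng.integers(config.parts_per_scat[0],
                                             config.parts_per_scat[1] + 1))
                    _emit_squid(part_rows, scat_id, species, date, taxon, kind,
                                [mass / n_ind] * n_ind, models[taxon])
                else:
                    taxon, kind = _GROUP_TAXA[group]
                    n_ind = int(rng.integers(config.parts_per_scat[0],
                                             config.parts_per_scat[1] + 1))
                    _emit_fish(part_rows, scat_id, species, date, taxon, kind,
                               [mass / n_ind] * n_ind, models[taxon])
            truth = {"scat_id": scat_id, "species": species, "archetype": label}
            truth.update({group: comp[gi] for gi, group in enumerate(FUNCTIONAL_GROUPS)})
            truth_rows.append(truth)
    parts = pd.DataFrame(part_rows)
    parts["date"] = pd.to_datetime(parts["date"])
    return parts, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# whisker isotope series


def _check_spd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (2, 2) or not np.allclose(mat, mat.T):
        raise ValueError(f"{name} must be a symmetric 2x2 matrix")
    if np.linalg.eigvalsh(mat).min() <= 0:
        raise ValueError(f"{name} must be positive definite")
    return mat


@dataclass
class SpeciesIsotopeTruth:
    mu: np.ndarray  # true species mean (d13C, d15N), per mil
    omega: np.ndarray  # between-individual covariance, per mil squared
    sigma: np.ndarray  # within-individual (residual) covariance
    n_individuals: int

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.omega = _check_spd(self.omega, "omega")
        self.sigma = _check_spd(self.sigma, "sigma")
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")


@dataclass
class IsotopeSimConfig:
    species: dict[str, SpeciesIsotopeTruth]
    segments_range: tuple[int, int] = (6, 13)
    segment_spacing_mm: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.segments_range[0] < 3:
            raise ValueError("segments per individual must be >= 3")


def simulate_whiskers(config: IsotopeSimConfig) -> pd.DataFrame:
    """Whisker series from the generative two-level model.

    Per individual i the latent mean is a bivariate Student draw with
    df = its segment count around the species mean (scale = omega); each
    segment adds bivariate-normal residual noise (sigma). Returns a long
    table (individual, species, segment_mm, d13C, d15N) with the latent
    alpha values attached as attrs['alpha'].
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    alpha_rows = []
    for species in sorted(config.species):
        truth = config.species[species]
        L = np.linalg.cholesky(truth.omega)
        for i in range(truth.n_individuals):
            ind = f"{species[:3].upper()}{i + 1:02d}"
            n_seg = int(rng.integers(config.segments_range[0], config.segments_range[1] + 1))
            # bivariate Student via normal / sqrt(chi2/df) scale mixture
            z = rng.standard_normal(2)
            w = rng.chisquare(n_seg) / n_seg
            alpha = truth.mu + (L @ z) / np.sqrt(w)
            alpha_rows.append(
                {"individual": ind, "species": species, "alpha_d13C": alpha[0],
                 "alpha_d15N": alpha[1], "n_segments": n_seg}
            )
            noise = rng.multivariate_normal(np.zeros(2), truth.sigma, size=n_seg,
                                            method="cholesky")
            for s in range(n_seg):
                rows.append(
                    {
                        "individual": ind,
                        "species": species,
                        "segment_mm": (s + 1) * config.segment_spacing_mm,
                        "d13C": alpha[0] + noise[s, 0],
                        "d15N": alpha[1] + noise[s, 1],
                    }
                )
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = pd.DataFrame(alpha_rows)
    return out


# ---------------------------------------------------------------------------
# dives


@dataclass
class DiveSimConfig:
    n_individuals: int = 3
    n_dives: int = 200  # per individual
    proportion_u: float = 0.6
    foraging_centers: list[tuple[float, float]] = field(
        default_factory=lambda: [(1.4, 50.2)]
    )  # lon/lat per behavioural mode
    spread_km: float = 5.0
    transit_spread_km: float = 40.0
    depth_range_m: tuple[float, float] = (5.0, 60.0)
    duration_range_s: tuple[float, float] = (60.0, 480.0)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.proportion_u <= 1.0:
            raise ValueError("proportion of U dives must be in [0, 1]")
        if self.spread_km <= 0 or self.transit_spread_km <= 0:
            raise ValueError("spatial spreads must be positive")
        if not self.foraging_centers:
            raise ValueError("at least one foraging center required")


_U_PROFILE = np.array([0.96, 0.98, 1.0, 1.0, 1.0, 1.0, 1.0, 0.98, 0.96])
_V_PROFILE = np.array([0.2, 0.4, 0.6, 0.8, 1.0, 0.8, 0.6, 0.4, 0.2])


def simulate_dives(config: DiveSimConfig) -> pd.DataFrame:
    """Dive table with U-shaped (flat-bottom, high TAD, clustered) and
    V-shaped (low TAD, dispersed) dives."""
    rng = np.random.default_rng(config.seed)
    centers = np.asarray(config.foraging_centers, dtype=float)
    mean_center = centers.mean(axis=0)
    rows = []
    t0 = pd.Timestamp("2012-06-01 00:00:00")
    km_per_deg_lat = 111.32
    for i in range(config.n_individuals):
        ind = f"IND{i + 1:02d}"
        for d in range(config.n_dives):
            is_u = rng.random() < config.proportion_u
            max_depth = rng.uniform(*config.depth_range_m)
            duration = rng.uniform(*config.duration_range_s)
            if is_u:
                profile = _U_PROFILE * max_depth
                pa = rng.uniform(0.92, 0.98)
                center = centers[rng.integers(len(centers))]
                spread_deg_lat = config.spread_km / km_per_deg_lat
            else:
                profile = _V_PROFILE * max_depth
                pa = rng.uniform(0.45, 0.55)
                center = mean_center
                spread_deg_lat = config.transit_spread_km / km_per_deg_lat
            lat = center[1] + rng.normal(0, spread_deg_lat)
            lon = center[0] + rng.normal(
                0, spread_deg_lat / np.cos(np.radians(center[1]))
            )
            row = {
                "individual": ind,
                "start_time": (t0 + pd.Timedelta(minutes=20 * d, days=0)).isoformat(),
                "max_depth_m": max_depth,
                "duration_s": duration,
                "percent_area": pa,
                "lon": lon,
                "lat": lat,
            }
            row.update({f"depth_p{p}": profile[j] for j, p in enumerate(range(10, 100, 10))})
            rows.append(row)
    out = pd.DataFrame(rows)
    out["start_time"] = pd.to_datetime(out["start_time"])
    return out
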