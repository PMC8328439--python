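"""Scat hard-part diet reconstruction.

Turns diagnostic hard-part records (otoliths, bones, cephalopod beaks) into
per-scat prey counts, reconstructed ingested mass, and a scats x
functional-group composition matrix.

Conventions
-----------
* measurements are in mm, reconstructed body lengths in mm, masses in g;
* fish individual counts: per paired structure type ``ceil(n/2)``, per
  unpaired structure type ``n``, overall the maximum across structure types;
* cephalopod counts: max of upper- and lower-beak tallies;
* no digestion correction factors are applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "FUNCTIONAL_GROUPS",
    "AllometryModel",
    "AllometryTable",
    "FunctionalGroupScheme",
    "count_individuals",
    "reconstruct_scat_mass",
    "reconstruct_table",
    "assign_functional_group",
    "build_composition_matrix",
    "scale_matrix",
    "derive_season",
    "read_scat_table",
    "read_allometry_table",
]

#: The six functional prey groups, in canonical column order.
FUNCTIONAL_GROUPS = (
    "small benthic flatfish",
    "large benthic flatfish",
    "benthic non-flatfish",
    "demersal fish",
    "pelagic fish",
    "pelagic squids",
)

PAIRED = "paired"
UNPAIRED = "unpaired"
UPPER_BEAK = "upper_beak"
LOWER_BEAK = "lower_beak"
_STRUCTURE_CLASSES = {PAIRED, UNPAIRED, UPPER_BEAK, LOWER_BEAK}

SCAT_COLUMNS = [
    "scat_id",
    "species",
    "date",
    "taxon",
    "structure",
    "structure_class",
    "measurable",
    "measurement_mm",
    "measurement_kind",
]


def derive_season(date) -> str:
    """Season of a sampling date: April-September is spring/summer,
    October-March autumn/winter."""
    month = pd.Timestamp(date).month
    return "spring/summer" if 4 <= month <= 9 else "autumn/winter"


def read_scat_table(path) -> pd.DataFrame:
    """Read a scat hard-part CSV and validate its schema.

    Expected columns: scat_id, species, date (ISO-8601), taxon, structure,
    structure_class (paired|unpaired|upper_beak|lower_beak), measurable
    (bool-like), measurement_mm (blank when not measurable),
    measurement_kind.
    """
    df = pd.read_csv(path, parse_dates=["date"])
    missing = set(SCAT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"scat table missing columns: {sorted(missing)}")
    bad = set(df["structure_class"].unique()) - _STRUCTURE_CLASSES
    if bad:
        raise ValueError(f"unknown structure_class values: {sorted(bad)}")
    df["measurable"] = df["measurable"].astype(bool)
    measurable = df["measurable"]
    if df.loc[measurable, "measurement_mm"].isna().any():
        raise ValueError("measurable parts must carry a measurement")
    if (df.loc[measurable, "measurement_mm"] <= 0).any():
        raise ValueError("measurements must be positive")
    df["season"] = df["date"].map(derive_season)
    return df


# ---------------------------------------------------------------------------
# allometry


@dataclass(frozen=True)
class AllometryModel:
    """Monotone measurement->length (mm) and length->mass (g) model pair."""

    measurement_kind: str
    length_form: str  # 'linear' or 'power'
    length_a: float
    length_b: float
    mass_form: str
    mass_a: float
    mass_b: float

    def _eval(self, form: str, a: float, b: float, x: float) -> float:
        if form == "linear":
            return a * x + b
        if form == "power":
            return a * x**b
        raise ValueError(f"unknown model form {form!r}")

    def length_mm(self, measurement_mm: float) -> float:
        return self._eval(self.length_form, self.length_a, self.length_b, measurement_mm)

    def mass_g(self, length_mm: float) -> float:
        return self._eval(self.mass_form, self.mass_a, self.mass_b, length_mm)

    def invert_mass(self, mass_g: float) -> float:
        """Measurement (mm) producing the given mass; only for invertible
        (positive-slope linear / power) forms. Used by the simulator."""
        if self.mass_form == "power":
            length = (mass_g / self.mass_a) ** (1.0 / self.mass_b)
        else:
            length = (mass_g - self.mass_b) / self.mass_a
        if self.length_form == "power":
            return (length / self.length_a) ** (1.0 / self.length_b)
        return (length - self.length_b) / self.length_a


class AllometryTable:
    """Per-taxon allometric models keyed by taxon label."""

    def __init__(self, models: dict[str, AllometryModel]):
        self.models = dict(models)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.models

    def __getitem__(self, taxon: str) -> AllometryModel:
        try:
            return self.models[taxon]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} missing from allometry table") from None

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AllometryTable":
        required = {
            "taxon",
            "measurement_kind",
            "length_form",
            "length_a",
            "length_b",
            "mass_form",
            "mass_a",
            "mass_b",
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"allometry table missing columns: {sorted(missing)}")
        models = {}
        for row in df.itertuples(index=False):
            models[row.taxon] = AllometryModel(
                measurement_kind=row.measurement_kind,
                length_form=row.length_form,
                length_a=float(row.length_a),
                length_b=float(row.length_b),
                mass_form=row.mass_form,
                mass_a=float(row.mass_a),
                mass_b=float(row.mass_b),
            )
        return cls(models)


def read_allometry_table(path) -> AllometryTable:
    return AllometryTable.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# functional groups


@dataclass
class FunctionalGroupScheme:
    """Taxon -> functional-group mapping, with flatfish split by length.

    Flatfish taxa map to 'benthic flatfish' in the table and are resolved to
    small/large at assignment time using ``flatfish_threshold_mm``
    (inclusive for 'large').
    """

    mapping: dict[str, str] = field(default_factory=dict)
    flatfish_threshold_mm: float = 200.0

    @classmethod
    def default(cls, flatfish_threshold_mm: float = 200.0) -> "FunctionalGroupScheme":
        with resources.files("trophicniche.data").joinpath("functional_groups.csv").open() as fh:
            df = pd.read_csv(fh)
        return cls.from_frame(df, flatfish_threshold_mm)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, flatfish_threshold_mm: float = 200.0
    ) -> "FunctionalGroupScheme":
        mapping = dict(zip(df["taxon"], df["group"]))
        return cls(mapping, flatfish_threshold_mm)

    def lookup(self, taxon: str) -> str:
        """Raw group of a taxon; pooled labels ('A/B') match components."""
        if taxon in self.mapping:
            return self.mapping[taxon]
        for label, group in self.mapping.items():
            if taxon in [part.strip() for part in label.split("/")]:
                return group
        raise KeyError(f"taxon {taxon!r} not in functional-group scheme")


def assign_functional_group(
    taxon: str, length_mm: float | None, scheme: FunctionalGroupScheme
) -> str:
    """Functional group of one reconstructed individual.

    Flatfish are large when ``length_mm >= threshold`` (boundary inclusive),
    small below; all other taxa map directly.
    """
    group = scheme.lookup(taxon)
    if group == "benthic flatfish":
        if length_mm is None or not np.isfinite(length_mm):
            raise ValueError(f"flatfish taxon {taxon!r} needs a reconstructed length")
        if length_mm >= scheme.flatfish_threshold_mm:
            return "large benthic flatfish"
        return "small benthic flatfish"
    if group not in FUNCTIONAL_GROUPS:
        raise ValueError(f"scheme maps {taxon!r} to unknown group {group!r}")
    return group


# ---------------------------------------------------------------------------
# counting and mass reconstruction


def count_individuals(parts: pd.DataFrame) -> int:
    """Minimum number of prey individuals behind one scat x taxon part set.

    Fish: the larger of ``ceil(n/2)`` per paired structure type and ``n``
    per unpaired structure type. Cephalopods: max of upper- and lower-beak
    counts. Beak rows and fish-bone rows must not be mixed within a taxon.
    """
    if len(parts) == 0:
        warnings.warn("count_individuals called on empty part set", stacklevel=2)
        return 0
    classes = set(parts["structure_class"])
    beaks = classes & {UPPER_BEAK, LOWER_BEAK}
    if beaks and classes - {UPPER_BEAK, LOWER_BEAK}:
        raise ValueError("cephalopod beaks mixed with fish structures for one taxon")
    if beaks:
        n_upper = int((parts["structure_class"] == UPPER_BEAK).sum())
        n_lower = int((parts["structure_class"] == LOWER_BEAK).sum())
        return max(n_upper, n_lower)
    best = 0
    for (_, cls), grp in parts.groupby(["structure", "structure_class"]):
        n = len(grp)
        candidate = math.ceil(n / 2) if cls == PAIRED else n
        best = max(best, candidate)
    return best


def reconstruct_scat_mass(
    parts: pd.DataFrame,
    allometry: AllometryTable,
    scheme: FunctionalGroupScheme | None = None,
    fallback_mean_mass: dict[str, float] | None = None,
    fallback_mean_length: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Reconstruct ingested mass for one scat.

    Per taxon, each measurable part yields a body length and mass; the total
    ingested mass is ``count * mean(measured masses)``, i.e. individuals
    beyond the measured ones are imputed at the within-scat mean. When no
    conspecific was measurable in the scat, the dataset-wide fallback means
    are used (with a warning).

    Returns a frame with one row per (taxon, group) holding the estimated
    count, number measured, and mass in grams. When ``scheme`` is None the
    group column is omitted and one row per taxon is returned.
    """
    if parts["scat_id"].nunique() > 1:
        raise ValueError("reconstruct_scat_mass expects parts of a single scat")
    rows = []
    for taxon, tparts in parts.groupby("taxon", sort=True):
        count = count_individuals(tparts)
        if count == 0:
            continue
        if taxon not in allometry:
            raise KeyError(f"taxon {taxon!r} missing from allometry table")
        model = allometry[taxon]
        measured = tparts.loc[tparts["measurable"], "measurement_mm"].to_numpy(float)
        if measured.size:
            lengths = np.array([model.length_mm(m) for m in measured])
            masses = np.array([model.mass_g(length) for length in lengths])
            mean_mass = float(masses.mean())
            mean_length = float(lengths.mean())
        else:
            if fallback_mean_mass is None or taxon not in fallback_mean_mass:
                raise ValueError(
                    f"no measurable part for taxon {taxon!r} and no fallback mean"
                )
            warnings.warn(
                f"taxon {taxon!r}: no measurable part in scat, "
                "imputing dataset-wide mean mass",
                stacklevel=2,
            )
            lengths = np.array([])
            masses = np.array([])
            mean_mass = fallback_mean_mass[taxon]
            mean_length = (fallback_mean_length or {}).get(taxon, np.nan)
        total_mass = count * mean_mass

        if scheme is None:
            rows.append(
                {
                    "taxon": taxon,
                    "count": count,
                    "n_measured": int(measured.size),
                    "mass_g": total_mass,
                }
            )
            continue

        # distribute individuals over groups: measured ones by their own
        # length, imputed ones at the within-scat mean length
        per_ind_lengths = list(lengths) + [mean_length] * (count - measured.size)
        per_ind_masses = list(masses) + [mean_mass] * (count - measured.size)
        if count < measured.size:
            # more measured parts than estimated individuals: rescale so the
            # total equals count * mean mass while keeping measured lengths
            per_ind_lengths = list(lengths)
            per_ind_masses = list(masses * (total_mass / masses.sum()))
        group_mass: dict[str, float] = {}
        for length, mass in zip(per_ind_lengths, per_ind_masses):
            group = assign_functional_group(taxon, length, scheme)
            group_mass[group] = group_mass.get(group, 0.0) + mass
        for group, mass in group_mass.items():
            rows.append(
                {
                    "taxon": taxon,
                    "group": group,
                    "count": count,
                    "n_measured": int(measured.size),
                    "mass_g": mass,
                }
            )
    columns = ["taxon", "count", "n_measured", "mass_g"]
    if scheme is not None:
        columns.insert(1, "group")
    return pd.DataFrame(rows, columns=columns)


def _dataset_fallbacks(table: pd.DataFrame, allometry: AllometryTable):
    mean_mass: dict[str, float] = {}
    mean_length: dict[str, float] = {}
    measured = table[table["measurable"]]
    for taxon, tparts in measured.groupby("taxon"):
        model = allometry[taxon]
        lengths = np.array([model.length_mm(m) for m in tparts["measurement_mm"]])
        masses = np.array([model.mass_g(length) for length in lengths])
        mean_mass[taxon] = float(masses.mean())
        mean_length[taxon] = float(lengths.mean())
    return mean_mass, mean_length


def reconstruct_table(
    table: pd.DataFrame,
    allometry: AllometryTable,
    scheme: FunctionalGroupScheme | None = None,
) -> pd.DataFrame:
    """Reconstruct every scat of a full hard-part table.

    Returns a long frame: scat_id, species, date, season, taxon, [group,]
    count, n_measured, mass_g.
    """
    scheme = scheme or FunctionalGroupScheme.default()
    fallback_mass, fallback_length = _dataset_fallbacks(table, allometry)
    frames = []
    meta_cols = ["species", "date"]
    for scat_id, parts in table.groupby("scat_id", sort=True):
        rec = reconstruct_scat_mass(
            parts,
            allometry,
            scheme=scheme,
            fallback_mean_mass=fallback_mass,
            fallback_mean_length=fallback_length,
        )
        if rec.empty:
            continue
        rec.insert(0, "scat_id", scat_id)
        for i, col in enumerate(meta_cols, start=1):
            rec.insert(i, col, parts[col].iloc[0])
        frames.append(rec)
    if not frames:
        return pd.DataFrame(
            columns=["scat_id", *meta_cols, "taxon", "group", "count", "n_measured", "mass_g"]
        )
    out = pd.concat(frames, ignore_index=True)
    out["season"] = out["date"].map(derive_season)
    return out


# ---------------------------------------------------------------------------
# composition matrix


def build_composition_matrix(masses: pd.DataFrame) -> pd.DataFrame:
    """Scats x functional-group matrix of reconstructed-mass proportions.

    ``masses`` is the long output of :func:`reconstruct_table` (needs
    scat_id, species, date, group, mass_g). Rows are normalized to sum to 1;
    zero-mass scats are dropped with a warning.
    """
    if masses.empty or not np.isfinite(masses["mass_g"]).any():
        raise ValueError("no reconstructed mass to build a composition matrix from")
    wide = (
        masses.pivot_table(
            index="scat_id", columns="group", values="mass_g", aggfunc="sum", fill_value=0.0
        )
        .reindex(columns=list(FUNCTIONAL_GROUPS), fill_value=0.0)
    )
    totals = wide.sum(axis=1)
    if (totals <= 0).all():
        raise ValueError("all scats have zero reconstructed mass")
    zero = totals <= 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} zero-mass scats", stacklevel=2)
        wide = wide.loc[~zero]
        totals = totals.loc[~zero]
    props = wide.div(totals, axis=0)
    meta = (
        masses.drop_duplicates("scat_id")
        .set_index("scat_id")[["species", "date"]]
        .reindex(props.index)
    )
    props.insert(0, "species", meta["species"])
    props.insert(1, "date", meta["date"])
    props.insert(2, "season", meta["date"].map(derive_season))
    return props


def composition_values(matrix: pd.DataFrame) -> np.ndarray:
    """Numeric group-proportion block of a composition matrix."""
    return matrix[list(FUNCTIONAL_GROUPS)].to_numpy(float)


def scale_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-standardize the composition matrix (mean 0, sd 1, ddof=1).

    Constant columns are centered only, with a warning. Requires >= 2 rows.
    """
    if len(matrix) < 2:
        raise ValueError("scaling needs at least two scats")
    out = matrix.copy()
    X = composition_values(matrix)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant column(s) left centered, not scaled",
            stacklevel=2,
        )
    sd_safe = np.where(constant, 1.0, sd)
    out[list(FUNCTIONAL_GROUPS)] = (X - mean) / sd_safe
    return out
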