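import itertools
import math

import numpy as np
import pandas as pd
import pytest

from trophicniche import diet
from trophicniche.diet import (
    FUNCTIONAL_GROUPS,
    AllometryModel,
    AllometryTable,
    FunctionalGroupScheme,
    assign_functional_group,
    build_composition_matrix,
    count_individuals,
    derive_season,
    reconstruct_scat_mass,
    scale_matrix,
)


def parts_frame(records):
    rows = []
    for structure, cls, measurable, meas in records:
        rows.append(
            {
                "scat_id": "s1",
                "species": "harbour",
                "date": pd.Timestamp("2010-06-01"),
                "taxon": "t",
                "structure": structure,
                "structure_class": cls,
                "measurable": measurable,
                "measurement_mm": meas,
                "measurement_kind": "otolith length",
            }
        )
    return pd.DataFrame(rows)


class TestCountIndividuals:
    def test_five_otoliths(self):
        parts = parts_frame([("otolith", "paired", True, 3.0)] * 5)
        assert count_individuals(parts) == 3  # ceil(5/2)

    def test_unpaired_dominates(self):
        parts = parts_frame(
            [("otolith", "paired", True, 3.0)] * 5
            + [("parasphenoid", "unpaired", False, np.nan)] * 4
        )
        assert count_individuals(parts) == 4

    def test_cephalopod_rule(self):
        parts = parts_frame(
            [("upper beak", "upper_beak", False, np.nan)] * 3
            + [("lower beak", "lower_beak", True, 2.0)] * 5
        )
        assert count_individuals(parts) == 5

    def test_empty_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert count_individuals(parts_frame([])) == 0

    def test_matches_enumeration_oracle(self):
        """Exhaustive check against a brute-force oracle for all structure
        multisets of size <= 8 over two paired and one unpaired type."""
        structures = [
            ("otolith", "paired"),
            ("dentary", "paired"),
            ("parasphenoid", "unpaired"),
        ]
        for total in range(1, 9):
            for combo in itertools.combinations_with_replacement(range(3), total):
                counts = [combo.count(i) for i in range(3)]
                parts = parts_frame(
                    [
                        (structures[i][0], structures[i][1], False, np.nan)
                        for i in range(3)
                        for _ in range(counts[i])
                    ]
                )
                oracle = max(
                    math.ceil(counts[0] / 2) if counts[0] else 0,
                    math.ceil(counts[1] / 2) if counts[1] else 0,
                    counts[2],
                )
                assert count_individuals(parts) == oracle


@pytest.fixture()
def toy_allometry():
    # L = 10 * OL (mm), M = 0.001 * L^3 (g)
    return AllometryTable(
        {
            "t": AllometryModel("otolith length", "linear", 10.0, 0.0, "power", 1e-3, 3.0)
        }
    )


class TestReconstruction:
    def test_direct_arithmetic(self, toy_allometry):
        parts = parts_frame([("otolith", "paired", True, 4.0)] * 2)
        rec = reconstruct_scat_mass(parts, toy_allometry)
        assert rec["count"].iloc[0] == 1
        assert rec["mass_g"].iloc[0] == pytest.approx(64.0)  # (40 mm)^3 * 1e-3

    def test_imputation_at_mean(self, toy_allometry):
        # 3 individuals estimated, two measured at 10 g and 20 g -> 45 g
        m10 = (10 / 1e-3) ** (1 / 3) / 10  # measurement giving 10 g
        m20 = (20 / 1e-3) ** (1 / 3) / 10
        parts = parts_frame(
            [
                ("otolith", "paired", True, m10),
                ("otolith", "paired", True, m20),
                ("parasphenoid", "unpaired", False, np.nan),
                ("parasphenoid", "unpaired", False, np.nan),
                ("parasphenoid", "unpaired", False, np.nan),
            ]
        )
        rec = reconstruct_scat_mass(parts, toy_allometry)
        assert rec["count"].iloc[0] == 3
        assert rec["mass_g"].iloc[0] == pytest.approx(45.0)

    def test_no_imputation_when_counts_match(self, toy_allometry):
        m10 = (10 / 1e-3) ** (1 / 3) / 10
        m20 = (20 / 1e-3) ** (1 / 3) / 10
        parts = parts_frame(
            [("otolith", "paired", True, m10)] * 2 + [("otolith", "paired", True, m20)] * 2
        )
        rec = reconstruct_scat_mass(parts, toy_allometry)
        assert rec["count"].iloc[0] == 2
        assert rec["mass_g"].iloc[0] == pytest.approx(30.0)

    def test_missing_taxon_raises(self):
        parts = parts_frame([("otolith", "paired", True, 4.0)])
        with pytest.raises(KeyError, match="'t'"):
            reconstruct_scat_mass(parts, AllometryTable({}))

    def test_mass_conservation_with_groups(self, toy_allometry):
        parts = parts_frame([("otolith", "paired", True, 4.0)] * 6)
        scheme = FunctionalGroupScheme({"t": "demersal fish"})
        with_groups = reconstruct_scat_mass(parts, toy_allometry, scheme=scheme)
        without = reconstruct_scat_mass(parts, toy_allometry)
        assert with_groups["mass_g"].sum() == pytest.approx(
            without["mass_g"].sum(), abs=1e-9
        )


class TestFunctionalGroups:
    def test_small_flatfish(self):
        scheme = FunctionalGroupScheme.default()
        assert (
            assign_functional_group("Pleuronectes platessa", 150.0, scheme)
            == "small benthic flatfish"
        )

    def test_boundary_inclusive_large(self):
        scheme = FunctionalGroupScheme.default()
        assert (
            assign_functional_group("Solea solea", 200.0, scheme)
            == "large benthic flatfish"
        )

    def test_squid_any_length(self):
        scheme = FunctionalGroupScheme.default()
        assert assign_functional_group("Loligo spp.", 500.0, scheme) == "pelagic squids"
        assert assign_functional_group("Loligo spp.", 10.0, scheme) == "pelagic squids"

    def test_unknown_taxon_raises(self):
        with pytest.raises(KeyError):
            assign_functional_group("Carcharodon carcharias", 100.0,
                                    FunctionalGroupScheme.default())

    def test_default_scheme_has_six_groups(self):
        scheme = FunctionalGroupScheme.default()
        resolved = {
            "large benthic flatfish" if g == "benthic flatfish" else g
            for g in scheme.mapping.values()
        } | {"small benthic flatfish"}
        assert resolved == set(FUNCTIONAL_GROUPS)


def masses_frame(rows):
    return pd.DataFrame(
        rows, columns=["scat_id", "species", "date", "group", "mass_g"]
    ).assign(date=lambda d: pd.to_datetime(d["date"]))


class TestCompositionMatrix:
    def test_single_group_row(self):
        m = build_composition_matrix(
            masses_frame([("s1", "harbour", "2010-06-01", "pelagic fish", 50.0)])
        )
        np.testing.assert_allclose(
            m[list(FUNCTIONAL_GROUPS)].to_numpy()[0], [0, 0, 0, 0, 1, 0]
        )

    def test_thirty_seventy(self):
        m = build_composition_matrix(
            masses_frame(
                [
                    ("s1", "harbour", "2010-06-01", "demersal fish", 30.0),
                    ("s1", "harbour", "2010-06-01", "pelagic fish", 70.0),
                ]
            )
        )
        row = m[list(FUNCTIONAL_GROUPS)].iloc[0]
        assert row["demersal fish"] == pytest.approx(0.3)
        assert row["pelagic fish"] == pytest.approx(0.7)

    def test_rows_sum_to_one(self, composition_matrix):
        sums = composition_matrix[list(FUNCTIONAL_GROUPS)].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            build_composition_matrix(
                masses_frame([("s1", "harbour", "2010-06-01", "pelagic fish", 0.0)])
            )

    def test_zero_mass_scat_dropped_with_warning(self):
        frame = masses_frame(
            [
                ("s1", "harbour", "2010-06-01", "pelagic fish", 10.0),
                ("s2", "harbour", "2010-06-01", "pelagic fish", 0.0),
            ]
        )
        with pytest.warns(UserWarning, match="zero-mass"):
            m = build_composition_matrix(frame)
        assert list(m.index) == ["s1"]


class TestScaleMatrix:
    def make(self, cols):
        n = len(next(iter(cols.values())))
        data = {g: cols.get(g, np.zeros(n)) for g in FUNCTIONAL_GROUPS}
        df = pd.DataFrame(data)
        df.insert(0, "species", "harbour")
        df.insert(1, "date", pd.Timestamp("2010-06-01"))
        df.insert(2, "season", "spring/summer")
        return df

    def test_two_point_column(self):
        with pytest.warns(UserWarning):  # other columns constant
            scaled = scale_matrix(self.make({"pelagic fish": np.array([0.0, 1.0])}))
        np.testing.assert_allclose(
            scaled["pelagic fish"].to_numpy(), [-0.70710678, 0.70710678]
        )

    def test_idempotent_on_standardized(self, composition_matrix):
        scaled = scale_matrix(composition_matrix)
        again = scale_matrix(scaled)
        np.testing.assert_allclose(
            diet.composition_values(again), diet.composition_values(scaled), atol=1e-12
        )

    def test_constant_column_zeroed_with_warning(self):
        df = self.make(
            {
                "pelagic fish": np.array([0.4, 0.6, 0.5]),
                "demersal fish": np.array([0.5, 0.5, 0.5]),
            }
        )
        with pytest.warns(UserWarning, match="constant"):
            scaled = scale_matrix(df)
        np.testing.assert_allclose(scaled["demersal fish"].to_numpy(), 0.0)

    def test_single_row_raises(self):
        with pytest.raises(ValueError):
            scale_matrix(self.make({"pelagic fish": np.array([1.0])}))


def test_season_derivation():
    assert derive_season("2010-04-01") == "spring/summer"
    assert derive_season("2010-09-30") == "spring/summer"
    assert derive_season("2010-10-01") == "autumn/winter"
    assert derive_season("2010-03-31") == "autumn/winter"


def test_roundtrip_against_generating_composition(scat_dataset, composition_matrix):
    """Reconstructed proportions match the drawn composition within 2%."""
    _, truth = scat_dataset
    t = truth.set_index("scat_id")[list(FUNCTIONAL_GROUPS)]
    got = composition_matrix[list(FUNCTIONAL_GROUPS)]
    err = (got - t.loc[got.index]).abs().to_numpy().max()
    assert err < 0.02
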