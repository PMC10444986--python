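import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from florivis import resources as rs
from florivis.io import ValidationError


class TestSucroseDensity:
    def test_intercept_at_zero(self):
        assert rs.sucrose_density(0.0) == pytest.approx(0.9988603, abs=1e-12)

    def test_hand_evaluated_point(self):
        # 0.0037921*20 + 0.0000178*400 + 0.9988603
        assert rs.sucrose_density(20.0) == pytest.approx(1.0818223, abs=1e-7)

    @given(st.floats(0.0, 84.0))
    @settings(derandomize=True, max_examples=50)
    def test_strictly_increasing(self, c):
        assert rs.sucrose_density(c + 1.0) > rs.sucrose_density(c)

    def test_range_bounds(self):
        c = np.linspace(0, 85, 1000)
        d = rs.sucrose_density(c)
        assert d.min() >= 0.9988603
        assert d.max() <= rs.sucrose_density(85.0)

    @pytest.mark.parametrize("bad", [-1.0, 85.1, 200.0])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            rs.sucrose_density(bad)


class TestNectarSugarMass:
    def test_zero_volume(self):
        assert rs.nectar_sugar_mass("direct", 30.0, nectar_volume_ul=0.0) == 0.0

    def test_direct_worked_example(self):
        s = rs.nectar_sugar_mass("direct", 20.0, nectar_volume_ul=1.0)
        assert s == pytest.approx(216.36446, abs=1e-5)

    def test_rinse_uses_rinse_volume(self):
        s = rs.nectar_sugar_mass("rinse", 5.0, rinse_volume_ul=2.0)
        d5 = 0.0037921 * 5 + 0.0000178 * 25 + 0.9988603
        assert s == pytest.approx(10 * d5 * 2 * 5, rel=1e-12)

    @given(st.floats(0.01, 10.0), st.floats(0.1, 80.0))
    @settings(derandomize=True, max_examples=50)
    def test_linear_in_volume(self, v, c):
        s1 = rs.nectar_sugar_mass("direct", c, nectar_volume_ul=v)
        s2 = rs.nectar_sugar_mass("direct", c, nectar_volume_ul=2 * v)
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    def test_missing_required_field(self):
        with pytest.raises(ValidationError):
            rs.nectar_sugar_mass("direct", 20.0)
        with pytest.raises(ValidationError):
            rs.nectar_sugar_mass("rinse", 20.0)


class TestPollen:
    @pytest.mark.parametrize(
        "counts,u,expected",
        [((0, 0), 500.0, 0.0), ((40, 60), 100.0, 500.0), ((10, 10), 30.0, 30.0)],
    )
    def test_grains_per_flower(self, counts, u, expected):
        assert rs.grains_per_flower(counts, u) == pytest.approx(expected)

    def test_nonpositive_suspension_rejected(self):
        with pytest.raises(ValueError):
            rs.grains_per_flower((1, 1), 0.0)

    def test_sphere_volume(self):
        assert rs.grain_volume(10.0, 10.0) == pytest.approx(523.5988, abs=1e-4)

    def test_prolate_volume(self):
        assert rs.grain_volume(20.0, 10.0) == pytest.approx(1047.1976, abs=1e-4)

    @pytest.mark.parametrize("major,minor", [(0.0, 0.0), (10.0, 0.0), (5.0, 10.0)])
    def test_axis_validation(self, major, minor):
        with pytest.raises(ValidationError):
            rs.grain_volume(major, minor)

    @pytest.mark.parametrize(
        "n,v,expected",
        [(0.0, 1000.0, 0.0), (1e6, 1000.0, 1.0), (500.0, 1047.1976, 5.2360e-4)],
    )
    def test_volume_per_flower_unit_conversion(self, n, v, expected):
        assert rs.pollen_volume_per_flower(n, v) == pytest.approx(expected, rel=1e-4)

    def test_matches_per_grain_summation_oracle(self):
        # converting each grain's volume individually and summing must agree
        rng = np.random.default_rng(7)
        vols = rng.uniform(100.0, 5000.0, size=200)  # µm³ per grain
        oracle_ul = sum(v / 1e9 for v in vols)
        assert rs.pollen_volume_per_flower(len(vols), vols.mean()) == pytest.approx(
            oracle_ul, rel=1e-12
        )


class TestSpeciesProfiles:
    def _nectar_rows(self, species_id, masses, conc=20.0):
        d = rs.sucrose_density(conc)
        return [
            (species_id, "direct", m / (10 * d * conc), conc, np.nan) for m in masses
        ]

    def test_mean_of_samples(self, species_df):
        nectar = pd.DataFrame(
            self._nectar_rows("erigeron", [100.0, 200.0]),
            columns=rs.NECTAR_COLUMNS,
        )
        prof = rs.build_species_profiles(nectar, None, None, species_df)
        row = prof.set_index("species_id").loc["erigeron"]
        assert row["mean_sugar_ug"] == pytest.approx(150.0, rel=1e-9)
        assert row["n_nectar"] == 2

    def test_pollen_without_nectar_is_flagged_not_zero(self, species_df):
        counts = pd.DataFrame(
            [("lamium", "s0", 50, 50, 100.0)], columns=rs.POLLEN_COUNT_COLUMNS
        )
        grains = pd.DataFrame(
            [("lamium", 20.0, 10.0)], columns=rs.POLLEN_GRAIN_COLUMNS
        )
        prof = rs.build_species_profiles(None, counts, grains, species_df)
        row = prof.set_index("species_id").loc["lamium"]
        assert np.isnan(row["mean_sugar_ug"])  # unmeasured, never 0
        assert row["n_nectar"] == 0
        # grains per flower = 50 * 100/10 = 500; V = 1047.1976 µm³
        assert row["mean_pollen_ul"] == pytest.approx(500 * 1047.1976 / 1e9, rel=1e-4)

    def test_empty_inputs(self, species_df):
        prof = rs.build_species_profiles(None, None, None, species_df)
        assert prof["mean_sugar_ug"].isna().all()
        assert prof["mean_pollen_ul"].isna().all()
        assert (prof["n_nectar"] == 0).all()

    def test_grain_volume_from_mean_axes(self, species_df):
        # two grains: mean axes (15, 9) -> V computed from means, not mean of Vs
        grains = pd.DataFrame(
            [("erigeron", 10.0, 8.0), ("erigeron", 20.0, 10.0)],
            columns=rs.POLLEN_GRAIN_COLUMNS,
        )
        counts = pd.DataFrame(
            [("erigeron", "s0", 10, 10, 10.0)], columns=rs.POLLEN_COUNT_COLUMNS
        )
        prof = rs.build_species_profiles(None, counts, grains, species_df)
        row = prof.set_index("species_id").loc["erigeron"]
        v_mean_axes = rs.grain_volume(15.0, 9.0)
        assert row["mean_pollen_ul"] == pytest.approx(10 * v_mean_axes / 1e9, rel=1e-9)


class TestCoverage:
    def test_coverage_excludes_nectarless_species_from_nectar_base(self):
        species = pd.DataFrame(
            {
                "species_id": ["a", "b", "c"],
                "origin": ["alien", "native", "native"],
                "has_nectaries": [True, True, False],
                "floral_unit_type": ["flower"] * 3,
            }
        )
        prof = pd.DataFrame(
            {
                "species_id": ["a", "b", "c"],
                "mean_sugar_ug": [1.0, np.nan, np.nan],
                "mean_pollen_ul": [0.1, 0.2, np.nan],
                "n_nectar": [3, 0, 0],
                "n_pollen": [2, 2, 0],
            }
        )
        cov = rs.measurement_coverage(prof, species)
        assert cov["nectar_species_pct"] == 50.0  # 1 of 2 with nectaries
        assert cov["pollen_species_pct"] == pytest.approx(66.7)
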