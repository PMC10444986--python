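import datetime as dt

import numpy as np
import pandas as pd
import pytest

from florivis import io, simulate as sim
from florivis import resources as rs
from conftest import true_profiles


def _mini_config(**kw):
    archetypes = kw.pop(
        "archetypes",
        (
            sim.SpeciesArchetype("sp_a", "alien", 60.0, 120.0, 50.0, 900.0, 0.5),
            sim.SpeciesArchetype("sp_b", "native", 60.0, 120.0, 50.0, 100.0, 0.05),
        ),
    )
    return sim.SimulationConfig(
        sites=("site1",), archetypes=archetypes, **kw
    )


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        d1 = sim.generate(sim.SimulationConfig(seed=7))
        d2 = sim.generate(sim.SimulationConfig(seed=7))
        for name in ("species", "floral_counts", "visits", "nectar_samples",
                     "pollen_counts", "pollen_grains"):
            pd.testing.assert_frame_equal(getattr(d1, name), getattr(d2, name))

    def test_different_seeds_differ(self):
        d1 = sim.generate(sim.SimulationConfig(seed=1))
        d2 = sim.generate(sim.SimulationConfig(seed=2))
        assert not d1.floral_counts.equals(d2.floral_counts)


class TestPhenology:
    def test_zero_outside_flowering_window(self):
        arch = sim.SpeciesArchetype("s", "native", 50.0, 30.0, 40.0, 10.0, 0.1)
        assert sim._phenology_mean(arch, 150.0) == 0.0
        assert sim._phenology_mean(arch, 50.0) == 40.0

    def test_mean_counts_near_expectation(self):
        # law of large numbers at the phenology peak with weak overdispersion
        cfg = _mini_config(n_plots=1000, theta_counts=100.0, seed=5)
        counts = sim.simulate_phenology_counts(cfg)
        arch = cfg.archetypes[0]
        peak_date = cfg.boundaries.year1_start + dt.timedelta(days=int(arch.peak_day))
        # nearest survey occasion to the peak
        dates = sim.survey_dates(cfg)
        nearest = min(dates, key=lambda d: abs((d - peak_date).days))
        t = sim._cycle_day(nearest, cfg.boundaries)
        expected = sim._phenology_mean(arch, t)
        observed = counts[
            (counts["date"] == nearest) & (counts["species_id"] == "sp_a")
        ]["floral_units"]
        # absent rows are zeros
        mean = observed.sum() / 1000
        assert mean == pytest.approx(expected, rel=0.10)

    def test_default_community_bimodal_resource_curve(self):
        from scipy.signal import find_peaks

        curve = sim.expected_resource_curve(sim.SimulationConfig())
        v = curve["value"].to_numpy()
        idx, _ = find_peaks(v, prominence=0.1 * v.max())
        assert len(idx) == 2  # late spring/early summer and autumn


class TestResourceSamples:
    def test_zero_variance_round_trips_exactly(self):
        arch = sim.SpeciesArchetype(
            "s", "native", 50.0, 30.0, 40.0, 123.0, 0.04,
            sugar_sigma_log=0.0, pollen_sigma_log=0.0,
        )
        cfg = _mini_config(archetypes=(arch,), seed=3)
        nectar, pcounts, pgrains = sim.simulate_resource_samples(cfg)
        species = pd.DataFrame(
            {"species_id": ["s"], "origin": ["native"],
             "has_nectaries": [True], "floral_unit_type": ["flower"]}
        )
        prof = rs.build_species_profiles(nectar, pcounts, pgrains, species)
        assert prof["mean_sugar_ug"].iloc[0] == pytest.approx(123.0, rel=1e-9)
        assert prof["mean_pollen_ul"].iloc[0] == pytest.approx(0.04, rel=1e-9)

    def test_stochastic_recovery_within_15pct(self):
        arch = sim.SpeciesArchetype("s", "native", 50.0, 30.0, 40.0, 100.0, 0.05)
        species = pd.DataFrame(
            {"species_id": ["s"], "origin": ["native"],
             "has_nectaries": [True], "floral_unit_type": ["flower"]}
        )
        ok = 0
        for seed in range(20):
            cfg = _mini_config(
                archetypes=(arch,), seed=seed, n_nectar_range=(50, 50)
            )
            nectar, pcounts, pgrains = sim.simulate_resource_samples(cfg)
            prof = rs.build_species_profiles(nectar, pcounts, pgrains, species)
            if abs(prof["mean_sugar_ug"].iloc[0] / 100.0 - 1) < 0.15:
                ok += 1
        assert ok >= 18  # ~95% of seeds

    def test_unmeasured_species_emit_no_rows(self):
        arch = sim.SpeciesArchetype("s", "native", 50.0, 30.0, 40.0, None, None)
        cfg = _mini_config(archetypes=(arch,), seed=0)
        nectar, pcounts, pgrains = sim.simulate_resource_samples(cfg)
        assert len(nectar) == 0 and len(pcounts) == 0 and len(pgrains) == 0

    def test_rinse_method_used_for_tiny_flowers(self, default_dataset):
        methods = default_dataset.nectar_samples.groupby("species_id")["method"].agg(set)
        assert {"rinse"} in list(methods.values)  # at least one rinse-only species
        # and rinse samples still recover their species mean within tolerance
        prof = rs.build_species_profiles(
            default_dataset.nectar_samples, None, None, default_dataset.species
        )
        gt = default_dataset.ground_truth["species"]
        rinse_species = [s for s, m in methods.items() if m == {"rinse"}]
        for s in rinse_species:
            got = prof.set_index("species_id").loc[s, "mean_sugar_ug"]
            assert got == pytest.approx(gt[s]["sugar_mean_ug"], rel=0.5)


class TestVisits:
    def _two_species_config(self, regime, seed=0):
        archetypes = (
            sim.SpeciesArchetype("rich", "alien", 60.0, 360.0, 50.0, 900.0, 0.9,
                                 sugar_sigma_log=0.0, pollen_sigma_log=0.0),
            sim.SpeciesArchetype("poor", "native", 60.0, 360.0, 50.0, 100.0, 0.1,
                                 sugar_sigma_log=0.0, pollen_sigma_log=0.0),
        )
        return sim.SimulationConfig(
            sites=("site1",), archetypes=archetypes, regime=regime, seed=seed,
            visits_per_site_year=10_000.0, theta_counts=1000.0, nonwild_rate=0.0,
        )

    def test_resource_proportional_allocation(self):
        cfg = self._two_species_config("resource_proportional")
        counts = sim.simulate_phenology_counts(cfg)
        visits = sim.simulate_visits(cfg, counts)
        share = visits.groupby("species_id")["count"].sum()
        frac = share["rich"] / share.sum()
        # equal floral abundance; rich species holds 0.9 of both resources
        assert 0.88 < frac < 0.92

    def test_even_preference_allocation(self):
        cfg = self._two_species_config("even_preference")
        counts = sim.simulate_phenology_counts(cfg)
        visits = sim.simulate_visits(cfg, counts)
        share = visits.groupby("species_id")["count"].sum()
        frac = share["rich"] / share.sum()
        assert 0.45 < frac < 0.55

    def test_native_bias_shifts_allocation(self):
        cfg = self._two_species_config("native_biased")
        counts = sim.simulate_phenology_counts(cfg)
        visits = sim.simulate_visits(cfg, counts)
        share = visits.groupby("species_id")["count"].sum()
        assert share["poor"] > share["rich"]

    def test_non_flowering_species_get_no_visits(self, default_dataset):
        ds = default_dataset
        flowering = set(
            map(tuple, ds.floral_counts[["site", "date", "plot_id", "species_id"]]
                .itertuples(index=False))
        )
        visited = set(
            map(tuple, ds.visits[["site", "date", "plot_id", "species_id"]]
                .itertuples(index=False))
        )
        assert visited <= flowering

    def test_nonwild_groups_present(self, default_dataset):
        groups = set(default_dataset.visits["insect_group"])
        assert "honeybee" in groups


class TestGenerate:
    def test_default_config_echo(self, default_dataset):
        ds = default_dataset
        assert ds.species["origin"].nunique() == 2
        periods = io.assign_periods(ds.floral_counts["date"])
        assert set(periods["study_year"]) == {1, 2}
        assert len(set(ds.floral_counts["site"])) >= 2

    def test_tables_round_trip_through_validation(self, tmp_path, default_dataset):
        default_dataset.write(tmp_path)
        tables = io.validate_dataset(tmp_path)
        pd.testing.assert_frame_equal(tables["species"], default_dataset.species)
        pd.testing.assert_frame_equal(
            tables["floral_counts"], default_dataset.floral_counts
        )
        pd.testing.assert_frame_equal(tables["visits"], default_dataset.visits)
        rs.read_nectar_samples(tmp_path / "nectar_samples.csv")
        rs.read_pollen_counts(tmp_path / "pollen_counts.csv")
        rs.read_pollen_grains(tmp_path / "pollen_grains.csv")

    def test_write_deterministic_checksums(self, tmp_path):
        import hashlib

        sums = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            sim.generate(sim.SimulationConfig(seed=9), out)
            sums.append(
                {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                 for p in sorted(out.glob("*.csv"))}
            )
        assert sums[0] == sums[1]

    def test_ground_truth_sufficient_for_scoring(self, default_dataset):
        gt = default_dataset.ground_truth
        assert gt["regime"] in sim.REGIMES
        assert set(gt["species"]) == set(default_dataset.species["species_id"])
        profs = true_profiles(default_dataset)
        assert profs["mean_sugar_ug"].notna().sum() > 20
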