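import numpy as np
import pandas as pd
import pytest
from scipy import stats

from occutrend import synthetic as syn
from occutrend.trends import ols_slope


class TestLandscape:
    def test_zone_counts(self, demo_config):
        frame = syn.generate_landscape(demo_config)
        assert len(frame) == 9 * demo_config.n_squares_per_zone
        assert frame.groupby("zone").size().min() == demo_config.n_squares_per_zone

    def test_elevation_class_rule(self):
        assert syn.elevation_class(999.0) == "low"
        assert syn.elevation_class(1001.0) == "high"
        assert syn.elevation_class(1000.0) == "high"

    def test_classes_consistent_with_zones(self, demo_config):
        frame = syn.generate_landscape(demo_config)
        high = frame["zone"].str.endswith("high")
        assert (frame.loc[high, "elevation_m"] >= 1000).all()
        assert (frame.loc[~high, "elevation_m"] < 1000).all()

    def test_seed_determinism(self, demo_config):
        a = syn.generate_landscape(demo_config)
        b = syn.generate_landscape(demo_config)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            syn.SimulationConfig(n_squares_per_zone=0)
        with pytest.raises(ValueError):
            syn.SimulationConfig(sd_square=-1.0)


class TestDriverTrajectories:
    def test_zero_noise_zero_trend_constant_climate(self):
        cfg = syn.SimulationConfig(
            n_squares_per_zone=2, n_years=11, climate_noise_sd=0.0,
            precip_noise_sd=0.0, temp_trend_range=(0.0, 0.0),
            seasonality_trend_range=(0.0, 0.0), precip_trend_range=(0.0, 0.0))
        raw = syn.generate_driver_trajectories(cfg)
        clim = raw["climate_monthly"]
        for (z, m), g in clim.groupby(["zone", "month"]):
            assert g["temp_c"].nunique() == 1
            assert g["precip_mm"].nunique() == 1

    def test_configured_temperature_trend_recovered(self):
        cfg = syn.SimulationConfig(
            n_squares_per_zone=2, n_years=41, climate_noise_sd=0.05,
            temp_trend_range=(0.05, 0.05), seasonality_trend_range=(0.0, 0.0))
        raw = syn.generate_driver_trajectories(cfg)
        clim = raw["climate_monthly"]
        for z, g in clim.groupby("zone"):
            annual = g.groupby("year")["temp_c"].mean()
            slope = float(ols_slope(annual.to_numpy(),
                                    annual.index.to_numpy(dtype=float)))
            assert slope == pytest.approx(0.05, abs=0.01)

    def test_gap_fraction(self):
        cfg = syn.SimulationConfig(n_squares_per_zone=2, n_years=41,
                                   landuse_gap_fraction=0.5)
        raw = syn.generate_driver_trajectories(cfg)
        lu = raw["landuse"]
        census_start = cfg.start_year + int(0.4 * cfg.n_years)
        early = lu[(lu["year"] > cfg.start_year) & (lu["year"] < census_start)]
        frac = early["agri_area_km2"].isna().mean()
        assert 0.3 < frac < 0.7
        late = lu[lu["year"] >= census_start]
        assert late["agri_area_km2"].notna().all()


class TestOccupancyDynamics:
    def _tiny(self, **kw):
        base = dict(n_squares_per_zone=8, n_zones=9, n_years=21,
                    n_species_per_group=(4, 2, 2), rng_seed=3)
        base.update(kw)
        return syn.SimulationConfig(**base)

    def test_all_coefficients_zero_gives_half(self):
        cfg = self._tiny(
            occ_intercept=0.0, occ_elev=0.0, occ_elev2=0.0, sd_region=0.0,
            sd_square=0.0, species_intercept_sd=0.0, year_walk_sd=0.0,
            driver_effect_sizes={}, trait_interactions={})
        frame = syn.generate_landscape(cfg)
        raw = syn.generate_driver_trajectories(cfg)
        dt, _ = syn.derive_driver_table(raw, cfg)
        species = syn.generate_species(cfg)
        truth = syn.simulate_occupancy_dynamics(frame, dt, species, cfg)
        assert np.allclose(truth.psi, 0.5)

    def test_zero_driver_effects_give_null_trends(self):
        cfg = self._tiny(driver_effect_sizes={}, trait_interactions={},
                         year_walk_sd=0.02)
        frame = syn.generate_landscape(cfg)
        raw = syn.generate_driver_trajectories(cfg)
        dt, _ = syn.derive_driver_table(raw, cfg)
        species = syn.generate_species(cfg)
        truth = syn.simulate_occupancy_dynamics(frame, dt, species, cfg)
        tt = truth.true_trends_zone["true_trend"]
        mc_se = tt.std() / np.sqrt(len(tt))
        assert abs(tt.mean()) < 3 * max(mc_se, 1e-9)

    def test_positive_temperature_effect_orders_zones(self):
        cfg = self._tiny(
            driver_effect_sizes={"temp_mean_change": 0.8},
            trait_interactions={}, year_walk_sd=0.0, landuse_agri_only=False)
        frame = syn.generate_landscape(cfg)
        raw = syn.generate_driver_trajectories(cfg)
        dt, _ = syn.derive_driver_table(raw, cfg)
        species = syn.generate_species(cfg)
        truth = syn.simulate_occupancy_dynamics(frame, dt, species, cfg)
        merged = truth.true_trends_zone.merge(dt, on=["zone", "interval"])
        rho = stats.spearmanr(merged["temp_mean_change"],
                              merged["true_trend"]).statistic
        assert rho > 0.3

    def test_z_only_where_psi_positive(self, demo_world):
        truth = demo_world["truth"]
        assert truth.z.dtype == bool
        assert not np.any(truth.z & (truth.psi <= 0))


class TestVisitsAndRecords:
    def test_no_occupancy_no_records(self, demo_world):
        truth = demo_world["truth"]
        empty = syn.TrueState(psi=truth.psi, z=np.zeros_like(truth.z),
                              species=truth.species,
                              true_trends_zone=truth.true_trends_zone,
                              true_trends_country=truth.true_trends_country)
        out = syn.simulate_visits_and_records(empty, demo_world["frame"],
                                              demo_world["config"])
        assert len(out["records"]) == 0

    def test_perfect_detection_recovers_occupancy(self):
        cfg = syn.SimulationConfig(
            n_squares_per_zone=6, n_zones=9, n_years=6,
            n_species_per_group=(2, 1, 1), det_intercept=30.0,
            det_yday=0.0, det_yday2=0.0, det_effort_sd=0.0, det_skill_sd=0.0,
            det_expert_bonus=0.0, det_year_sd=0.0, visit_intensity=4.0,
            larval_fraction=0.0,
            source_probs={"private": 1.0, "project": 0.0,
                          "targeted_project": 0.0, "redlist": 0.0},
            rng_seed=1)
        frame = syn.generate_landscape(cfg)
        raw = syn.generate_driver_trajectories(cfg)
        dt, _ = syn.derive_driver_table(raw, cfg)
        species = syn.generate_species(cfg)
        truth = syn.simulate_occupancy_dynamics(frame, dt, species, cfg)
        out = syn.simulate_visits_and_records(truth, frame, cfg)
        rec = out["records"]
        sq_index = {s: i for i, s in enumerate(frame["square_id"])}
        rec["year"] = pd.to_datetime(rec["date"]).dt.year
        for si, sp in enumerate(species["species_id"]):
            got = {(sq_index[r.square_id], r.year - cfg.start_year)
                   for r in rec[rec["species_id"] == sp].itertuples()}
            # every visited occupied square-year appears; no false positives
            for (i, t) in got:
                assert truth.z[si, i, t]

    def test_lower_detection_intercept_fewer_records(self):
        kw = dict(n_squares_per_zone=6, n_zones=9, n_years=6,
                  n_species_per_group=(2, 1, 1), rng_seed=7)
        cfg_hi = syn.SimulationConfig(det_intercept=0.5, **kw)
        cfg_lo = syn.SimulationConfig(det_intercept=-1.5, **kw)
        frame = syn.generate_landscape(cfg_hi)
        raw = syn.generate_driver_trajectories(cfg_hi)
        dt, _ = syn.derive_driver_table(raw, cfg_hi)
        species = syn.generate_species(cfg_hi)
        truth = syn.simulate_occupancy_dynamics(frame, dt, species, cfg_hi)
        n_hi = len(syn.simulate_visits_and_records(truth, frame, cfg_hi)["records"])
        n_lo = len(syn.simulate_visits_and_records(truth, frame, cfg_lo)["records"])
        assert n_lo < n_hi

    def test_naive_occupancy_below_truth_under_imperfect_detection(self, demo_world):
        truth, frame, cfg = (demo_world["truth"], demo_world["frame"],
                             demo_world["config"])
        rec = demo_world["records"]
        rec = rec.assign(year=pd.to_datetime(rec["date"]).dt.year)
        sq_index = {s: i for i, s in enumerate(frame["square_id"])}
        # naive occupancy over all squares vs true mean z, per species
        below = 0
        species = truth.species["species_id"].tolist()
        for si, sp in enumerate(species):
            sp_rec = rec[rec["species_id"] == sp]
            occ_pairs = {(sq_index[s], y - cfg.start_year)
                         for s, y in zip(sp_rec["square_id"], sp_rec["year"])}
            naive = len(occ_pairs) / (truth.z.shape[1] * truth.z.shape[2])
            below += int(naive <= truth.z[si].mean())
        assert below >= 0.9 * len(species)

    def test_record_determinism(self, demo_world):
        out = syn.simulate_visits_and_records(demo_world["truth"],
                                              demo_world["frame"],
                                              demo_world["config"])
        pd.testing.assert_frame_equal(out["records"], demo_world["records"])

    def test_expert_tail_exists(self, demo_world):
        rec = demo_world["records"]
        private = rec[rec["observer_id"].notna()]
        counts = private.groupby("observer_id").size().sort_values()
        # heavy-tailed activity: the top observer dominates
        assert counts.iloc[-1] > 10 * counts.iloc[0]
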