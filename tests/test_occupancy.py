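import numpy as np
import pandas as pd
import pytest

import helpers_sim as hs
from occutrend.occupancy import (
    DEFAULT_PRIORS, OccupancyDesign, OccupancyModel, OccupancyParams,
    OccupancyPosterior, check_convergence, derive_mean_occupancy, marginal_loglik,
)


def _simple_design(visits_y, n_years=1):
    sites = pd.DataFrame({"square_id": ["a"], "elevation_scaled": [0.0],
                          "region": ["r1"], "zone": ["z1"]})
    visits = pd.DataFrame({
        "square_id": "a", "year": 2000, "y": visits_y, "yday_scaled": 0.0,
        "shortlist": 0, "longlist": 0, "expert": 0, "project": 0,
        "targeted_project": 0, "redlist": 0})
    return OccupancyDesign("sp", sites, visits, np.arange(2000, 2000 + n_years))


def _flat_params(design, mu_o=0.0, mu_d=0.0):
    p = OccupancyParams.zeros(len(design.regions), design.n_sites,
                              len(design.zones), design.n_years)
    p.mu_o, p.mu_d = mu_o, mu_d
    return p


class TestMarginalLoglik:
    def test_no_detection_two_visits(self):
        # psi=0.5, p=0.5, y=(0,0): 0.5*0.25 + 0.5 = 0.625
        d = _simple_design([0, 0])
        assert marginal_loglik(d, _flat_params(d)) == pytest.approx(np.log(0.625), abs=1e-12)

    def test_one_detection(self):
        # psi=0.5, p=0.5, y=(1,0): 0.5*0.25 = 0.125
        d = _simple_design([1, 0])
        assert marginal_loglik(d, _flat_params(d)) == pytest.approx(np.log(0.125), abs=1e-12)

    def test_matches_enumeration_oracle(self, rng):
        worst = 0.0
        for _ in range(100):
            design, params = hs.random_tiny_instance(rng)
            delta = abs(marginal_loglik(design, params)
                        - hs.enumeration_loglik(design, params))
            worst = max(worst, delta)
        assert worst < 1e-12

    def test_permuting_visits_leaves_likelihood_unchanged(self, rng):
        design, params = hs.random_tiny_instance(rng)
        base = marginal_loglik(design, params)
        perm = design.visits.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled = OccupancyDesign("tiny", design.sites, perm[hs.VISIT_COLS],
                                   design.years)
        assert marginal_loglik(shuffled, params) == pytest.approx(base, abs=1e-10)

    def test_nonfinite_linear_predictor_located(self):
        d = _simple_design([0, 0])
        p = _flat_params(d, mu_o=np.inf)
        with pytest.raises(FloatingPointError, match="occupancy"):
            marginal_loglik(d, p)


class TestDerivedOccupancy:
    def _posterior_stub(self, design, mu_o):
        draws = {k: np.zeros((1, 1)) for k in
                 ["mu_o", "beta_o1", "beta_o2"]}
        draws["mu_o"][:] = mu_o
        draws["alpha_o1"] = np.zeros((1, 1, len(design.regions)))
        draws["alpha_o2"] = np.zeros((1, 1, design.n_sites))
        draws["gamma"] = np.zeros((1, 1, len(design.zones), design.n_years))
        return draws

    def test_all_psi_one(self):
        d, _, _ = hs.constant_prob_dataset(np.random.default_rng(0), 8, 2, 1)
        zone, cty = derive_mean_occupancy(self._posterior_stub(d, 50.0), d)
        assert np.allclose(zone, 1.0) and np.allclose(cty, 1.0)

    def test_country_weighting_with_absent_zones(self):
        # psi=1 in one zone holding 25% of squares; species absent elsewhere
        sites = pd.DataFrame({
            "square_id": [f"s{i}" for i in range(4)],
            "elevation_scaled": 0.0,
            "region": "r1",
            "zone": ["z1", "z2", "z3", "z4"],
        })
        visits = pd.DataFrame({
            "square_id": ["s0"], "year": [2000], "y": [1], "yday_scaled": [0.0],
            "shortlist": [0], "longlist": [0], "expert": [0], "project": [0],
            "targeted_project": [0], "redlist": [0]})
        d = OccupancyDesign("sp", sites, visits, np.array([2000]))
        assert d.zone_has_record.tolist() == [True, False, False, False]
        zone, cty = derive_mean_occupancy(self._posterior_stub(d, 50.0), d)
        assert cty[0, 0, 0] == pytest.approx(0.25)

    def test_two_zone_hand_computation(self):
        # zone z1: sites with psi = expit(1), expit(1); zone z2: expit(1+2) x2
        sites = pd.DataFrame({
            "square_id": ["a", "b", "c", "d"],
            "elevation_scaled": 0.0, "region": "r1",
            "zone": ["z1", "z1", "z2", "z2"]})
        visits = pd.DataFrame({
            "square_id": ["a", "c"], "year": [2000, 2000], "y": [1, 1],
            "yday_scaled": 0.0, "shortlist": 0, "longlist": 0, "expert": 0,
            "project": 0, "targeted_project": 0, "redlist": 0})
        d = OccupancyDesign("sp", sites, visits, np.array([2000]))
        draws = self._posterior_stub(d, 1.0)
        draws["gamma"][0, 0, 1, 0] = 2.0  # zone z2 year effect
        zone, cty = derive_mean_occupancy(draws, d)
        e1 = 1 / (1 + np.exp(-1.0))
        e2 = 1 / (1 + np.exp(-3.0))
        assert zone[0, 0, 0, 0] == pytest.approx(e1, abs=1e-12)
        assert zone[0, 0, 1, 0] == pytest.approx(e2, abs=1e-12)
        assert cty[0, 0, 0] == pytest.approx(0.5 * e1 + 0.5 * e2, abs=1e-12)


class TestConvergenceDiagnostics:
    def _posterior(self, zone_occ, country_occ):
        C, D, Z, T = zone_occ.shape
        return OccupancyPosterior(
            species_id="x", draws={}, zones=[f"z{i}" for i in range(Z)],
            years=np.arange(T), analysis_years=np.arange(T),
            zone_occ=zone_occ, country_occ=country_occ,
            zone_has_record=np.ones(Z, bool), n_squares_per_zone=np.ones(Z, int))

    def test_identical_chains_rhat_near_one(self, rng):
        base = rng.uniform(0.2, 0.8, (1, 400, 2, 3))
        zone = np.concatenate([base, base + rng.normal(0, 1e-3, base.shape)], axis=0)
        cty = zone.mean(axis=2)
        out = check_convergence(self._posterior(zone, cty))
        assert out["available"]
        assert out["max_rhat"] < 1.05

    def test_shifted_chains_flagged(self, rng):
        a = rng.normal(0.3, 0.01, (1, 400, 1, 2))
        b = rng.normal(0.7, 0.01, (1, 400, 1, 2))
        zone = np.concatenate([a, b], axis=0)
        out = check_convergence(self._posterior(zone, zone.mean(axis=2)))
        assert out["max_rhat"] > 1.1
        assert out["fraction_below_threshold"] < 1.0

    def test_single_chain_unavailable(self, rng):
        zone = rng.uniform(size=(1, 100, 1, 2))
        out = check_convergence(self._posterior(zone, zone.mean(axis=2)))
        assert out["available"] is False


class TestFitting:
    def test_seed_determinism(self, rng):
        d, _, _ = hs.constant_prob_dataset(rng, n_squares=20, n_years=3, n_visits=2)
        m1 = OccupancyModel(chains=2, n_iter=60, warmup=60, thin=2, seed=9).fit(d)
        m2 = OccupancyModel(chains=2, n_iter=60, warmup=60, thin=2, seed=9).fit(d)
        for k in m1.posterior_.draws:
            assert np.array_equal(m1.posterior_.draws[k], m2.posterior_.draws[k])
        assert np.array_equal(m1.posterior_.country_occ, m2.posterior_.country_occ)

    def test_degenerate_designs_rejected(self, rng):
        d, _, _ = hs.constant_prob_dataset(rng, n_squares=5, n_years=1)
        with pytest.raises(ValueError, match="years"):
            OccupancyModel().fit(d)
        d2, _, _ = hs.constant_prob_dataset(rng, n_squares=5, n_years=3, psi=0.0)
        with pytest.raises(ValueError, match="detection"):
            OccupancyModel().fit(d2)

    def test_all_detected_drives_occupancy_to_one(self, rng):
        d, _, _ = hs.constant_prob_dataset(rng, n_squares=30, n_years=3,
                                           n_visits=3, psi=1.0, p=1.0)
        m = OccupancyModel(chains=2, n_iter=150, warmup=150, thin=2, seed=4).fit(d)
        assert m.posterior_.country_occ_flat().mean() > 0.95

    def test_posterior_stable_under_visit_permutation(self, rng):
        d, _, _ = hs.constant_prob_dataset(rng, n_squares=30, n_years=4, n_visits=2)
        perm = d.visits[hs.VISIT_COLS].sample(frac=1.0, random_state=3).reset_index(drop=True)
        d2 = OccupancyDesign("const", d.sites, perm, d.years)
        m1 = OccupancyModel(chains=2, n_iter=200, warmup=200, thin=2, seed=11).fit(d)
        m2 = OccupancyModel(chains=2, n_iter=200, warmup=200, thin=2, seed=11).fit(d2)
        a = m1.posterior_.country_occ_flat().mean()
        b = m2.posterior_.country_occ_flat().mean()
        assert a == pytest.approx(b, abs=0.03)


class TestCalibration:
    def test_nominal_coverage_of_occupancy_intercept(self):
        """Simulation-based calibration of the reduced (single-zone) model:
        central 90% intervals for the occupancy intercept should cover the
        prior-drawn truth in about 90% of replicates."""
        rng = np.random.default_rng(2024)
        n_rep = 100
        S, T, J = 15, 2, 2
        sites = pd.DataFrame({"square_id": [f"s{i}" for i in range(S)],
                              "elevation_scaled": 0.0, "region": "r1",
                              "zone": "z1"})
        covered = []
        for _ in range(n_rep):
            mu_o = rng.normal(0, DEFAULT_PRIORS["intercept_sd"])
            mu_d = rng.normal(0, DEFAULT_PRIORS["intercept_sd"])
            s_sq = abs(rng.normal(0, 1.0))
            s_dy = abs(rng.normal(0, 1.0))
            sq = rng.normal(0, s_sq, S)
            g1 = rng.normal(0, DEFAULT_PRIORS["gamma_first_sd"])
            sg = abs(rng.standard_cauchy())
            gam = np.array([g1, rng.normal(g1, sg)])
            ady = rng.normal(0, s_dy, T)
            rows = []
            for i in range(S):
                for t in range(T):
                    pz = 1 / (1 + np.exp(-(mu_o + sq[i] + gam[t])))
                    zi = rng.uniform() < pz
                    p_det = 1 / (1 + np.exp(-(mu_d + ady[t])))
                    for _j in range(J):
                        y = int(zi and (rng.uniform() < p_det))
                        rows.append({"square_id": f"s{i}", "year": 2000 + t, "y": y,
                                     "yday_scaled": 0.0, "shortlist": 0,
                                     "longlist": 0, "expert": 0, "project": 0,
                                     "targeted_project": 0, "redlist": 0})
            visits = pd.DataFrame(rows)
            if visits["y"].sum() == 0:
                continue  # not fittable; excluded from the coverage tally
            d = OccupancyDesign("sbc", sites, visits, np.array([2000, 2001]))
            m = OccupancyModel(chains=1, n_iter=200, warmup=200, thin=1,
                               seed=int(rng.integers(2 ** 31))).fit(d)
            draws = m.posterior_.draws["mu_o"].ravel()
            lo, hi = np.quantile(draws, [0.05, 0.95])
            covered.append(int(lo <= mu_o <= hi))
        assert len(covered) >= 80
        assert 0.78 <= np.mean(covered) <= 0.99
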