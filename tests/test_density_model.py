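"""Piecewise density: evaluation, mode detection, fitting, serialization."""

import numpy as np
import pytest
from scipy import integrate, stats

from contactprefs import density_model as dm
from contactprefs import synthetic_data as sd


def one_component_density():
    az = [
        dm.AzimuthalComponent(0.0, np.pi, 0.7, 2.0, 0.2),
        dm.AzimuthalComponent(np.pi, 2 * np.pi, 0.3, 4.5, 0.4),
    ]
    comp = dm.PolarComponent(0.0, np.pi, 1.0, 0.7, 8.0, 2.9, 0.05, azimuthal=az)
    return dm.PiecewiseDensity("f2", "C14", 4.0, [comp])


class TestEvalDensity:
    def test_zero_outside_support(self):
        d = one_component_density()
        assert dm.eval_density(d, (4.1, 0.5, 1.0)) == 0.0

    def test_value_is_product_of_independent_1d_factors(self):
        """Independent 1D truncated densities (scipy quad / truncnorm) agree
        with the assembled 3D evaluation at a chosen point."""
        d = one_component_density()
        comp = d.components[0]
        point = (2.7, 0.9, 1.5)

        vm_unnorm = lambda x: np.exp(comp.kappa * np.cos(x - comp.mu_theta))
        z, _ = integrate.quad(vm_unnorm, 0, np.pi)
        f_theta = vm_unnorm(point[1]) / z

        sd_r = np.sqrt(comp.var_r)
        a, b = (0 - comp.mu_r) / sd_r, (d.r_max - comp.mu_r) / sd_r
        f_r = stats.truncnorm.pdf(point[0], a, b, loc=comp.mu_r, scale=sd_r)

        az = comp.azimuthal[0]  # phi = 1.5 is in [0, pi)
        sd_p = np.sqrt(az.var_phi)
        a, b = (az.phi_lo - az.mu_phi) / sd_p, (az.phi_hi - az.mu_phi) / sd_p
        f_phi = az.weight * stats.truncnorm.pdf(point[2], a, b, loc=az.mu_phi, scale=sd_p)

        assert np.isclose(dm.eval_density(d, point), f_theta * f_r * f_phi, rtol=1e-9)

    def test_mode_is_maximal_on_grid(self):
        d = one_component_density()
        comp = d.components[0]
        mode = (comp.mu_r, comp.mu_theta, comp.azimuthal[0].mu_phi)
        peak = dm.eval_density(d, mode)
        rr = np.linspace(0.05, 3.95, 20)
        tt = np.linspace(0.05, np.pi - 0.05, 20)
        pp = np.linspace(0.05, np.pi - 0.05, 20)  # stay in the peak's sub-interval
        grid = np.array(np.meshgrid(rr, tt, pp, indexing="ij")).reshape(3, -1).T
        assert peak >= dm.eval_density_many(d, grid).max()

    def test_no_negative_density_across_boundaries(self, rng):
        d = sd.gen_random_density(rng)
        pts = np.column_stack([
            rng.uniform(0, d.r_max, 500),
            rng.uniform(0, np.pi, 500),
            rng.uniform(0, 2 * np.pi, 500),
        ])
        assert (dm.eval_density_many(d, pts) >= 0).all()


class TestLogLikelihood:
    def test_single_point(self):
        d = one_component_density()
        p = np.array([[2.8, 0.7, 1.9]])
        assert np.isclose(dm.log_likelihood(d, p), np.log(dm.eval_density(d, p[0])))

    def test_duplication_doubles(self, rng):
        d = one_component_density()
        pts = np.column_stack([
            rng.uniform(1, 3.9, 20), rng.uniform(0.1, 3.0, 20), rng.uniform(0.1, 6.0, 20)
        ])
        assert np.isclose(dm.log_likelihood(d, np.vstack([pts, pts])),
                          2 * dm.log_likelihood(d, pts))

    def test_matches_brute_force_product(self, rng):
        d = one_component_density()
        pts = np.column_stack([
            rng.uniform(1, 3.9, 50), rng.uniform(0.1, 3.0, 50), rng.uniform(0.1, 6.0, 50)
        ])
        brute = float(np.sum([np.log(dm.eval_density(d, p)) for p in pts]))
        assert np.isclose(dm.log_likelihood(d, pts), brute, rtol=1e-12)

    def test_empty_cloud_raises(self):
        with pytest.raises(ValueError):
            dm.log_likelihood(one_component_density(), np.empty((0, 3)))

    def test_zero_density_record_gives_neg_inf(self):
        d = one_component_density()
        with pytest.warns(UserWarning):
            assert dm.log_likelihood(d, np.array([[5.0, 0.5, 1.0]])) == -np.inf

    def test_mode_beats_tail(self):
        """Adding a point at the mode raises mean log-likelihood more than
        adding one far in the tail."""
        d = one_component_density()
        comp = d.components[0]
        base = np.array([[2.9, 0.7, 2.0]])
        at_mode = np.vstack([base, [(comp.mu_r, comp.mu_theta, comp.azimuthal[0].mu_phi)]])
        in_tail = np.vstack([base, [(0.3, 3.0, 0.1)]])
        assert dm.log_likelihood(d, at_mode) / 2 >= dm.log_likelihood(d, in_tail) / 2


class TestDetectModes:
    def test_single_von_mises(self, rng):
        x = np.mod(rng.vonmises(1.5, 10.0, size=500), 2 * np.pi)
        n, cuts = dm.detect_modes(x, domain=(0, 2 * np.pi))
        assert n == 1 and len(cuts) == 0

    def test_two_von_mises(self, rng):
        x = np.concatenate([
            rng.vonmises(0.5, 20.0, size=250), rng.vonmises(2.5, 20.0, size=250)
        ])
        x = np.mod(x, 2 * np.pi)
        n, cuts = dm.detect_modes(x, domain=(0, np.pi), max_modes=4)
        assert n == 2
        assert 0.5 < cuts[0] < 2.5

    def test_uniform_clamped(self, rng):
        x = rng.uniform(0, np.pi, 500)
        n, _ = dm.detect_modes(x, max_modes=4)
        assert 1 <= n <= 4

    def test_few_samples_fallback(self):
        n, cuts = dm.detect_modes(np.array([0.1, 0.2, 0.3]))
        assert n == 1 and len(cuts) == 0


class TestMlEstimates:
    def test_one_component_recovery(self, one_comp_spec):
        truth = one_comp_spec.components[0]
        d = dm.ml_estimates(sd.gen_cloud(one_comp_spec))
        assert len(d.components) == 1
        c = d.components[0]
        assert abs(c.mu_theta - truth.mu_theta) < np.deg2rad(2)
        assert abs(c.kappa - truth.kappa) / truth.kappa < 0.15
        assert abs(c.mu_r - truth.mu_r) < 0.05

    def test_two_component_recovery(self, two_comp_spec):
        d = dm.ml_estimates(sd.gen_cloud(two_comp_spec))
        assert len(d.components) == 2
        for c, truth in zip(sorted(d.components, key=lambda c: c.theta_lo),
                            two_comp_spec.components):
            assert abs(c.mu_theta - truth.mu_theta) < np.deg2rad(2)
            assert abs(c.kappa - truth.kappa) / truth.kappa < 0.15
            assert abs(c.mu_r - truth.mu_r) < 0.05
            assert abs(c.weight - truth.weight) < 0.05

    def test_degenerate_point_mass(self):
        pts = np.tile([[2.5, 1.0, 3.0]], (50, 1))
        d = dm.ml_estimates(pts, r_max=4.0)
        c = d.components[0]
        assert c.var_r == dm.VAR_FLOOR
        assert c.kappa == dm.KAPPA_CAP

    def test_weights_sum_to_one(self, two_comp_spec):
        d = dm.ml_estimates(sd.gen_cloud(two_comp_spec))
        assert np.isclose(sum(c.weight for c in d.components), 1.0, atol=1e-12)

    def test_sparse_interval_merged(self, one_comp_spec):
        """A partition cut with almost no samples beyond it collapses."""
        cloud = sd.gen_cloud(one_comp_spec)
        d = dm.ml_estimates(cloud, partition=[3.1])
        assert len(d.components) == 1
        d.validate()


class TestSerialization:
    def test_json_round_trip(self, rng):
        d = sd.gen_random_density(rng)
        d2 = dm.PiecewiseDensity.from_json(d.to_json())
        assert d2.to_dict() == d.to_dict()


class TestEstimator:
    def test_sklearn_interface(self, one_comp_spec):
        from sklearn.base import clone

        X = sd.gen_cloud(one_comp_spec).to_array()
        est = dm.PiecewiseDensityEstimator(max_modes=3)
        assert clone(est).get_params()["max_modes"] == 3
        est.fit(X)
        assert est.density_.n_train == len(X)
        logp = est.score_samples(X[:10])
        assert np.isfinite(logp).all()
        assert np.isclose(est.score(X[:10]), logp.sum())

    def test_input_validation(self):
        est = dm.PiecewiseDensityEstimator()
        with pytest.raises(ValueError):
            est.fit(np.ones((5, 2)))
        with pytest.raises(ValueError):
            est.fit(np.array([[-1.0, 0.5, 0.5]] * 5))
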