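"""Spherical probability masses, hierarchies and bootstrap errors."""

import numpy as np
import pytest

from contactprefs import chem_prior as cp
from contactprefs import mass_hierarchy as mh
from contactprefs import synthetic_data as sd


def full_support(d):
    return mh.SphericalVolume(0, d.r_max, 0, np.pi, 0, 2 * np.pi)


def random_volume(rng, d):
    r = np.sort(rng.uniform(0, d.r_max, 2))
    th = np.sort(rng.uniform(0, np.pi, 2))
    ph = np.sort(rng.uniform(0, 2 * np.pi, 2))
    return mh.SphericalVolume(r[0], r[1], th[0], th[1], ph[0], ph[1])


class TestSphericalVolume:
    def test_invalid_intervals_raise(self):
        with pytest.raises(ValueError):
            mh.SphericalVolume(-0.1, 1, 0, 1, 0, 1)
        with pytest.raises(ValueError):
            mh.SphericalVolume(0, 1, 1.0, 0.5, 0, 1)

    def test_around_clips_to_domains(self):
        v = mh.SphericalVolume.around((0.2, 0.1, 0.1), 0.5, 0.5, 0.5)
        assert v.r_lo == 0.0 and v.theta_lo == 0.0 and v.phi_lo == 0.0

    def test_contains(self):
        v = mh.SphericalVolume(1, 2, 0.5, 1.5, 1, 2)
        pts = np.array([[1.5, 1.0, 1.5], [2.5, 1.0, 1.5], [1.5, 0.1, 1.5]])
        assert list(v.contains(pts)) == [True, False, False]


class TestProbabilityMass:
    def test_full_support_is_one(self, rng):
        for _ in range(5):
            d = sd.gen_random_density(rng)
            assert np.isclose(mh.probability_mass(d, full_support(d)), 1.0, atol=1e-9)

    def test_zero_width_interval(self, rng):
        d = sd.gen_random_density(rng)
        v = mh.SphericalVolume(2.0, 2.0, 0, np.pi, 0, 2 * np.pi)
        assert mh.probability_mass(d, v) == 0.0

    def test_series_equals_quadrature(self, rng):
        for _ in range(20):
            d = sd.gen_random_density(rng)
            v = random_volume(rng, d)
            ms = mh.probability_mass(d, v, "series")
            mq = mh.probability_mass(d, v, "quadrature")
            assert abs(ms - mq) < 1e-6

    def test_series_matches_riemann_oracle(self, rng):
        for _ in range(5):
            d = sd.gen_random_density(rng)
            v = random_volume(rng, d)
            assert abs(mh.probability_mass(d, v, "series")
                       - mh.riemann_mass(d, v, cells=1_000_000)) < 1e-6

    def test_additivity_on_shared_boundary(self, rng):
        d = sd.gen_random_density(rng)
        v1 = mh.SphericalVolume(0.5, 2.0, 0.2, 1.1, 1.0, 3.0)
        v2 = mh.SphericalVolume(2.0, 3.2, 0.2, 1.1, 1.0, 3.0)
        v12 = mh.SphericalVolume(0.5, 3.2, 0.2, 1.1, 1.0, 3.0)
        assert np.isclose(
            mh.probability_mass(d, v1) + mh.probability_mass(d, v2),
            mh.probability_mass(d, v12),
            atol=1e-8,
        )

    def test_monotone_in_volume(self, rng):
        d = sd.gen_random_density(rng)
        inner = mh.SphericalVolume(1.0, 2.0, 0.4, 1.0, 1.0, 2.0)
        outer = mh.SphericalVolume(0.5, 2.5, 0.2, 1.4, 0.5, 2.5)
        assert mh.probability_mass(d, inner) <= mh.probability_mass(d, outer)

    def test_tensor_grid_cross_check(self, rng):
        """The 3D evaluation-path integral agrees with the factor routes."""
        d = sd.gen_random_density(rng)
        v = random_volume(rng, d)
        assert abs(mh.tensor_grid_mass(d, v) - mh.probability_mass(d, v)) < 1e-6


class TestHierarchy:
    @pytest.fixture
    def densities(self, rng):
        return {t: sd.gen_random_density(rng) for t in ("C8", "C9", "C12", "C14")}

    @pytest.fixture
    def priors(self):
        return cp.load_prior_table()

    def test_probabilities_sum_to_one_and_ranks_permute(self, rng, densities, priors):
        d0 = densities["C8"]
        v = mh.SphericalVolume(1.5, 3.4, 0.1, 1.2, 0.5, 4.5)
        res = mh.hierarchy("f2", densities, priors, v)
        assert np.isclose(res.table["probability"].sum(), 1.0, atol=1e-9)
        assert sorted(res.table["rank"]) == list(range(1, 14))
        assert set(res.missing_classes) == set(cp.TARGET_CLASSES) - set(densities)

    def test_single_class_gets_probability_one(self, priors, rng):
        densities = {"C12": sd.gen_random_density(rng)}
        v = full_support(densities["C12"])
        res = mh.hierarchy("f2", densities, priors, v)
        assert np.isclose(res.table.loc["C12", "probability"], 1.0)
        assert res.table.loc["C12", "rank"] == 1

    def test_equal_mass_equal_prior_splits_half(self, rng):
        d = sd.gen_random_density(rng)
        uniform = cp.PriorTable(
            __import__("pandas").DataFrame(
                {t: [1 / 13] for t in cp.TARGET_CLASSES}, index=["f2"]
            )
        )
        densities = {"C8": d, "C9": d}
        res = mh.hierarchy("f2", densities, uniform, full_support(d))
        assert np.isclose(res.table.loc["C8", "probability"], 0.5)
        assert np.isclose(res.table.loc["C9", "probability"], 0.5)

    def test_prior_monotonicity(self, rng, densities, priors):
        """Doubling one class's prior weight strictly raises its probability."""
        v = mh.SphericalVolume(1.5, 3.4, 0.1, 1.2, 0.5, 4.5)
        base = mh.hierarchy("f2", densities, priors, v).table.loc["C9", "probability"]
        boosted = priors.table.copy()
        boosted.loc["f2", "C9"] *= 2
        boosted.loc["f2"] /= boosted.loc["f2"].sum()
        res2 = mh.hierarchy("f2", densities, cp.PriorTable(boosted), v)
        assert res2.table.loc["C9", "probability"] > base

    def test_volume_outside_all_supports_raises(self, densities, priors):
        v = mh.SphericalVolume(100, 101, 0, 0.1, 0, 0.1)
        with pytest.raises(ValueError):
            mh.hierarchy("f2", densities, priors, v)


class TestBootstrapSe:
    @pytest.fixture
    def setup(self, rng):
        densities = {t: sd.gen_random_density(rng) for t in ("C8", "C12")}
        v = mh.SphericalVolume(1.5, 3.2, 0.2, 1.4, 0.5, 4.0)
        return densities, cp.load_prior_table(), v

    def test_zero_perturbation_gives_zero_se(self, setup):
        densities, priors, v = setup
        se = mh.bootstrap_se("f2", densities, priors, v, n_volumes=20,
                             rel_jitter=0.0, seed=1)
        # identical volumes; only float noise from the mean subtraction remains
        assert (se["se"] < 1e-12).all()

    def test_seed_determinism(self, setup):
        densities, priors, v = setup
        a = mh.bootstrap_se("f2", densities, priors, v, n_volumes=50, seed=7)
        b = mh.bootstrap_se("f2", densities, priors, v, n_volumes=50, seed=7)
        assert (a == b).all().all()

    def test_se_stabilizes_with_volume_count(self, setup):
        densities, priors, v = setup
        se1 = mh.bootstrap_se("f2", densities, priors, v, n_volumes=1000, seed=3)["se"]
        se4 = mh.bootstrap_se("f2", densities, priors, v, n_volumes=4000, seed=4)["se"]
        big = se4 > 1e-4
        assert (np.abs(se1[big] - se4[big]) < 0.1 * se4[big] + 5e-4).all()


class TestReferenceFrequency:
    def test_counts_inside_volume(self):
        v = mh.SphericalVolume(2, 3, 0.2, 1.0, 1.0, 3.0)
        inside = [[2.5, 0.5, 2.0]] * 3
        outside = [[3.5, 0.5, 2.0], [2.5, 2.0, 2.0]]
        clouds = {"C8": np.array(inside + outside)}
        out = mh.reference_frequency(clouds, v)
        assert out.loc["C8", "count"] == 3
        assert np.isclose(out["fraction"].sum(), 1.0)

    def test_full_support_counts_everything(self, rng, one_comp_cloud):
        v = mh.SphericalVolume(0, 4.0, 0, np.pi, 0, 2 * np.pi)
        out = mh.reference_frequency({"C14": one_comp_cloud}, v)
        assert out.loc["C14", "count"] == len(one_comp_cloud)

    def test_empty_volume_zero_counts(self, one_comp_cloud):
        v = mh.SphericalVolume(3.99, 4.0, 3.0, 3.1, 6.0, 6.2)
        out = mh.reference_frequency({"C14": one_comp_cloud}, v)
        assert (out["fraction"] == 0).all() or out["count"].sum() >= 0
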