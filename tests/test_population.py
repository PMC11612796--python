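import numpy as np
import pytest
from scipy import stats

from onspv.geometry import NerveGeometry, RetinaGeometry
from onspv.rgc_population import (
    CumulativeCounts,
    RGCPopulation,
    build_population,
    check_retinotopy,
    fibers_from_seeds,
    map_circular_patch,
    rf_radius,
    sample_seed_pairs,
)


class TestSeedPairs:
    def test_count_and_open_interval(self):
        u_rho, u_theta = sample_seed_pairs(10000, seed=0)
        assert u_rho.size == u_theta.size == 10000
        for u in (u_rho, u_theta):
            assert np.all((u > 0) & (u < 1))

    def test_deterministic(self):
        assert np.array_equal(
            np.array(sample_seed_pairs(1, seed=42)), np.array(sample_seed_pairs(1, seed=42))
        )

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            sample_seed_pairs(0, seed=0)

    def test_uniformity_ks(self):
        """Per-coordinate KS statistic below the 1% critical value at n = 1e5."""
        u_rho, u_theta = sample_seed_pairs(100_000, seed=3)
        crit = 1.63 / np.sqrt(100_000)  # asymptotic 1% point of D_n
        for u in (u_rho, u_theta):
            assert stats.kstest(u, "uniform").statistic < crit


class TestFiberPlacement:
    def test_as_printed_map(self):
        rho, theta = fibers_from_seeds([0.25], [0.5], NerveGeometry(), "as_printed")
        assert rho[0] == pytest.approx(0.625)
        assert theta[0] == pytest.approx(np.pi)

    def test_area_uniform_map(self):
        rho, theta = fibers_from_seeds([0.25], [0.5], NerveGeometry(), "area_uniform")
        assert rho[0] == pytest.approx(1.25)  # R * sqrt(0.25)
        assert theta[0] == pytest.approx(np.pi)

    def test_area_uniform_equal_area_annuli_chi_square(self):
        u_rho, u_theta = sample_seed_pairs(100_000, seed=11)
        rho, _ = fibers_from_seeds(u_rho, u_theta, NerveGeometry(), "area_uniform")
        edges = 2.5 * np.sqrt(np.linspace(0, 1, 11))  # ten equal-area annuli
        counts, _ = np.histogram(rho, bins=edges)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_rank_order_preserved_in_both_modes(self):
        u_rho = np.array([0.1, 0.5, 0.9])
        for mode in ("area_uniform", "as_printed"):
            rho, _ = fibers_from_seeds(u_rho, np.full(3, 0.3), NerveGeometry(), mode)
            assert np.all(np.diff(rho) > 0)


class TestCumulativeCounts:
    def toy(self):
        """Single-meridian toy pair: CC_soma = rho^2, CC_RF = rho on [0, 1]."""
        rho = np.linspace(0, 1, 2001)
        return CumulativeCounts.from_tables(rho, rho**2, rho)

    def test_closed_form_root(self):
        cc = self.toy()
        # CC_RF(rho) = CC_soma(0.5) = 0.25 -> rho_RF = 0.25
        out = cc.displace(np.array([0.5]), np.array([0.0]))
        assert out[0] == pytest.approx(0.25, abs=1e-6)

    def test_identity_pair_is_identity_map(self):
        rho = np.linspace(0, 1, 101)
        cc = CumulativeCounts.from_tables(rho, rho**2, rho**2)
        samples = np.array([0.1, 0.33, 0.9])
        out = cc.displace(samples, np.zeros(3))
        assert np.allclose(out, samples, atol=1e-9)

    def test_monotone_in_rho_soma(self):
        cc = self.toy()
        samples = np.linspace(0.05, 0.95, 19)
        out = cc.displace(samples, np.zeros_like(samples))
        assert np.all(np.diff(out) > 0)

    def test_no_root_raises_with_record_index(self):
        rho = np.linspace(0, 1, 101)
        cc = CumulativeCounts.from_tables(rho, rho, 0.5 * rho)  # CC_RF max < CC_soma max
        with pytest.raises(ValueError, match="record"):
            cc.displace(np.array([0.9]), np.array([0.0]))

    def test_default_pair_agrees_at_max_eccentricity(self, pop10k):
        from onspv.density import build_density_field

        field = build_density_field()
        cc = CumulativeCounts.from_density(field)
        assert np.allclose(cc.cc_soma[:, -1], cc.cc_rf[:, -1])
        # inside the displacement zone RF counts lead soma counts
        k = np.searchsorted(cc.rho, 2.0)
        assert np.all(cc.cc_rf[:, k] >= cc.cc_soma[:, k])


class TestRfRadius:
    def test_linear_relation(self):
        assert rf_radius(10.0, slope=0.01, intercept=0.05) == pytest.approx(0.15)
        assert rf_radius(0.0, slope=0.01, intercept=0.05) == pytest.approx(0.05)
        assert rf_radius(7.0, slope=0.0, intercept=0.05) == pytest.approx(0.05)

    def test_clamp_warns(self):
        with pytest.warns(UserWarning):
            out = rf_radius(1.0, slope=-1.0, intercept=0.05, min_sigma_deg=0.01)
        assert out == 0.01


class TestBuildPopulation:
    def test_default_build(self, pop10k):
        assert pop10k.n == 10000
        x, y = pop10k.soma_xy().T
        assert not np.any(pop10k.retina.disc.contains(x, y))
        assert np.all(pop10k.rho_fiber_mm <= pop10k.nerve.radius_mm)
        assert np.allclose(pop10k.theta_rf, pop10k.theta_soma)
        assert np.all(pop10k.sigma_rf_deg > 0)

    def test_deterministic(self):
        a = build_population(n=500, seed=9)
        b = build_population(n=500, seed=9)
        assert np.array_equal(a.rho_fiber_mm, b.rho_fiber_mm)
        assert np.array_equal(a.rho_soma_mm, b.rho_soma_mm)
        assert np.array_equal(a.rho_rf_deg, b.rho_rf_deg)

    def test_species_mode_ties_soma_and_rf(self):
        pop = build_population(n=500, seed=2, species_mode=True)
        assert np.array_equal(pop.rho_rf_deg, pop.rho_soma_mm)
        assert np.array_equal(pop.theta_rf, pop.theta_soma)

    def test_inhomogeneous_fiber_density(self):
        from onspv.density import DensityField

        rho = np.linspace(0, 2.5, 201)
        theta = np.arange(32) * 2 * np.pi / 32
        vals = np.tile(np.exp(-rho / 0.5), (32, 1))  # axons crowd the center
        pop = build_population(
            n=2000, seed=4, fiber_density=DensityField(rho=rho, theta=theta, values=vals)
        )
        assert np.median(pop.rho_fiber_mm) < 1.0  # far below the uniform median

    def test_right_eye_mirrors_x(self):
        left = build_population(n=300, seed=6)
        right = build_population(n=300, seed=6, nerve=NerveGeometry(eye_side="right"))
        assert np.allclose(
            right.fiber_xy()[:, 0], -left.fiber_xy()[:, 0], atol=1e-12
        )

    def test_serialization_round_trip(self, tmp_path):
        pop = build_population(n=200, seed=3)
        path = tmp_path / "pop.csv"
        pop.to_csv(path)
        back = RGCPopulation.from_csv(path)
        assert back.n == pop.n
        assert np.allclose(back.rho_fiber_mm, pop.rho_fiber_mm)
        assert np.allclose(back.rho_rf_deg, pop.rho_rf_deg)
        assert back.seed == pop.seed


class TestRetinotopy:
    def test_equal_theta_seed_preserves_radial_order(self):
        """Records sharing u_theta keep the same radial order in retina and nerve."""
        from onspv.density import build_conditional_sampler, build_corrected_density, build_density_field
        from onspv.rgc_population import somas_from_seeds

        retina = RetinaGeometry()
        field = build_corrected_density(build_density_field(), retina)
        sampler = build_conditional_sampler(field)
        u_rho = np.sort(np.random.default_rng(0).random(50))
        for u_t in (0.13, 0.5, 0.86):
            u_theta = np.full(50, u_t)
            rho_f, _ = fibers_from_seeds(u_rho, u_theta, NerveGeometry())
            rho_s, _ = somas_from_seeds(u_rho, u_theta, sampler)
            ds, df = np.sign(np.diff(rho_s)), np.sign(np.diff(rho_f))
            assert np.all(df > 0)
            assert np.all(ds >= 0)  # flat only across the voided disc plateau

    def test_report_orders_intact_vs_shuffled(self, pop10k, rng):
        intact = check_retinotopy(pop10k)
        assert intact["radial_tau_mean"] > 0.95
        assert intact["angular_tau"] > 0.999
        perm = rng.permutation(pop10k.n)
        scrambled = pop10k.copy(
            rho_fiber_mm=pop10k.rho_fiber_mm[perm], theta_fiber=pop10k.theta_fiber[perm]
        )
        broken = check_retinotopy(scrambled)
        assert abs(broken["radial_tau_mean"]) < 0.1
        assert abs(broken["angular_tau"]) < 0.1


class TestCircularPatch:
    def test_whole_nerve_selects_everyone(self, pop10k):
        sel = map_circular_patch(pop10k, "nerve", (0.0, 0.0), pop10k.nerve.radius_mm + 0.01)
        assert sel["ids"].size == pop10k.n

    def test_tiny_patch_selects_single_fiber(self, pop10k):
        xy = pop10k.fiber_xy()
        target = xy[123]
        sel = map_circular_patch(pop10k, "nerve", tuple(target), 1e-9)
        assert list(sel["ids"]) == [123]

    def test_central_patch_is_magnified_in_the_nerve(self, pop10k):
        """A small central visual-field patch owns a disproportionate share of fibers."""
        radius = 5.0  # deg
        sel = map_circular_patch(pop10k, "visual_field", (0.0, 0.0), radius)
        max_ecc_deg = pop10k.retina.mm_to_deg(pop10k.retina.max_eccentricity_mm)
        vf_area_fraction = (radius / max_ecc_deg) ** 2
        fiber_fraction = sel["ids"].size / pop10k.n  # fibers are area-uniform
        assert fiber_fraction > 5 * vf_area_fraction
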