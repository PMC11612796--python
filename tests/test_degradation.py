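import numpy as np
import pytest

from onspv.degradation import (
    DegenerationScenario,
    ShuffleSpec,
    UnitGrid,
    correct_global_shuffle,
    degenerate_fibers,
    disable_sites,
    encapsulation_depletion,
    global_shuffle,
    local_shuffle,
    mean_pairwise_distance,
    stimulate_shuffled,
)
from onspv.electrodes import ElectrodeGrid, StimRule, apply_partition_rule, assign, make_reduced_grid, make_regular_grid
from onspv.encoding import build_rf_stack, encode, reconstruct
from onspv.rgc_population import build_population, check_retinotopy


@pytest.fixture(scope="module")
def pop2k():
    return build_population(n=2000, seed=8)


def test_mean_pairwise_distance_matches_brute_force(rng):
    xy = rng.random((40, 2))
    d = np.linalg.norm(xy[:, None] - xy[None, :], axis=-1)
    brute = d[np.triu_indices(40, 1)].mean()
    assert mean_pairwise_distance(xy, chunk=7) == pytest.approx(brute)


class TestLocalShuffle:
    def test_zero_swaps_is_identity(self, pop2k):
        out = local_shuffle(pop2k, ShuffleSpec(n_swaps=0))
        assert np.array_equal(out.rho_fiber_mm, pop2k.rho_fiber_mm)

    def test_default_swap_count_is_fifth_of_population(self, pop2k):
        out = local_shuffle(pop2k, ShuffleSpec(seed=1))
        assert out.config["local_shuffle"]["n_swaps"] == 400  # 2000 / 5

    def test_is_a_permutation_and_leaves_somas_alone(self, pop2k):
        out = local_shuffle(pop2k, ShuffleSpec(seed=1))
        assert np.allclose(np.sort(out.rho_fiber_mm), np.sort(pop2k.rho_fiber_mm))
        assert np.array_equal(out.rho_soma_mm, pop2k.rho_soma_mm)
        assert np.array_equal(out.rho_rf_deg, pop2k.rho_rf_deg)

    def test_swap_displacements_concentrate_below_three_sigma(self, pop2k):
        sigma = 0.3
        out = local_shuffle(pop2k, ShuffleSpec(sigma_mm=sigma, n_swaps=400, seed=2))
        moved = np.linalg.norm(out.fiber_xy() - pop2k.fiber_xy(), axis=1)
        moved = moved[moved > 0]
        assert np.quantile(moved, 0.95) < 3 * sigma

    def test_degrades_retinotopy_monotonically_in_swaps(self, pop2k):
        taus = []
        for n_swaps in (0, 200, 2000):
            out = local_shuffle(pop2k, ShuffleSpec(n_swaps=n_swaps, seed=3))
            taus.append(check_retinotopy(out)["radial_tau_mean"])
        assert taus[0] > taus[1] > taus[2]

    def test_invalid_sigma(self, pop2k):
        with pytest.raises(ValueError):
            local_shuffle(pop2k, ShuffleSpec(sigma_mm=-1.0))


class TestGlobalShuffle:
    def test_swap_count_is_fifth_of_units(self, pop2k):
        out = global_shuffle(pop2k, seed=0)
        assert out.config["global_shuffle"]["n_swaps"] == 7  # round(36 / 5)

    def test_zero_swaps_is_identity(self, pop2k):
        out = global_shuffle(pop2k, seed=0, n_swaps=0)
        assert np.array_equal(out.rho_fiber_mm, pop2k.rho_fiber_mm)

    def test_unit_occupancies_are_permuted_not_changed(self, pop2k):
        """Rigid unit swaps preserve the multiset of per-unit fiber counts."""
        units = UnitGrid(pop2k.nerve)
        before = np.bincount(
            units.unit_of(pop2k.fiber_xy())[units.unit_of(pop2k.fiber_xy()) >= 0],
            minlength=units.n_units,
        )
        out = global_shuffle(pop2k, seed=5)
        u_after = units.unit_of(out.fiber_xy())
        after = np.bincount(u_after[u_after >= 0], minlength=units.n_units)
        assert sorted(before) == sorted(after)
        assert np.array_equal(out.rho_soma_mm, pop2k.rho_soma_mm)


class TestShuffleCorrection:
    def unit_aligned_grid(self, nerve):
        units = UnitGrid(nerve)
        ctr = units.centers()
        half = units.side / 2
        rects = np.column_stack([ctr[:, 0] - half, ctr[:, 1] - half, ctr[:, 0] + half, ctr[:, 1] + half])
        return units, ElectrodeGrid("nerve", ctr, rects)

    def test_no_shuffle_gives_identity_map(self, pop2k):
        grid = make_reduced_grid()
        assert np.array_equal(correct_global_shuffle(pop2k, grid), np.arange(grid.n_sites))

    def test_aligned_whole_unit_swap_corrected_exactly(self, pop2k, geom_small):
        units, grid = self.unit_aligned_grid(pop2k.nerve)
        ctr = units.centers()
        xy = pop2k.fiber_xy()
        u = units.unit_of(xy)
        i, j = 8, 27
        xy2 = xy.copy()
        xy2[u == i] += ctr[j] - ctr[i]
        xy2[u == j] -= ctr[j] - ctr[i]
        shuffled = pop2k.copy(
            rho_fiber_mm=np.hypot(xy2[:, 0], xy2[:, 1]),
            theta_fiber=np.mod(np.arctan2(xy2[:, 1], xy2[:, 0]), 2 * np.pi),
            fiber_xy_original=xy,
        )
        site_map = correct_global_shuffle(shuffled, grid)
        expected = np.arange(grid.n_sites)
        expected[i], expected[j] = j, i
        assert np.array_equal(site_map, expected)
        # the corrected pattern equals the intended one fiber-by-fiber
        stack = build_rf_stack(pop2k, geom_small)
        rng = np.random.default_rng(0)
        nat_rates = rng.random(pop2k.n) * 300 * (rng.random(pop2k.n) < 0.6)
        from onspv.encoding import FiringPattern

        nat = FiringPattern(nat_rates)
        intended = apply_partition_rule(nat, assign(pop2k, grid), StimRule(), grid)
        corrected = stimulate_shuffled(nat, shuffled, grid, StimRule(), site_map=site_map)
        assert np.array_equal(np.sort(corrected.rates), np.sort(intended.rates))
        target = reconstruct(intended, pop2k, geom_small, stack).data
        got = reconstruct(corrected, shuffled, geom_small, stack).data
        assert np.allclose(got, target, atol=1e-12)

    def test_correction_improves_percepts_after_default_shuffle(
        self, pop10k, geom_small, stack_small, fixture_scenes
    ):
        grid = make_reduced_grid()
        rule = StimRule()
        shuffled = global_shuffle(pop10k, seed=0)
        unc_mses, cor_mses = [], []
        for scene in fixture_scenes:
            nat = encode(scene, pop10k, stack_small)
            target = reconstruct(
                apply_partition_rule(nat, assign(pop10k, grid), rule, grid),
                pop10k, geom_small, stack_small,
            ).data
            unc = reconstruct(
                stimulate_shuffled(nat, shuffled, grid, rule), shuffled, geom_small, stack_small
            ).data
            cor = reconstruct(
                stimulate_shuffled(nat, shuffled, grid, rule, correction="least_squares"),
                shuffled, geom_small, stack_small,
            ).data
            unc_mses.append(np.mean((unc - target) ** 2))
            cor_mses.append(np.mean((cor - target) ** 2))
        for u, c in zip(unc_mses, cor_mses):
            if u > 0:
                assert c < u
        assert np.mean(cor_mses) < np.mean(unc_mses)


class TestBrokenSites:
    def test_ten_percent_of_reduced_grid(self):
        grid = disable_sites(make_reduced_grid(), fraction=0.10, seed=0)
        assert (~grid.active).sum() == 15  # round(14.8)

    def test_zero_fraction_unchanged(self):
        grid = disable_sites(make_reduced_grid(), fraction=0.0)
        assert grid.active.all()

    def test_all_broken_gives_black_percept(self, pop10k, geom_small, stack_small, fixture_scenes):
        from onspv.electrodes import best_perception

        grid = disable_sites(make_regular_grid(10), fraction=1.0)
        percept = best_perception(fixture_scenes[0], pop10k, grid, stack=stack_small)
        assert not percept.data.any()


class TestEncapsulation:
    def test_zero_radius_no_deaths(self, pop2k):
        out = encapsulation_depletion(pop2k, make_regular_grid(14), 0.0)
        assert not out.dead.any()

    def test_matches_brute_force_distance_count(self, pop10k):
        grid = make_regular_grid(14)
        out = encapsulation_depletion(pop10k, grid, 50.0)
        xy = pop10k.fiber_xy()
        brute = np.zeros(pop10k.n, bool)
        for c in grid.centers:
            brute |= np.hypot(xy[:, 0] - c[0], xy[:, 1] - c[1]) <= 0.05
        assert np.array_equal(out.dead, brute)

    def test_huge_radius_kills_all_in_grid_fibers(self, pop2k):
        grid = make_regular_grid(14)
        half_diag = np.hypot(5 / 14, 5 / 14) / 2
        out = encapsulation_depletion(pop2k, grid, half_diag * 1000 + 1)
        assert out.dead.all()


class TestDegeneration:
    @pytest.mark.parametrize("kind", ["uniform", "foveal", "peripheral"])
    def test_realized_fraction_near_target(self, pop10k, kind):
        out = degenerate_fibers(pop10k, DegenerationScenario(kind=kind, seed=7))
        assert out.dead.mean() == pytest.approx(0.5, abs=0.02)

    def test_uniform_fraction_concentrates(self, pop10k):
        fracs = [
            degenerate_fibers(pop10k, DegenerationScenario(kind="uniform", seed=s)).dead.mean()
            for s in range(10)
        ]
        assert np.std(fracs) < 0.01

    def test_foveal_sigmoid_midpoint(self, pop10k):
        scenario = DegenerationScenario(kind="foveal", seed=0)
        r_ret = pop10k.retina.max_eccentricity_mm
        base = scenario.base_probability(np.array([0.35 * r_ret]), r_ret)
        assert base[0] == pytest.approx(0.5)

    def test_foveal_kills_center_peripheral_kills_edge(self, pop10k):
        lo, hi = np.quantile(pop10k.rho_soma_mm, [0.1, 0.9])
        fov = degenerate_fibers(pop10k, DegenerationScenario(kind="foveal", seed=1))
        per = degenerate_fibers(pop10k, DegenerationScenario(kind="peripheral", seed=1))
        assert fov.dead[pop10k.rho_soma_mm <= lo].mean() > fov.dead[pop10k.rho_soma_mm >= hi].mean()
        assert per.dead[pop10k.rho_soma_mm >= hi].mean() > per.dead[pop10k.rho_soma_mm <= lo].mean()

    def test_soma_and_rf_untouched(self, pop2k):
        out = degenerate_fibers(pop2k, DegenerationScenario(seed=0))
        assert np.array_equal(out.rho_soma_mm, pop2k.rho_soma_mm)
        assert np.array_equal(out.rho_rf_deg, pop2k.rho_rf_deg)
        assert np.array_equal(out.rho_fiber_mm, pop2k.rho_fiber_mm)
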