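"""Climate-space gridding, kernel densities, Schoener's D, equivalency test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tickniche import (
    GridSpec,
    NicheDensity,
    equivalency_test,
    kernel_density,
    make_grid,
    niche_density,
    occupancy,
    overlap_matrix,
    schoener_d,
    silverman_bandwidths,
)
from tickniche.simulate import sample_niche_scores, separated_gaussian_pair, true_schoener_d


def unit_grid(r=10, d=2):
    return GridSpec(d=d, r=r, bounds=((0.0, 1.0),) * d)


class TestMakeGrid:
    def test_uniform_partition_bin_width(self, rng):
        scores = rng.uniform(size=(50, 2))
        scores[0] = [0.0, 0.0]
        scores[1] = [1.0, 1.0]
        grid = make_grid(scores, d=2, r=10, margin=0.0)
        np.testing.assert_allclose(grid.widths, 0.1)

    def test_every_point_in_exactly_one_cell(self, rng):
        bg = rng.normal(size=(200, 2))
        occ = rng.normal(size=(40, 2))
        grid = make_grid(bg, occ, d=2, r=25)
        idx = grid.assign(np.vstack([bg, occ]))
        assert idx.min() >= 0 and idx.max() <= 24

    def test_interior_edge_point_goes_to_higher_bin(self):
        # r = 8 makes bin edges exactly representable; 0.375 is the shared
        # edge of bins 2 and 3, and half-open intervals put it in bin 3,
        # exactly as direct interval arithmetic says.
        grid = unit_grid(r=8)
        edge = 0.375
        lo, w = 0.0, 0.125
        direct = next(k for k in range(8) if lo + k * w <= edge < lo + (k + 1) * w)
        assert grid.assign([[edge, 0.05]])[0, 0] == direct == 3

    def test_upper_bound_closed_into_last_bin(self):
        grid = unit_grid(r=10)
        assert tuple(grid.assign([[1.0, 1.0]])[0]) == (9, 9)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            make_grid(np.ones((5, 2)), d=2, r=10)


class TestKernelDensity:
    def test_tiny_bandwidth_concentrates_in_containing_cell(self):
        grid = unit_grid(r=10)
        point = np.array([[0.34, 0.71]])
        dens = kernel_density(point, grid, 0.005)
        cell = tuple(grid.assign(point)[0])
        assert dens[cell] == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_mixture_evaluation(self, rng):
        grid = unit_grid(r=10)
        pts = rng.uniform(0.2, 0.8, size=(2, 2))
        h = np.array([0.07, 0.12])
        dens = kernel_density(pts, grid, h)
        cx, cy = grid.centers(0), grid.centers(1)
        direct = np.zeros((10, 10))
        for i in range(10):
            for j in range(10):
                for p in pts:
                    direct[i, j] += np.exp(
                        -0.5 * ((cx[i] - p[0]) / h[0]) ** 2
                        - 0.5 * ((cy[j] - p[1]) / h[1]) ** 2
                    )
        direct /= direct.sum()
        np.testing.assert_allclose(dens, direct, atol=1e-12)

    def test_normalizes_to_one(self, rng):
        for d in (1, 2, 3):
            grid = unit_grid(r=7, d=d)
            dens = kernel_density(rng.uniform(size=(15, d)), grid, 0.2)
            assert dens.sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_bandwidth_rejected(self, rng):
        with pytest.raises(ValueError, match="bandwidth"):
            kernel_density(rng.uniform(size=(3, 2)), unit_grid(), 0.0)

    def test_silverman_shrinks_with_n(self, rng):
        small = silverman_bandwidths(rng.normal(size=(20, 2)))
        large = silverman_bandwidths(rng.normal(size=(2000, 2)))
        assert (large < small).all()


class TestOccupancy:
    def test_uniform_availability_is_noop(self, rng):
        o = rng.uniform(size=(8, 8))
        o /= o.sum()
        e = np.full((8, 8), 1 / 64)
        np.testing.assert_allclose(occupancy(o, e), o, atol=1e-12)

    def test_correction_off_passes_o_through(self, rng):
        o = rng.uniform(size=(5, 5))
        o /= o.sum()
        e = rng.uniform(size=(5, 5))
        e /= e.sum()
        np.testing.assert_array_equal(occupancy(o, e, correct_by_availability=False), o)

    def test_correction_matches_elementwise_ratio(self, rng):
        o = rng.uniform(size=(6, 6)) ** 3
        o /= o.sum()
        e = rng.uniform(0.001, 1.0, size=(6, 6))
        e /= e.sum()
        z = occupancy(o, e)
        ratio = o / e
        np.testing.assert_allclose(z, ratio / ratio.sum(), atol=1e-12)
        # Cells where availability is scarce gain relative occupancy.
        scarce = e < np.median(e)
        assert (z[scarce] / o[scarce]).mean() > (z[~scarce] / o[~scarce]).mean()

    def test_no_habitable_environment_errors(self):
        o = np.full((3, 3), 1 / 9)
        with pytest.raises(ValueError, match="mass floor"):
            occupancy(o, np.zeros((3, 3)))


class TestSchoenerD:
    def test_identity_gives_one(self, rng):
        z = rng.uniform(size=(9, 9))
        z /= z.sum()
        assert schoener_d(z, z) == 1.0

    def test_disjoint_supports_give_zero(self):
        z1 = np.zeros(10); z1[:5] = 0.2
        z2 = np.zeros(10); z2[5:] = 0.2
        assert schoener_d(z1, z2) == pytest.approx(0.0, abs=1e-15)

    def test_hand_worked_example(self):
        z1 = np.array([0.5, 0.25, 0.25, 0.0])
        z2 = np.array([0.25, 0.25, 0.25, 0.25])
        assert schoener_d(z1, z2) == pytest.approx(0.75, abs=1e-15)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            schoener_d(np.ones(4) / 4, np.ones(5) / 5)

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_symmetric_and_bounded(self, seed):
        r = np.random.default_rng(seed)
        z1 = r.uniform(size=12); z1 /= z1.sum()
        z2 = r.uniform(size=12); z2 /= z2.sum()
        d12, d21 = schoener_d(z1, z2), schoener_d(z2, z1)
        assert d12 == d21 and 0.0 <= d12 <= 1.0

    def test_estimate_error_nonincreasing_in_n(self):
        # Fixed synthetic pair; median |D_est - D*| over seeds must not grow
        # as the per-species sample grows 500 -> 5000.
        a, b = separated_gaussian_pair("mid", n_records=1)
        truth = true_schoener_d(a.mean, a.cov, b.mean, b.cov)
        meds = []
        for n in (500, 5000):
            errs = []
            for seed in range(10):
                r = np.random.default_rng(seed)
                bg = r.uniform(-5, 5, size=(2000, 2))
                sa = r.multivariate_normal(a.mean, a.cov, size=n)
                sb = r.multivariate_normal(b.mean, b.cov, size=n)
                grid = make_grid(bg, np.vstack([sa, sb]), d=2, r=100)
                da = niche_density("A", sa, bg, grid=grid, correct_by_availability=False)
                db = niche_density("B", sb, bg, grid=grid, correct_by_availability=False,
                                   e=da.e)
                errs.append(abs(schoener_d(da, db) - truth))
            meds.append(np.median(errs))
        assert meds[1] <= meds[0]


class TestEquivalencyTest:
    def test_identical_point_sets_give_d1_p1(self, rng):
        occ = rng.normal(size=(20, 2))
        bg = rng.uniform(-4, 4, size=(500, 2))
        res = equivalency_test(occ, occ.copy(), bg, n_permutations=49, seed=0)
        assert res.D == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_reproducible_for_fixed_seed(self, rng):
        occ1 = rng.normal(size=(15, 2))
        occ2 = rng.normal(1.0, 1.0, size=(15, 2))
        bg = rng.uniform(-5, 5, size=(400, 2))
        a = equivalency_test(occ1, occ2, bg, n_permutations=29, seed=11)
        b = equivalency_test(occ1, occ2, bg, n_permutations=29, seed=11)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.null_D, b.null_D)

    def test_pvalue_formula_add_one_lower_tail(self, rng):
        occ1 = rng.normal(size=(12, 2))
        occ2 = rng.normal(size=(12, 2))
        bg = rng.uniform(-4, 4, size=(300, 2))
        res = equivalency_test(occ1, occ2, bg, n_permutations=39, seed=2)
        expected = (1 + np.count_nonzero(res.null_D <= res.D)) / 40
        assert res.p_value == expected
        assert 0.0 < res.p_value <= 1.0

    def test_too_few_occurrences_names_species(self, rng):
        bg = rng.uniform(size=(100, 2))
        with pytest.raises(ValueError, match="left"):
            equivalency_test(rng.normal(size=(3, 2)), rng.normal(size=(10, 2)),
                             bg, labels=("left", "right"))


class TestOverlapMatrix:
    def _density(self, name, z, grid):
        return NicheDensity(species=name, grid=grid, o=z, e=z, z=z,
                            bandwidths=np.array([0.1, 0.1]), n_occurrences=10)

    def test_identical_species_offdiagonal_one(self, rng):
        grid = unit_grid(r=5)
        z = rng.uniform(size=(5, 5)); z /= z.sum()
        table = overlap_matrix({"a": self._density("a", z, grid),
                                "b": self._density("b", z.copy(), grid)})
        assert table.loc["a", "b"] == 1.0
        assert (np.diag(table.values) == 1.0).all()

    def test_composition_with_disjoint_third_species(self):
        grid = unit_grid(r=4)
        z_ab = np.zeros((4, 4)); z_ab[:2] = 1 / 8
        z_c = np.zeros((4, 4)); z_c[2:] = 1 / 8
        table = overlap_matrix({
            "A": self._density("A", z_ab, grid),
            "B": self._density("B", z_ab.copy(), grid),
            "C": self._density("C", z_c, grid),
        })
        assert table.loc["A", "B"] == 1.0
        assert table.loc["A", "C"] == pytest.approx(0.0, abs=1e-15)
        assert table.loc["B", "C"] == pytest.approx(0.0, abs=1e-15)

    def test_empty_species_omitted(self, rng):
        grid = unit_grid(r=5)
        z = rng.uniform(size=(5, 5)); z /= z.sum()
        densities = {"a": self._density("a", z, grid),
                     "b": self._density("b", z, grid)}
        densities["ghost"] = NicheDensity("ghost", grid, z, z, z,
                                          np.array([0.1, 0.1]), n_occurrences=0)
        table = overlap_matrix(densities)
        assert "ghost" not in table.index

    def test_pipeline_recovers_constructed_overlap(self, rng):
        a, b = separated_gaussian_pair("high", n_records=2000)
        truth = true_schoener_d(a.mean, a.cov, b.mean, b.cov)
        sa = sample_niche_scores(a, rng)
        sb = sample_niche_scores(b, rng)
        bg = rng.uniform(-5, 5, size=(3000, 2))
        grid = make_grid(bg, np.vstack([sa, sb]), d=2, r=100)
        da = niche_density("A", sa, bg, grid=grid, correct_by_availability=False)
        db = niche_density("B", sb, bg, grid=grid, correct_by_availability=False, e=da.e)
        assert abs(schoener_d(da, db) - truth) < 0.05
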