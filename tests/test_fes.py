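"""Density map, Boltzmann inversion and watershed clustering."""

import numpy as np
import pandas as pd
import pytest

import crypticpocket as cp
from crypticpocket.fes import FreeEnergySurface, _flood
from conftest import gaussian_mixture_projections, projection_set

KT_300 = 0.5962


class TestDensityMap:
    def test_one_frame_per_quadrant(self, make_projections):
        proj = make_projections([[-1, -1], [-1, 1], [1, -1], [1, 1]])
        surf = cp.density_map(proj, (2, 2), smooth_sigma=0.0)
        np.testing.assert_allclose(surf.density, 0.25)
        assert surf.density.sum() == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_density_quadrant_symmetric(self, make_projections):
        """A point-symmetric sample must give a density grid that is exactly
        invariant under reflection through the origin, and each half-plane
        carries half the mass."""
        rng = np.random.default_rng(0)
        half = rng.normal(0, 1, (5000, 2))
        n = 10_000
        proj = make_projections(np.vstack([half, -half]))
        surf = cp.density_map(proj, (40, 40), smooth_sigma=0.0)
        # symmetric up to the extreme samples, which sit exactly on an edge
        # and may round into either neighbouring bin
        asym = np.abs(surf.density - surf.density[::-1, ::-1])
        assert asym.sum() <= 8 / n
        assert surf.density[:20].sum() == pytest.approx(
            0.5, abs=3 * np.sqrt(0.25 / n))

    def test_empty_projections_rejected(self, make_projections):
        with pytest.raises(ValueError):
            cp.density_map(make_projections(np.empty((0, 2))))

    def test_single_bin_degenerate_warns(self, make_projections):
        proj = make_projections(np.zeros((10, 2)))
        with pytest.warns(UserWarning, match="degenerate"):
            cp.density_map(proj, (4, 4), smooth_sigma=0.0)


def two_bin_surface(p1=0.8, p2=0.2):
    density = np.array([[p1, p2], [0.0, 0.0]])
    edges = np.array([0.0, 1.0, 2.0])
    return FreeEnergySurface(edges, edges, density)


class TestBoltzmannInversion:
    def test_uniform_density_is_flat(self):
        density = np.full((4, 4), 1 / 16)
        surf = FreeEnergySurface(np.arange(5.0), np.arange(5.0), density)
        out = cp.boltzmann_invert(surf, KT_300)
        np.testing.assert_allclose(out.g, 0.0, atol=1e-12)

    def test_two_bin_closed_form(self):
        """p = 0.8 / 0.2 at 300 K: the free-energy gap is kT ln 4 =
        0.8265 kcal/mol."""
        out = cp.boltzmann_invert(two_bin_surface(), KT_300)
        dg = out.g[0, 1] - out.g[0, 0]
        assert dg == pytest.approx(KT_300 * np.log(4.0), abs=1e-9)
        assert dg == pytest.approx(0.8265, abs=1e-4)
        assert out.g[0, 0] == 0.0

    def test_linearity_in_kt(self):
        a = cp.boltzmann_invert(two_bin_surface(), KT_300)
        b = cp.boltzmann_invert(two_bin_surface(), 2 * KT_300)
        assert b.g[0, 1] == pytest.approx(2 * a.g[0, 1], rel=1e-12)

    def test_empty_bins_get_sentinel_not_nan(self):
        out = cp.boltzmann_invert(two_bin_surface(), KT_300)
        assert np.all(np.isfinite(out.g))
        finite_max = out.g[0, 1]
        assert out.g[1, 0] == pytest.approx(finite_max + 3 * KT_300)

    def test_nonpositive_kt_rejected(self):
        with pytest.raises(ValueError):
            cp.boltzmann_invert(two_bin_surface(), 0.0)


def steepest_descent_oracle(g):
    """Brute-force assignment: every bin follows its steepest-descent path
    (lowest 8-neighbour, ties by row-major index) to a local minimum."""
    b1, b2 = g.shape

    def lowest_neighbour(i, j):
        best = None
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if (di, dj) == (0, 0):
                    continue
                ni, nj = i + di, j + dj
                if 0 <= ni < b1 and 0 <= nj < b2:
                    cand = (g[ni, nj], ni * b2 + nj)
                    if best is None or cand < best:
                        best = cand
        return divmod(best[1], b2), best[0]

    def descend(i, j):
        while True:
            (ni, nj), gval = lowest_neighbour(i, j)
            if (gval, ni * b2 + nj) >= (g[i, j], i * b2 + j):
                return (i, j)
            i, j = ni, nj

    minima = {}
    labels = np.zeros((b1, b2), dtype=int)
    for i in range(b1):
        for j in range(b2):
            m = descend(i, j)
            if m not in minima:
                minima[m] = len(minima) + 1
            labels[i, j] = minima[m]
    return labels


class TestWatershed:
    def test_single_gaussian_single_basin(self):
        proj, _ = gaussian_mixture_projections(3, 10_000, [1.0],
                                               [(0.0, 0.0)], [1.0])
        surf = cp.boltzmann_invert(cp.density_map(proj, (100, 100)), KT_300)
        part = cp.watershed_partition(surf, proj, min_basin_population=0.05)
        assert part.n_basins == 1
        assert part.populations[1] == pytest.approx(1.0, abs=1e-12)

    def test_two_gaussian_population_recovery(self):
        proj, labels = gaussian_mixture_projections(
            11, 20_000, [0.7, 0.3], [(-3.0, -2.0), (5.0, 4.0)], [1.0, 0.8])
        surf = cp.boltzmann_invert(cp.density_map(proj, (100, 100)), KT_300)
        part = cp.watershed_partition(surf, proj, min_basin_population=0.05)
        assert part.n_basins == 2
        pops = sorted(part.populations.values())
        true_minor = np.mean(labels == 1)
        assert pops[0] == pytest.approx(true_minor, abs=0.03)
        assert pops[1] == pytest.approx(1 - true_minor, abs=0.03)

    def test_small_basin_merged_into_lowest_pass_neighbour(self):
        proj, _ = gaussian_mixture_projections(
            5, 20_000, [0.75, 0.20, 0.05],
            [(-4.0, 0.0), (4.0, 0.0), (0.0, 4.0)], [0.8, 0.8, 0.5])
        surf = cp.boltzmann_invert(cp.density_map(proj, (100, 100)), KT_300)
        unmerged = cp.watershed_partition(surf, proj,
                                          min_basin_population=0.0)
        merged = cp.watershed_partition(surf, proj,
                                        min_basin_population=0.10)
        assert unmerged.n_basins >= 3
        assert merged.n_basins == 2
        assert sum(merged.populations.values()) == pytest.approx(1.0,
                                                                 abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_flood_matches_steepest_descent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.random((6, 6))
        labels = _flood(g, np.ones_like(g, dtype=bool))
        oracle = steepest_descent_oracle(g)
        # same partition up to label naming
        for basin in np.unique(labels):
            cells = oracle[labels == basin]
            assert len(np.unique(cells)) == 1
        assert len(np.unique(labels)) == len(np.unique(oracle))

    def test_frame_order_permutation_invariance(self):
        proj, _ = gaussian_mixture_projections(
            9, 4000, [0.6, 0.4], [(-3.0, 0.0), (3.0, 0.0)], [0.7, 0.7])
        surf = cp.boltzmann_invert(cp.density_map(proj, (60, 60)), KT_300)
        part = cp.watershed_partition(surf, proj)
        rng = np.random.default_rng(0)
        perm = rng.permutation(proj.n_frames)
        shuffled = projection_set(proj.projections[perm])
        surf2 = cp.boltzmann_invert(cp.density_map(shuffled, (60, 60)),
                                    KT_300)
        part2 = cp.watershed_partition(surf2, shuffled)
        np.testing.assert_array_equal(part.bin_labels, part2.bin_labels)
        np.testing.assert_array_equal(part.frame_labels[perm],
                                      part2.frame_labels)

    def test_basin_count_bounded_by_minima_and_pops_sum(self):
        proj, _ = gaussian_mixture_projections(
            21, 5000, [0.5, 0.5], [(-3.0, 0.0), (3.0, 0.0)], [0.8, 0.8])
        surf = cp.boltzmann_invert(cp.density_map(proj, (50, 50)), KT_300)
        part = cp.watershed_partition(surf, proj)
        assert sum(part.populations.values()) == pytest.approx(1.0,
                                                               abs=1e-12)
        g, occ = surf.g, ~surf.empty_mask
        n_minima = 0
        for i, j in np.argwhere(occ):
            vals = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if (di, dj) == (0, 0):
                        continue
                    ni, nj = i + di, j + dj
                    if (0 <= ni < g.shape[0] and 0 <= nj < g.shape[1]
                            and occ[ni, nj]):
                        vals.append(g[ni, nj])
            if not vals or g[i, j] <= min(vals):
                n_minima += 1
        assert part.n_basins <= n_minima


class TestRepresentatives:
    def test_single_frame_basin(self, make_projections):
        proj = make_projections([[0.0, 0.0]])
        surf = cp.boltzmann_invert(cp.density_map(proj, (2, 2),
                                                  smooth_sigma=0.0), KT_300)
        part = cp.watershed_partition(surf, proj)
        reps = cp.representative_frames(part, proj)
        assert reps == {1: 0}

    def test_symmetric_three_frames_middle_is_medoid(self, make_projections):
        proj = make_projections([[-1.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        labels = np.ones(3, dtype=int)
        part = cp.ClusterPartition(np.ones((1, 1), dtype=int), labels,
                                   {1: 1.0}, {1: ((0, 0), 0.0)})
        reps = cp.representative_frames(part, proj)
        assert reps[1] == 1

    def test_matches_exhaustive_medoid_oracle(self, make_projections):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 2, (200, 2))
        proj = make_projections(pts)
        labels = np.ones(200, dtype=int)
        part = cp.ClusterPartition(np.ones((1, 1), dtype=int), labels,
                                   {1: 1.0}, {1: ((0, 0), 0.0)})
        reps = cp.representative_frames(part, proj)
        d2 = np.sum((pts[:, None] - pts[None, :]) ** 2, axis=2)
        oracle = int(np.argmin(d2.sum(axis=1)))
        assert reps[1] == oracle


class TestSubcluster:
    def test_single_state_family_one_basin(self):
        spec = cp.TwoStateSpec(n_frames=600, populations=(1.0, 0.0),
                               noise_sd=0.3, seed=13)
        ens, _ = cp.make_two_state_ensemble(spec)
        sel = cp.select_loops(ens, [(8, 14), (20, 30), (40, 48)])
        part = cp.refit_and_subcluster(ens, np.arange(600), sel,
                                       bins=(60, 60),
                                       min_basin_population=0.05)
        assert part.n_basins == 1

    def test_three_substate_mixture_recovered(self):
        """A 0.75/0.15/0.10 substate mixture must come back as 3 basins with
        the dominant population within 0.03."""
        atoms, base = cp.base_scaffold(50)
        d1 = cp.synthetic.loop_displacement_field(atoms, [(8, 14)], 4.0,
                                                  (1.0, 0.0, 0.0))
        d2 = cp.synthetic.loop_displacement_field(atoms, [(40, 48)], 4.0,
                                                  (0.0, 0.0, 1.0))
        rng = np.random.default_rng(17)
        n = 6000
        states = rng.choice(3, size=n, p=[0.75, 0.15, 0.10])
        coords = np.repeat(base[None], n, axis=0)
        coords[states == 1] += d1
        coords[states == 2] += d2
        coords += rng.normal(0, 0.2, coords.shape)
        ens = cp.ConformationalEnsemble(coords, atoms)
        sel = cp.select_loops(ens, [(8, 14), (20, 30), (40, 48)])
        part = cp.refit_and_subcluster(ens, np.arange(n), sel,
                                       bins=(100, 100),
                                       min_basin_population=0.05)
        assert part.n_basins == 3
        dominant = max(part.populations.values())
        assert dominant == pytest.approx(np.mean(states == 0), abs=0.03)

    def test_representative_and_minimum_recorded(self):
        spec = cp.TwoStateSpec(n_frames=300, seed=19)
        ens, _ = cp.make_two_state_ensemble(spec)
        sel = cp.select_loops(ens, [(8, 14), (20, 30), (40, 48)])
        part = cp.refit_and_subcluster(ens, np.arange(300), sel,
                                       bins=(50, 50),
                                       min_basin_population=0.1)
        assert part.representatives is not None
        for basin, (ij, gval) in part.minima.items():
            assert gval >= 0.0
            assert part.bin_labels[ij] == basin
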