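"""Segmentation: level-set energy, Levy sampler, DBO role updates, optimizer."""

import math

import numpy as np
import pytest

from leukosuite.segment import (
    Candidate,
    DBOConfig,
    LevelSet,
    LocalRegionConfig,
    breed_update,
    dance_update,
    exhaustive_threshold_search,
    extract_boundary,
    forage_update,
    local_window_mask,
    localized_energy,
    mask_from_thresholds,
    optimize,
    roll_update,
    sample_levy_steps,
    segment_image,
    signed_distance,
    smooth_heaviside,
    steal_update,
    threshold_fitness,
)


class TestSmoothHeaviside:
    def test_outer_branches(self):
        assert smooth_heaviside(-2.0, 1.0) == 1.0
        assert smooth_heaviside(2.0, 1.0) == 0.0

    def test_symmetry_at_zero(self):
        assert smooth_heaviside(0.0, 1.0) == pytest.approx(0.5)

    def test_middle_branch_value(self):
        # ½{1 − η/ε − sin(πη/ε)/π} at η=ε/2
        expected = 0.25 - 1.0 / (2.0 * math.pi)
        assert smooth_heaviside(0.5, 1.0) == pytest.approx(expected)

    def test_monotone_and_continuous(self):
        eta = np.linspace(-2, 2, 2001)
        vals = smooth_heaviside(eta, 1.0)
        assert np.all(np.diff(vals) <= 1e-12)
        # continuity at the transition points
        assert abs(smooth_heaviside(-1.0 + 1e-9, 1.0) - 1.0) < 1e-6
        assert abs(smooth_heaviside(1.0 - 1e-9, 1.0)) < 1e-6


class TestLocalWindowMask:
    def test_self_distance(self):
        assert local_window_mask((3, 4), (3, 4), 1.0) == 1

    def test_strict_inequality_at_radius(self):
        assert local_window_mask((0, 0), (0, 5), 5.0) == 0

    def test_inside_radius(self):
        assert local_window_mask((0, 0), (3, 4), 6.0) == 1

    def test_symmetric(self, rng):
        for _ in range(20):
            a = tuple(rng.integers(0, 10, 2))
            b = tuple(rng.integers(0, 10, 2))
            s = rng.uniform(1, 8)
            assert local_window_mask(a, b, s) == local_window_mask(b, a, s)


def _brute_force_energy(img, phi, eps, s, band):
    """Independent double-loop evaluation of the localized energy."""
    h = smooth_heaviside(phi, eps)
    m, n = img.shape
    total = 0.0
    for y0 in range(m):
        for x0 in range(n):
            if abs(phi[y0, x0]) >= band:
                continue
            pts = [
                (y1, x1)
                for y1 in range(m)
                for x1 in range(n)
                if local_window_mask((y0, x0), (y1, x1), s)
            ]
            den_v = sum(h[p] for p in pts)
            den_u = sum(1 - h[p] for p in pts)
            v = sum(h[p] * img[p] for p in pts) / den_v if den_v > 0 else 0.0
            u = sum((1 - h[p]) * img[p] for p in pts) / den_u if den_u > 0 else 0.0
            total += sum(
                h[p] * (img[p] - v) ** 2 + (1 - h[p]) * (img[p] - u) ** 2 for p in pts
            )
    return total


class TestLocalizedEnergy:
    def test_two_level_image_zero_energy(self):
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        img = np.where(mask, 0.2, 0.8)
        e = localized_energy(img, LevelSet(signed_distance(mask), 1e-6), LocalRegionConfig(3.0, 2.0))
        assert e == pytest.approx(0.0, abs=1e-9)

    def test_shifted_contour_positive(self):
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        img = np.where(np.roll(mask, 1, axis=0), 0.2, 0.8)
        e = localized_energy(img, LevelSet(signed_distance(mask), 1e-6), LocalRegionConfig(3.0, 2.0))
        assert e > 0.1

    def test_matches_brute_force(self, rng):
        mask = np.zeros((8, 8), bool)
        mask[2:6, 3:7] = True
        phi = signed_distance(mask)
        for _ in range(5):
            img = rng.random((8, 8))
            e = localized_energy(img, LevelSet(phi, 1.0), LocalRegionConfig(3.0, 2.0))
            b = _brute_force_energy(img, phi, 1.0, 3.0, 2.0)
            assert e == pytest.approx(b, abs=1e-9)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            localized_energy(np.zeros((4, 4)), LevelSet(np.zeros((5, 5))), LocalRegionConfig())


class TestLevySampler:
    def test_deterministic(self):
        a = sample_levy_steps(100, 1.5, seed=3)
        b = sample_levy_steps(100, 1.5, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_delta_out_of_range(self):
        with pytest.raises(ValueError):
            sample_levy_steps(10, 2.5)
        with pytest.raises(ValueError):
            sample_levy_steps(10, 0.0)

    def test_hill_tail_index(self):
        x = np.abs(sample_levy_steps(100_000, 1.5, seed=0))
        x = np.sort(x)[::-1]
        k = 1000  # top 1%
        hill = 1.0 / np.mean(np.log(x[:k] / x[k]))
        assert abs(hill - 1.5) <= 0.2

    def test_gaussian_limit_kurtosis(self):
        from scipy.stats import kurtosis

        g = sample_levy_steps(100_000, 2.0, seed=0)
        assert abs(kurtosis(g)) <= 0.1

    def test_brownian_limit_linear_variance_growth(self):
        """At delta=2 a free walk shows ordinary diffusion: displacement
        variance linear in step count (R^2 >= 0.99 over 1e4 steps)."""
        from leukosuite.segment import walk_displacement_variance

        var = walk_displacement_variance(10_000, n_walkers=200, delta=2.0, seed=0)
        t = np.arange(1, var.size + 1)
        r = np.corrcoef(t, var)[0, 1]
        assert r**2 >= 0.99


class TestRoleUpdates:
    CFG = DBOConfig(max_iter=10, bounds=(0.0, 1.0), seed=0)

    def test_roll_zero_increments(self):
        cfg = DBOConfig(max_iter=10, roll_b=0.0, bounds=(0.0, 1.0))
        c = Candidate(np.array([0.5]), "roller")
        out = roll_update(c, np.array([0.4]), np.array([0.9]), cfg,
                          np.random.default_rng(0), a=1.0, lam=np.array([0.0]))
        np.testing.assert_allclose(out.position, [0.5])

    def test_roll_arithmetic(self):
        cfg = DBOConfig(max_iter=10, deflection_l=0.1, roll_b=0.3, bounds=(0.0, 1.0))
        c = Candidate(np.array([0.5]), "roller")
        out = roll_update(c, np.array([0.4]), np.array([0.9]), cfg,
                          np.random.default_rng(0), a=1.0, lam=np.array([1.0]))
        np.testing.assert_allclose(out.position, [0.912])

    def test_roll_clipping(self):
        cfg = DBOConfig(max_iter=10, bounds=(0.0, 1.0))
        c = Candidate(np.array([0.9]), "roller")
        out = roll_update(c, np.array([0.9]), np.array([0.0]), cfg,
                          np.random.default_rng(0), a=1.0, lam=np.array([50.0]))
        assert out.position[0] == 1.0

    def test_dance_angles(self):
        c = Candidate(np.array([0.6]), "roller")
        rng = np.random.default_rng(0)
        same = dance_update(c, np.array([0.2]), self.CFG, rng, beta=0.0)
        np.testing.assert_allclose(same.position, [0.6])
        sing = dance_update(c, np.array([0.2]), self.CFG, rng, beta=math.pi / 2)
        np.testing.assert_allclose(sing.position, [0.6])
        out = dance_update(c, np.array([0.2]), self.CFG, rng, beta=math.pi / 4)
        np.testing.assert_allclose(out.position, [1.0])  # 0.6 + 0.4 = 1.0

    def test_breed_anchor_and_collapse(self):
        c = Candidate(np.array([0.5]), "breeder")
        rng = np.random.default_rng(0)
        anchor = np.array([0.7])
        out = breed_update(c, anchor, 1, self.CFG, rng, A1=np.zeros(1), A2=np.zeros(1))
        np.testing.assert_allclose(out.position, anchor)
        out = breed_update(c, anchor, self.CFG.max_iter, self.CFG, rng)
        np.testing.assert_allclose(out.position, anchor)

    def test_breed_stays_in_shrunk_bounds(self):
        rng = np.random.default_rng(1)
        anchor = np.array([0.6, 0.4])
        for _ in range(1000):
            c = Candidate(rng.random(2), "breeder")
            t = int(rng.integers(1, self.CFG.max_iter + 1))
            out = breed_update(c, anchor, t, self.CFG, rng)
            r = 1.0 - t / self.CFG.max_iter
            lo = np.clip(anchor * (1 - r), 0, 1)
            hi = np.clip(anchor * (1 + r), 0, 1)
            assert np.all(out.position >= lo - 1e-12) and np.all(out.position <= hi + 1e-12)

    def test_forage_arithmetic(self):
        # LA2 = 0.2, UA2 = 0.8 arise from global_best=0.4, R=0.5... use direct values
        cfg = DBOConfig(max_iter=2, bounds=(0.0, 1.0))
        c = Candidate(np.array([0.5]), "forager")
        out = forage_update(c, np.array([0.4]), 1, cfg, np.random.default_rng(0),
                            D1=np.array([1.0]), D2=np.array([0.5]))
        # R = 0.5 → LA2 = 0.2, UA2 = 0.6 → 0.5 + 0.3 − 0.05 = 0.75
        np.testing.assert_allclose(out.position, [0.75])

    def test_forage_zero_noise_identity(self):
        c = Candidate(np.array([0.5]), "forager")
        out = forage_update(c, np.array([0.4]), 1, self.CFG, np.random.default_rng(0),
                            D1=np.zeros(1), D2=np.zeros(1))
        np.testing.assert_allclose(out.position, [0.5])

    def test_steal_cases(self):
        cfg = DBOConfig(max_iter=10, steal_Q=0.5, bounds=(0.0, 1.0))
        c = Candidate(np.array([0.5]), "thief")
        rng = np.random.default_rng(0)
        out = steal_update(c, np.array([0.3]), np.array([0.4]), np.array([0.9]), cfg, rng,
                           e=np.zeros(1))
        np.testing.assert_allclose(out.position, [0.3])
        out = steal_update(c, np.array([0.3]), np.array([0.4]), np.array([0.9]), cfg, rng,
                           e=np.ones(1))
        np.testing.assert_allclose(out.position, [0.55])

    def test_updates_respect_bounds(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            c = Candidate(rng.random(3), "thief")
            out = steal_update(c, rng.random(3), rng.random(3), rng.random(3), self.CFG, rng)
            assert np.all(out.position >= 0.0) and np.all(out.position <= 1.0)

    def test_wrong_role_rejected(self):
        c = Candidate(np.array([0.5]), "thief")
        with pytest.raises(ValueError):
            roll_update(c, np.zeros(1), np.zeros(1), self.CFG, np.random.default_rng(0))


class TestOptimize:
    def test_sphere_benchmark(self):
        wins = 0
        for seed in range(10):
            cfg = DBOConfig(max_iter=300, bounds=(-5.0, 5.0), seed=seed)
            _, f, trace = optimize(lambda x: float(np.sum(x**2)), 2, cfg)
            wins += f <= 1e-3
            assert np.all(np.diff(trace) <= 0)
        assert wins >= 8

    def test_quadratic_benchmark(self):
        wins = 0
        for seed in range(10):
            cfg = DBOConfig(max_iter=300, bounds=(0.0, 10.0), seed=seed)
            best, _, _ = optimize(lambda x: float((x[0] - 3.0) ** 2), 1, cfg)
            wins += abs(best[0] - 3.0) <= 0.01
        assert wins >= 9

    def test_constant_fitness_returns_feasible(self):
        cfg = DBOConfig(max_iter=20, bounds=(-1.0, 1.0), seed=0)
        best, f, _ = optimize(lambda x: 1.0, 3, cfg)
        assert f == 1.0
        assert np.all(np.abs(best) <= 1.0)

    def test_nonfinite_fitness_names_point(self):
        cfg = DBOConfig(max_iter=5, bounds=(0.0, 1.0), seed=0)
        with pytest.raises(ValueError, match="position"):
            optimize(lambda x: float("nan"), 1, cfg)

    def test_reproducible(self):
        cfg = DBOConfig(max_iter=50, bounds=(-5.0, 5.0), seed=4)
        r1 = optimize(lambda x: float(np.sum(x**2)), 2, cfg)
        r2 = optimize(lambda x: float(np.sum(x**2)), 2, cfg)
        np.testing.assert_array_equal(r1[0], r2[0])
        assert r1[1] == r2[1]


class TestSegmentImage:
    def test_perfect_binary_image(self):
        mask = np.zeros((16, 16), bool)
        mask[4:12, 4:12] = True
        img = np.where(mask, 0.2, 0.9)
        cfg = DBOConfig(max_iter=30, seed=0)
        out = segment_image(img, K=1, cfg=cfg)
        np.testing.assert_array_equal(out, mask)

    def test_threshold_matches_exhaustive_oracle(self, rng):
        """DBO fitness equals the 256-threshold exhaustive minimum."""
        img = np.clip(
            np.concatenate([rng.normal(0.3, 0.05, 128), rng.normal(0.7, 0.05, 128)]), 0, 1
        ).reshape(16, 16)
        _, oracle = exhaustive_threshold_search(img)
        fit = threshold_fitness(img)
        hits = 0
        for seed in range(10):
            cfg = DBOConfig(max_iter=100, seed=seed)
            _, best, _ = optimize(fit, 1, cfg)
            hits += abs(best - oracle) <= 1e-9
        assert hits >= 9

    def test_too_many_thresholds_rejected(self):
        img = np.where(np.eye(8, dtype=bool), 1.0, 0.0)
        with pytest.raises(ValueError):
            segment_image(img, K=5)

    def test_localized_mode_runs(self, smear_sample):
        from leukosuite import metrics

        cfg = DBOConfig(pop_size=10, role_counts=(2, 2, 3, 3), max_iter=8, seed=0)
        out = segment_image(smear_sample.image, K=1, cfg=cfg, fitness_mode="localized",
                            region_cfg=LocalRegionConfig(4.0, 2.0))
        dice, _ = metrics.overlap_scores(out, smear_sample.mask)
        assert dice > 0.8


class TestExtractBoundary:
    def test_empty_mask(self):
        out = extract_boundary(np.zeros((5, 5), bool))
        assert not out.any()

    def test_square_perimeter(self):
        mask = np.zeros((9, 9), bool)
        mask[2:7, 2:7] = True
        assert extract_boundary(mask).sum() == 16

    def test_disk_boundary_single_closed_curve(self):
        from scipy import ndimage

        yy, xx = np.mgrid[0:31, 0:31]
        mask = (yy - 15) ** 2 + (xx - 15) ** 2 <= 100
        boundary = extract_boundary(mask)
        n_comp = ndimage.label(boundary, structure=np.ones((3, 3)))[1]
        assert n_comp == 1
        # closed curve: every boundary pixel has >= 2 8-connected boundary neighbours
        neigh = ndimage.convolve(boundary.astype(int), np.ones((3, 3), int), mode="constant") - 1
        assert np.all(neigh[boundary] >= 2)
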