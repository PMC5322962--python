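"""Gamma index, passing rates, SDD, plane extraction/alignment, detector."""

import numpy as np
import pytest

import vmat4d as v
from vmat4d.gamma import GammaCriteria


def plane(values, spacing=2.5, origin=None, provenance="simulated"):
    values = np.asarray(values, dtype=float)
    if origin is None:
        origin = (-spacing * (values.shape[0] - 1) / 2.0,
                  -spacing * (values.shape[1] - 1) / 2.0)
    return v.DosePlane(values, spacing, origin, provenance=provenance)


def smooth_random_plane(seed, n=16, spacing=2.5, base=2.0):
    """Smooth positive dose plane (random low-frequency modes)."""
    rng = np.random.default_rng(seed)
    x = np.linspace(0, 1, n)
    X, Y = np.meshgrid(x, x, indexing="ij")
    vals = base + 0.0 * X
    for _ in range(4):
        fx, fy = rng.uniform(0.5, 2.5, 2)
        px, py = rng.uniform(0, 2 * np.pi, 2)
        vals = vals + rng.uniform(0.1, 0.5) * np.sin(
            2 * np.pi * fx * X + px) * np.sin(2 * np.pi * fy * Y + py)
    return plane(np.maximum(vals, 0.1), spacing=spacing)


def brute_force_gamma(reference, evaluated, criteria, search_factor=3.0,
                      upsample=10):
    """Independent oracle: per-pixel loops over the full fine search comb,
    with hand-written bilinear interpolation of the evaluated plane."""
    ref = reference.values
    ref_max = ref.max()
    mask = ref >= criteria.threshold_pct / 100.0 * ref_max
    dist = criteria.dist_mm
    step = dist / upsample
    radius = search_factor * dist
    n_off = int(np.floor(radius / step))
    gamma = np.full(ref.shape, np.nan)
    si = reference.axis_coords(0)
    lr = reference.axis_coords(1)

    def ev_at(psi, plr):
        i = (psi - evaluated.origin[0]) / evaluated.spacing[0]
        j = (plr - evaluated.origin[1]) / evaluated.spacing[1]
        n0, n1 = evaluated.shape
        if i < 0 or i > n0 - 1 or j < 0 or j > n1 - 1:
            return None
        i0, j0 = int(np.floor(min(i, n0 - 1 - 1e-12))), int(np.floor(min(j, n1 - 1 - 1e-12)))
        fi, fj = i - i0, j - j0
        V = evaluated.values
        return ((1 - fi) * (1 - fj) * V[i0, j0] + fi * (1 - fj) * V[i0 + 1, j0]
                + (1 - fi) * fj * V[i0, j0 + 1] + fi * fj * V[i0 + 1, j0 + 1])

    for a in range(ref.shape[0]):
        for b in range(ref.shape[1]):
            if not mask[a, b]:
                continue
            d_ref = ref[a, b]
            denom = (criteria.dose_pct / 100.0) * (d_ref if criteria.local else ref_max)
            best = np.inf
            for ii in range(-n_off, n_off + 1):
                for jj in range(-n_off, n_off + 1):
                    dsi, dlr = ii * step, jj * step
                    d2 = dsi**2 + dlr**2
                    if d2 > radius**2 + 1e-9:
                        continue
                    val = ev_at(si[a] + dsi, lr[b] + dlr)
                    if val is None:
                        continue
                    g2 = (val - d_ref) ** 2 / denom**2 + d2 / dist**2
                    best = min(best, g2)
            gamma[a, b] = np.sqrt(best)
    return gamma, mask


class TestGammaIndex:
    def test_identity_all_zero(self):
        p = smooth_random_plane(1)
        res = v.gamma_index(p, p)
        assert np.nanmax(res.gamma) == pytest.approx(0.0, abs=1e-12)
        assert v.passing_rate(res)[0] == 100

    def test_uniform_three_percent_offset_on_boundary(self):
        """1.000 Gy vs 1.030 Gy at 3%/3 mm local: gamma is exactly 1 — the
        dose term alone reaches the criterion at zero distance."""
        ref = plane(np.full((12, 12), 1.0))
        ev = plane(np.full((12, 12), 1.03))
        res = v.gamma_index(ref, ev)
        assert np.allclose(res.gamma[res.evaluated_mask], 1.0, atol=1e-9)
        assert v.passing_rate(res)[0] == 100

    def test_translation_by_dta_passes_interior(self):
        """Evaluated = reference translated by exactly the DTA criterion:
        the distance term alone brings interior gamma to <= 1."""
        p = smooth_random_plane(2, n=20)
        shifted_vals = np.roll(p.values, 1, axis=0)  # 2.5 mm shift < 3 mm
        ev = plane(shifted_vals)
        res = v.gamma_index(p, ev)
        interior = res.gamma[4:-4, 4:-4]
        assert np.nanmax(interior) <= 1.0 + 1e-9

    @pytest.mark.parametrize("seed,local", [(3, True), (4, False), (5, True)])
    def test_matches_brute_force_oracle(self, seed, local):
        """Vectorized gamma equals the exhaustive per-pixel oracle to 1e-6
        on small planes."""
        ref = smooth_random_plane(seed, n=12)
        ev = smooth_random_plane(seed + 100, n=12)
        crit = GammaCriteria(3.0, 3.0, local, 20.0)
        res = v.gamma_index(ref, ev, crit)
        expected, mask = brute_force_gamma(ref, ev, crit)
        assert np.array_equal(res.evaluated_mask, mask)
        assert np.allclose(res.gamma[mask], expected[mask], atol=1e-6)

    def test_criterion_loosening_monotone(self):
        """Loosening either criterion never flips a passing pixel to
        failing (search combs matched via the upsample factor)."""
        ref = smooth_random_plane(6, n=16)
        ev = smooth_random_plane(7, n=16)
        tight = v.gamma_index(ref, ev, GammaCriteria(3.0, 3.0), upsample=12)
        loose_dose = v.gamma_index(ref, ev, GammaCriteria(4.0, 3.0), upsample=12)
        loose_dist = v.gamma_index(ref, ev, GammaCriteria(3.0, 4.0), upsample=16)
        assert np.all(loose_dose.pass_mask[tight.pass_mask])
        assert np.all(loose_dist.pass_mask[tight.pass_mask])

    def test_local_equals_global_for_uniform_reference(self):
        ref = plane(np.full((10, 10), 2.0))
        ev = smooth_random_plane(8, n=10)
        g_local = v.gamma_index(ref, ev, GammaCriteria(3.0, 3.0, local=True))
        g_global = v.gamma_index(ref, ev, GammaCriteria(3.0, 3.0, local=False))
        m = g_local.evaluated_mask
        assert np.allclose(g_local.gamma[m], g_global.gamma[m], atol=1e-12)

    def test_empty_mask_rejected(self):
        ref = plane(np.full((8, 8), 1.0))
        crit = GammaCriteria(3.0, 3.0, True, 120.0)  # threshold above max
        with pytest.raises(ValueError, match="threshold"):
            v.gamma_index(ref, ref, crit)


class TestPassingRateAndSDD:
    def test_half_failing_fixture_gives_fifty_percent(self):
        """Left half matches, right half is +20% with pixels spaced beyond
        the search radius: exactly half the pixels fail."""
        vals = np.full((4, 4), 1.0)
        ref = plane(vals, spacing=10.0)
        ev_vals = vals.copy()
        ev_vals[:, 2:] = 1.2
        ev = plane(ev_vals, spacing=10.0)
        res = v.gamma_index(ref, ev)
        rate_int, rate = v.passing_rate(res)
        assert rate_int == 50 and rate == pytest.approx(50.0)

    def test_roi_below_threshold_rejected(self):
        vals = np.full((10, 10), 1.0)
        vals[:3, :3] = 0.05   # corner below the 20% threshold
        ref = plane(vals)
        res = v.gamma_index(ref, ref)
        corner = v.RoiMask2D(np.zeros((10, 10), dtype=bool), label="CTV")
        corner.mask[:3, :3] = True
        with pytest.raises(ValueError, match="no evaluated pixel"):
            v.passing_rate(res, corner)

    def test_threshold_invariance(self):
        """Reference pixels below the dose threshold never influence the
        reported rate."""
        base = smooth_random_plane(9, n=14)
        vals = base.values.copy()
        vals[0:2, :] = 0.01 * vals.max()
        ref1 = plane(vals)
        vals2 = vals.copy()
        vals2[0:2, :] = 0.15 * vals.max()  # still below 20%
        ref2 = plane(vals2)
        ev = smooth_random_plane(10, n=14)
        r1 = v.gamma_index(ref1, ev)
        r2 = v.gamma_index(ref2, ev)
        assert v.passing_rate(r1)[1] == v.passing_rate(r2)[1]

    def test_sdd_closed_forms(self):
        a = smooth_random_plane(11)
        b = a.with_values(a.values + 0.1)
        assert v.sdd(a, a) == 0.0
        assert v.sdd(a, b) == pytest.approx(0.01, rel=1e-9)
        c = a.with_values(a.values + 0.2)   # doubled residual
        assert v.sdd(a, c) == pytest.approx(4 * v.sdd(a, b), rel=1e-9)
        with pytest.raises(ValueError, match="empty"):
            v.sdd(a, b, np.zeros(a.shape, dtype=bool))


class TestAlignPlanes:
    def test_recovers_constructed_shift(self):
        """A plane displaced by (2.5, -2.5) mm is recovered to sub-step
        accuracy."""
        n = 25
        sp = 2.5
        ax = sp * (np.arange(n) - n // 2)
        SI, LR = np.meshgrid(ax, ax, indexing="ij")

        def field(x, y):
            return 2.0 * np.exp(-((x - 3) ** 2 + y**2) / 300.0) + \
                1.0 * np.exp(-((x + 15) ** 2 + (y - 10) ** 2) / 200.0)

        ref = plane(field(SI, LR), spacing=sp)
        moving = plane(field(SI - 2.5, LR + 2.5), spacing=sp)
        aligned, shift = v.align_planes(ref, moving)
        assert shift[0] == pytest.approx(2.5, abs=0.1)
        assert shift[1] == pytest.approx(-2.5, abs=0.1)
        inner = (slice(4, -4), slice(4, -4))
        assert np.allclose(aligned.values[inner], ref.values[inner],
                           atol=0.02 * ref.values.max())

    def test_identity_zero_shift(self):
        p = smooth_random_plane(12)
        aligned, shift = v.align_planes(p, p)
        assert abs(shift[0]) < 1e-6 and abs(shift[1]) < 1e-6
        assert np.allclose(aligned.values, p.values, atol=1e-9)

    def test_uniform_planes_warn_zero_shift(self):
        p = plane(np.full((10, 10), 1.0))
        with pytest.warns(UserWarning, match="featureless"):
            _, shift = v.align_planes(p, p)
        assert shift == (0.0, 0.0)


class TestExtractCoronalPlane:
    @pytest.fixture()
    def ramp_grid(self):
        n = 41
        sp = 2.0
        origin = -sp * (n - 1) / 2.0
        ax = origin + sp * np.arange(n)
        SI, AP, LR = np.meshgrid(ax, ax, ax, indexing="ij")
        vals = 5.0 + 0.02 * SI + 0.01 * LR + 0.005 * AP
        return v.DoseGrid(vals, sp, (origin,) * 3)

    def test_native_slice_identical(self, ramp_grid):
        """Grid-aligned extraction at native spacing returns stored values."""
        k = 10
        ap = ramp_grid.axis_coords(1)[k]
        p = v.extract_coronal_plane(ramp_grid, ap, 60.0, 2.0)
        i0 = int(round((p.origin[0] - ramp_grid.origin[0]) / 2.0))
        j0 = int(round((p.origin[1] - ramp_grid.origin[2]) / 2.0))
        sub = ramp_grid.values[i0:i0 + p.shape[0], k, j0:j0 + p.shape[1]]
        assert np.array_equal(p.values, sub)

    def test_linear_ramp_exact_at_any_spacing(self, ramp_grid):
        """Bilinear resampling reproduces affine fields exactly."""
        p = v.extract_coronal_plane(ramp_grid, 3.7, 50.0, 1.7)
        SI, LR = np.meshgrid(p.axis_coords(0), p.axis_coords(1), indexing="ij")
        expected = 5.0 + 0.02 * SI + 0.01 * LR + 0.005 * 3.7
        assert np.allclose(p.values, expected, atol=1e-9)

    def test_detector_roi_pixel_count(self, ramp_grid):
        """An 11 x 11 cm ROI at 2.5 mm spacing is 45 x 45 pixels."""
        big = v.DoseGrid(np.ones((61, 11, 61)), (2.5, 2.5, 2.5),
                         (-75.0, -12.5, -75.0))
        p = v.extract_coronal_plane(big, 0.0, 110.0, 2.5)
        assert p.shape == (45, 45)

    def test_roi_outside_grid_rejected(self, ramp_grid):
        with pytest.raises(ValueError, match="exceeds"):
            v.extract_coronal_plane(ramp_grid, 0.0, 200.0, 2.5)
        with pytest.raises(ValueError, match="outside grid"):
            v.extract_coronal_plane(ramp_grid, 100.0, 40.0, 2.5)


class TestDetectorResampling:
    def make_cover_plane(self, fn, spacing=1.0, half=60.0):
        n = int(2 * half / spacing) + 1
        ax = -half + spacing * np.arange(n)
        SI, LR = np.meshgrid(ax, ax, indexing="ij")
        return plane(fn(SI, LR), spacing=spacing)

    def test_uniform_plane_unchanged(self):
        p = self.make_cover_plane(lambda x, y: np.full_like(x, 2.0))
        out = v.resample_to_detector(p)
        assert np.allclose(out.values, 2.0, atol=1e-9)
        assert out.spacing == (2.5, 2.5)

    def test_linear_ramp_preserved(self):
        p = self.make_cover_plane(lambda x, y: 3.0 + 0.01 * x - 0.02 * y)
        out = v.resample_to_detector(p)
        SI, LR = np.meshgrid(out.axis_coords(0), out.axis_coords(1), indexing="ij")
        assert np.allclose(out.values, 3.0 + 0.01 * SI - 0.02 * LR, atol=1e-6)

    def test_hot_pixel_reduced_by_footprint_ratio(self):
        """A delta-like hot pixel smaller than a chamber reads reduced by
        the area ratio (oracle: numerical integration of the bilinear tent
        over the chamber footprint)."""
        sp = 0.5
        p = self.make_cover_plane(lambda x, y: np.zeros_like(x) + 0.001,
                                  spacing=sp)
        vals = p.values.copy()
        c = p.shape[0] // 2
        vals[c, c] += 1.0
        hot = p.with_values(vals)
        out = v.resample_to_detector(hot)
        k = out.shape[0] // 2
        # oracle: mean of the tent over the chamber footprint
        cs = 2.3
        xs = np.linspace(-cs / 2, cs / 2, 201)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        tent = np.clip(1 - np.abs(X) / sp, 0, None) * np.clip(1 - np.abs(Y) / sp, 0, None)
        expected = 0.001 + tent.mean()
        assert out.values[k, k] == pytest.approx(expected, rel=0.25)
        assert out.values[k, k] < 0.2   # far below the 1.0 peak

    def test_insufficient_coverage_rejected(self):
        p = self.make_cover_plane(lambda x, y: np.ones_like(x), half=40.0)
        with pytest.raises(ValueError, match="detector area"):
            v.resample_to_detector(p)
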