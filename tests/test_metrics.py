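"""Comparison metrics: gamma, DTA, dose deviation, shift search, chamber.

The gamma and DTA implementations are checked against independently coded
exhaustive-search oracles that interpolate the evaluated plane directly at
arbitrary positions (no shared code with the optimized path).
"""

import numpy as np
import pytest
from scipy import ndimage

from conftest import perturbed_pair, smooth_relative_plane
from filmqa.errors import ConsistencyError, DomainError, ExtentError
from filmqa.grids import DoseGrid3D, DosePlane2D
from filmqa.metrics import (AnalysisThresholds, ChamberSpec, DtaSpec,
                            GammaCriteria, ShiftSearchSpec, compare_chamber,
                            compute_dose_deviation, compute_dta, compute_gamma,
                            extract_center_profiles, locate_high_dose_center,
                            normalize_relative, optimize_shift,
                            summarize_comparison)

# ---------------------------------------------------------------------------
# independent oracles


def bilinear_many(vals, xs, ys):
    """Direct bilinear interpolation at arbitrary (x, y) positions in index
    units; NaN outside the support.  Written independently of the package's
    fine-lattice gather."""
    n0, n1 = vals.shape
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    out = np.full(xs.shape, np.nan)
    ok = (xs >= 0) & (ys >= 0) & (xs <= n0 - 1) & (ys <= n1 - 1)
    i = np.minimum(xs[ok].astype(int), n0 - 2)
    j = np.minimum(ys[ok].astype(int), n1 - 2)
    fx, fy = xs[ok] - i, ys[ok] - j
    out[ok] = (vals[i, j] * (1 - fx) * (1 - fy) + vals[i + 1, j] * fx * (1 - fy)
               + vals[i, j + 1] * (1 - fx) * fy + vals[i + 1, j + 1] * fx * fy)
    return out


def _disk(radius, sub):
    m = int(np.floor(radius / sub + 1e-9))
    offs = [(a * sub, b * sub) for a in range(-m, m + 1) for b in range(-m, m + 1)
            if (a * a + b * b) * sub * sub <= radius**2 + 1e-9]
    return np.array(offs)


def gamma_oracle(ref, ev, dose_tol, dist_tol, radius, sub):
    """Exhaustive gamma search on the full displacement disk at ``sub`` pitch."""
    offs = _disk(radius, sub)
    r2 = np.sum(offs**2, axis=1)
    out = np.full(ref.shape, np.nan)
    for i in range(ref.shape[0]):
        for j in range(ref.shape[1]):
            vals = bilinear_many(ev, i + offs[:, 0], j + offs[:, 1])
            g2 = r2 / dist_tol**2 + (ref[i, j] - vals) ** 2 / dose_tol**2
            out[i, j] = np.sqrt(np.nanmin(g2))
    return out


def dta_oracle(ref, ev, local_tol, radius, sub):
    """Radial brute-force DTA: smallest |s| with local dose agreement."""
    offs = _disk(radius, sub)
    dist = np.sqrt(np.sum(offs**2, axis=1))
    order = np.argsort(dist, kind="stable")
    offs, dist = offs[order], dist[order]
    out = np.full(ref.shape, np.nan)
    for i in range(ref.shape[0]):
        for j in range(ref.shape[1]):
            vals = bilinear_many(ev, i + offs[:, 0], j + offs[:, 1])
            ok = np.abs(vals - ref[i, j]) <= local_tol * abs(ref[i, j])
            out[i, j] = dist[np.argmax(ok)] if ok.any() else radius
    return out


# ---------------------------------------------------------------------------


class TestLocateHighDoseCenter:
    def test_gaussian_peak_within_half_voxel(self):
        x = np.arange(31)[:, None]
        y = np.arange(31)[None, :]
        vals = np.exp(-(((x - 14.3) ** 2) + (y - 16.7) ** 2) / (2 * 5.0**2))
        c = locate_high_dose_center(DosePlane2D(vals, [1, 1], [0, 0]))
        assert abs(c[0] - 14.3) <= 0.5 and abs(c[1] - 16.7) <= 0.5

    def test_symmetric_flat_top_exact_center(self):
        vals = np.zeros((21, 21))
        vals[8:13, 6:15] = 1.0
        c = locate_high_dose_center(DosePlane2D(vals, [1, 1], [0, 0]))
        np.testing.assert_allclose(c, [10.0, 10.0])

    def test_zero_plane_rejected(self):
        with pytest.raises(DomainError):
            locate_high_dose_center(DosePlane2D(np.zeros((5, 5)), [1, 1], [0, 0]))


class TestNormalizeRelative:
    def test_uniform_plane(self):
        p = DosePlane2D(np.full((25, 25), 5.0), [1, 1], [0, 0])
        out = normalize_relative(p, [12.0, 12.0])
        assert out.norm_dose == 5.0
        np.testing.assert_allclose(out.values, 1.0)

    def test_matches_sort_and_pick_median_oracle(self, rng):
        vals = ndimage.gaussian_filter(rng.uniform(1, 4, (31, 31)), 2,
                                       mode="nearest")
        p = DosePlane2D(vals, [1, 1], [0, 0])
        center = np.array([15.0, 15.0])
        out = normalize_relative(p, center, radius_mm=10.0)
        inside = []
        for i in range(31):
            for j in range(31):
                if (i - 15) ** 2 + (j - 15) ** 2 <= 100 + 1e-9:
                    inside.append(vals[i, j])
        inside = np.sort(inside)
        n = len(inside)
        med = inside[n // 2] if n % 2 else 0.5 * (inside[n // 2 - 1] + inside[n // 2])
        assert abs(out.norm_dose - med) < 1e-12

    def test_idempotent_on_relative_input(self, rng):
        vals = ndimage.gaussian_filter(rng.uniform(1, 4, (31, 31)), 2,
                                       mode="nearest")
        p = DosePlane2D(vals, [1, 1], [0, 0])
        once = normalize_relative(p, [15.0, 15.0])
        twice = normalize_relative(once, [15.0, 15.0])
        assert abs(twice.values[3, 3] / once.values[3, 3] - 1) < 1e-12
        assert abs(twice.norm_dose - once.norm_dose) < 1e-12


def shifted_copy(plane, shift):
    vals = ndimage.shift(plane.values, shift, order=1, mode="nearest")
    return DosePlane2D(vals, plane.spacing, plane.origin, True, 1.0)


class TestOptimizeShift:
    def field(self, rng):
        return smooth_relative_plane(rng, shape=(41, 41), sigma=5.0)

    def test_identity_gives_zero_shift(self, rng):
        p = self.field(rng)
        shift, _ = optimize_shift(p, p)
        np.testing.assert_allclose(shift, 0.0)

    def test_forward_shift_recovered_within_one_step(self, rng):
        calc = self.field(rng)
        meas = shifted_copy(calc, (1.0, -0.5))    # meas(r) = calc(r - (1,-0.5))
        shift, _ = optimize_shift(meas, calc)
        assert abs(shift[0] - (-1.0)) <= 0.1 + 1e-9
        assert abs(shift[1] - 0.5) <= 0.1 + 1e-9

    def test_out_of_bound_displacement_clamps(self, rng):
        calc = self.field(rng)
        meas = shifted_copy(calc, (2.5, 0.0))
        shift, _ = optimize_shift(meas, calc)
        assert abs(abs(shift[0]) - 1.5) < 1e-9    # on the search bound


class TestComputeGamma:
    def test_identity_zero_everywhere_pass_100(self, rng):
        p = smooth_relative_plane(rng)
        g, rates = compute_gamma(p, p)
        np.testing.assert_allclose(g[np.isfinite(g)], 0.0)
        assert rates[0.1] == 100.0 and rates[0.9] == 100.0

    def test_uniform_three_percent_offset_gives_gamma_1p5(self):
        ref = DosePlane2D(np.full((12, 12), 1.0), [1, 1], [0, 0], True, 1.0)
        ev = DosePlane2D(np.full((12, 12), 1.03), [1, 1], [0, 0], True, 1.0)
        g, rates = compute_gamma(ref, ev)
        np.testing.assert_allclose(g, 1.5, atol=1e-12)
        assert rates[0.1] == 0.0 and rates[0.9] == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref, ev = perturbed_pair(rng)
        crit = GammaCriteria(0.02, 2.0, 3.0, 0.05)
        g, _ = compute_gamma(ref, ev, crit)
        oracle = gamma_oracle(ref.values, ev.values, 0.02, 2.0, 3.0, 0.05)
        np.testing.assert_allclose(g, oracle, atol=1e-6)

    def test_never_exceeds_no_search_value_and_radius_monotone(self, rng):
        ref, ev = perturbed_pair(rng)
        crit_small = GammaCriteria(0.02, 2.0, 2.0, 0.1)
        crit_large = GammaCriteria(0.02, 2.0, 4.0, 0.1)
        g_small, _ = compute_gamma(ref, ev, crit_small)
        g_large, _ = compute_gamma(ref, ev, crit_large)
        no_search = np.abs(ref.values - ev.values) / 0.02
        assert np.all(g_small <= no_search + 1e-9)
        assert np.all(g_large <= g_small + 1e-9)

    def test_invariant_under_common_translation(self, rng):
        ref, ev = perturbed_pair(rng, shape=(21, 21))
        g0, _ = compute_gamma(ref, ev, GammaCriteria(0.02, 2.0, 3.0, 0.1))
        rolled_ref = DosePlane2D(np.roll(ref.values, 2, axis=0), [1, 1], [0, 0],
                                 True, 1.0)
        rolled_ev = DosePlane2D(np.roll(ev.values, 2, axis=0), [1, 1], [0, 0],
                                True, 1.0)
        g1, _ = compute_gamma(rolled_ref, rolled_ev,
                              GammaCriteria(0.02, 2.0, 3.0, 0.1))
        # compare away from the wrap seam and the search-disk boundary layer
        np.testing.assert_allclose(g1[6:17, 4:17], g0[4:15, 4:17], atol=1e-9)

    def test_high_threshold_selection_is_subset_of_low(self, rng):
        ref, ev = perturbed_pair(rng)
        dmax = np.nanmax(ev.values)
        low_sel = ref.values >= 0.1 * dmax
        high_sel = ref.values >= 0.9 * dmax
        assert np.all(low_sel[high_sel])


class TestDoseDeviation:
    def test_identity_and_constant_offset(self, rng):
        p = smooth_relative_plane(rng)
        dev, stats = compute_dose_deviation(p, p)
        np.testing.assert_allclose(dev, 0.0)
        assert stats[0.1] == (0.0, 0.0)
        ev = DosePlane2D(p.values - 0.017, [1, 1], [0, 0], True, 1.0)
        dev, stats = compute_dose_deviation(p, ev)
        np.testing.assert_allclose(dev, 1.7, atol=1e-9)
        np.testing.assert_allclose(stats[0.1][0], 1.7, atol=1e-9)

    def test_stats_match_direct_oracle(self, rng):
        ref, ev = perturbed_pair(rng)
        dev, stats = compute_dose_deviation(ref, ev)
        dmax = np.nanmax(ev.values)
        sel = ref.values >= 0.1 * dmax
        expect = 100 * (ref.values[sel] - ev.values[sel])
        np.testing.assert_allclose(stats[0.1], (expect.mean(), expect.std()),
                                   atol=1e-9)


class TestComputeDta:
    def test_identity_zero(self, rng):
        p = smooth_relative_plane(rng)
        dta, stats, sat = compute_dta(p, p)
        assert np.all(dta[np.isfinite(dta)] == 0.0)
        assert stats[0] == 0.0 and not sat.any()

    def test_linear_ramp_closed_form(self):
        """Reference d=1.0 with gradient g=0.04/mm; evaluated shifted 2 mm:
        DTA = s - local_tol*d/g = 1.875 mm."""
        x = np.arange(21.0)
        ref_vals = np.tile(1.0 + 0.04 * (x - 10.0), (9, 1)).T
        ev_vals = np.tile(1.0 + 0.04 * (x - 12.0), (9, 1)).T
        ref = DosePlane2D(ref_vals, [1, 1], [0, 0], True, 1.0)
        ev = DosePlane2D(ev_vals, [1, 1], [0, 0], True, 1.0)
        spec = DtaSpec(0.005, (0.10, 0.90), 4.0, 0.05)
        dta, _, _ = compute_dta(ref, ev, spec)
        assert abs(dta[10, 4] - 1.875) <= 0.05 + 1e-9

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_radial_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref, ev = perturbed_pair(rng)
        spec = DtaSpec(0.02, (0.10, 0.90), 3.0, 0.1)
        dta, _, _ = compute_dta(ref, ev, spec)
        oracle = dta_oracle(ref.values, ev.values, 0.02, 3.0, 0.1)
        sel = np.isfinite(dta)
        assert np.all(np.abs(dta[sel] - oracle[sel]) <= 0.1 + 1e-9)

    def test_larger_local_tol_never_increases_dta(self, rng):
        ref, ev = perturbed_pair(rng)
        tight, _, _ = compute_dta(ref, ev, DtaSpec(0.005, (0.1, 0.9), 4.0, 0.1))
        loose, _, _ = compute_dta(ref, ev, DtaSpec(0.02, (0.1, 0.9), 4.0, 0.1))
        sel = np.isfinite(tight) & np.isfinite(loose)
        assert np.all(loose[sel] <= tight[sel] + 1e-12)

    def test_saturated_voxels_carry_cap(self):
        ref = DosePlane2D(np.full((9, 9), 1.0), [1, 1], [0, 0], True, 1.0)
        ev = DosePlane2D(np.full((9, 9), 0.5), [1, 1], [0, 0], True, 1.0)
        spec = DtaSpec(0.005, (0.10, 0.90), 3.0, 0.5)
        dta, _, sat = compute_dta(ref, ev, spec, AnalysisThresholds())
        assert sat.all() and np.all(dta == 3.0)


class TestProfilesAndChamber:
    def test_identity_profiles_zero_pp(self, rng):
        p = smooth_relative_plane(rng, shape=(21, 21))
        prof = extract_center_profiles(p, p, [10.0, 10.0])
        np.testing.assert_allclose(prof["inline"]["diff_pp"], 0.0)
        assert prof["crossline"]["max_abs_pp"] == 0.0

    def test_constant_offset_reads_in_percentage_points(self, rng):
        p = smooth_relative_plane(rng, shape=(21, 21))
        ev = DosePlane2D(p.values - 0.012, [1, 1], [0, 0], True, 1.0)
        prof = extract_center_profiles(p, ev, [10.0, 10.0])
        np.testing.assert_allclose(prof["inline"]["diff_pp"], 1.2, atol=1e-9)

    def test_penumbra_shift_peaks_inside_penumbra_band(self):
        from scipy.special import erf
        x = np.arange(41.0)
        edge = lambda t: 0.5 * (1 + erf((20.0 - t) / (3.0 * np.sqrt(2))))
        calc = np.tile(edge(x), (21, 1)).T
        meas = np.tile(edge(x - 1.0), (21, 1)).T
        ref = DosePlane2D(meas, [1, 1], [0, 0], True, 1.0)
        ev = DosePlane2D(calc, [1, 1], [0, 0], True, 1.0)
        prof = extract_center_profiles(ref, ev, [10.0, 10.0])
        k = int(np.argmax(np.abs(prof["crossline"]["diff_pp"])))
        dmax = calc.max()
        assert 0.2 * dmax <= calc[k, 10] <= 0.8 * dmax

    def test_center_out_of_bounds_rejected(self, rng):
        p = smooth_relative_plane(rng)
        with pytest.raises(DomainError):
            extract_center_profiles(p, p, [99.0, 2.0])

    def test_chamber_uniform_and_linear_fields(self):
        n = 21
        coords = np.arange(n) - 10.0
        uniform = DoseGrid3D(np.full((n, n, n), 2.0), [-10, -10, -10], [1, 1, 1])
        assert compare_chamber(2.0, uniform, ChamberSpec([0, 0, 0], 3.0)) == 0.0
        x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")
        linear = DoseGrid3D(2.0 + 0.01 * x + 0.02 * y - 0.005 * z,
                            [-10, -10, -10], [1, 1, 1])
        diff = compare_chamber(2.0, linear, ChamberSpec([0, 0, 0], 3.0))
        assert abs(diff) < 1e-10   # odd terms cancel: sphere mean = center value

    def test_chamber_quadratic_field_closed_form(self):
        n = 41
        coords = 0.5 * np.arange(n) - 10.0
        x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")
        a, d0, r = 0.01, 2.0, 3.0
        vals = d0 + a * (x * x + y * y + z * z)
        grid = DoseGrid3D(vals, [-10, -10, -10], [0.5, 0.5, 0.5])
        measured = d0 + 0.6 * a * r * r   # continuum sphere mean
        diff = compare_chamber(measured, grid, ChamberSpec([0, 0, 0], r))
        # discrete 0.5 mm sub-lattice vs continuum: within 2% of the a-term
        assert abs(diff / 100.0 * (d0 + 0.6 * a * r * r)) <= 0.02 * a * r * r

    def test_sphere_outside_grid_rejected(self):
        grid = DoseGrid3D(np.ones((5, 5, 5)), [0, 0, 0], [1, 1, 1])
        with pytest.raises(ExtentError):
            compare_chamber(1.0, grid, ChamberSpec([0, 0, 0], 3.0))


class TestSummarize:
    def test_identity_row(self, rng):
        p = smooth_relative_plane(rng)
        g, rates = compute_gamma(p, p)
        dev, dev_stats = compute_dose_deviation(p, p)
        dta, dta_stats, sat = compute_dta(p, p)
        res = summarize_comparison("id0", g, rates, dev, dev_stats, dta,
                                   dta_stats, sat, [0.0, 0.0], 1.0, 1.0)
        row = res.to_row()
        assert row["gamma_pass_10_pct"] == 100.0
        assert row["gamma_pass_90_pct"] == 100.0
        assert row["dev_mean_10_pct"] == 0.0 and row["dev_sd_10_pct"] == 0.0
        assert row["dta_mean_mm"] == 0.0 and row["dta_sd_mm"] == 0.0

    def test_geometry_mismatch_rejected(self, rng):
        p = smooth_relative_plane(rng)
        g, rates = compute_gamma(p, p)
        dev, dev_stats = compute_dose_deviation(p, p)
        with pytest.raises(ConsistencyError):
            summarize_comparison("bad", g, rates, dev[:10], dev_stats,
                                 np.zeros_like(g), (0, 0),
                                 np.zeros_like(g, dtype=bool),
                                 [0, 0], 1.0, 1.0)
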