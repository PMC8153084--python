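"""WTMM engine tests: transform, chains, skeleton, partition functions,
scaling fits, Legendre spectrum, monofractality screening."""

import numpy as np
import pytest

from mammofractal import ScaleFamily, estimate_hurst, generate_fbm_surface
from mammofractal.wtmm import (
    MaximaLine,
    PartitionFunctionSet,
    Skeleton,
    assess_monofractality,
    build_skeleton,
    chain_maxima_points,
    compute_partition_functions,
    default_q_grid,
    extract_wtmm_chains,
    fit_tau,
    gradient_wavelet_transform,
    legendre_spectrum,
    select_scaling_range,
    wtmm_mask,
)


def make_pfs(scales, log2_z_fn, n_lines=1000):
    """Synthetic partition-function set with log2 Z(q, a) = log2_z_fn(q, a)."""
    q = default_q_grid()
    scales = np.asarray(scales, float)
    lz = np.array([[log2_z_fn(qq, a) for a in scales] for qq in q])
    return PartitionFunctionSet(
        q_grid=q,
        scales=scales,
        log2_z=lz,
        n_lines=np.full(scales.size, n_lines),
        h_qa=np.zeros_like(lz),
        d_qa=np.zeros_like(lz),
    )


def make_skeleton(lines_spec, scales):
    """Skeleton from (first_index, moduli-list) pairs."""
    lines = []
    for first, mods in lines_spec:
        ln = MaximaLine(first_scale_index=first)
        for j, m in enumerate(mods):
            ln.rows.append(10 + j)
            ln.cols.append(10)
            ln.modulus.append(float(m))
        lines.append(ln)
    return Skeleton(scales=np.asarray(scales, float), lines=lines)


class TestGradientTransform:
    def test_constant_image_zero_modulus(self, small_scales):
        f = gradient_wavelet_transform(np.full((64, 64), 3.0), small_scales)
        assert np.allclose(f.modulus, 0.0)
        assert all(extract_wtmm_chains(f, i) == [] for i in range(len(small_scales)))

    def test_planar_ramp_gradient(self, small_scales):
        x = np.tile(np.arange(128.0), (128, 1))
        f = gradient_wavelet_transform(x, small_scales)
        inner = (slice(40, 88), slice(40, 88))
        a = f.scales[3]
        # gradient along +x, argument zero, modulus = 2*pi*a * slope
        assert np.abs(f.argument[3][inner]).max() < 1e-12
        assert f.modulus[3][inner] == pytest.approx(2 * np.pi * a, rel=1e-10)

    def test_linearity(self, small_scales):
        rng = np.random.default_rng(0)
        fa = rng.standard_normal((64, 64))
        fb = rng.standard_normal((64, 64))
        ta = gradient_wavelet_transform(fa, small_scales)
        tb = gradient_wavelet_transform(fb, small_scales)
        tab = gradient_wavelet_transform(fa + fb, small_scales)
        assert np.allclose(tab.smoothed, ta.smoothed + tb.smoothed, atol=1e-10)
        # gradient components are linear; modulus is not, so compare vectors
        for t in (ta, tb, tab):
            t.gx = t.modulus * np.cos(t.argument) / t.scales[:, None, None]
            t.gy = t.modulus * np.sin(t.argument) / t.scales[:, None, None]
        assert np.allclose(tab.gx, ta.gx + tb.gx, atol=1e-10)
        assert np.allclose(tab.gy, ta.gy + tb.gy, atol=1e-10)

    def test_scale_too_large_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            gradient_wavelet_transform(np.zeros((32, 32)), ScaleFamily.log_spaced(2, 40, 10))

    def test_gaussian_bump_ring_maximum(self, small_scales):
        """Convolving two Gaussians gives a Gaussian of width sqrt(s0^2+a^2);
        the gradient modulus then peaks on the ring r = sqrt(s0^2 + a^2)."""
        s0 = 6.0
        rr, cc = np.mgrid[0:128, 0:128]
        bump = np.exp(-((rr - 64) ** 2 + (cc - 64) ** 2) / (2 * s0**2))
        f = gradient_wavelet_transform(bump, small_scales)
        i = 5
        a = f.scales[i]
        r_expected = np.sqrt(s0**2 + a**2)
        best = np.unravel_index(np.argmax(f.modulus[i]), f.modulus[i].shape)
        r_observed = np.hypot(best[0] - 64, best[1] - 64)
        assert r_observed == pytest.approx(r_expected, abs=1.0)
        # isotropy: modulus nearly constant along the ring
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        ring = f.modulus[i][
            np.round(64 + r_expected * np.sin(theta)).astype(int),
            np.round(64 + r_expected * np.cos(theta)).astype(int),
        ]
        assert np.ptp(ring) / ring.mean() < 0.05


class TestChains:
    def test_step_edge_single_chain(self, small_scales):
        img = np.zeros((96, 96))
        img[:, 48:] = 10.0
        f = gradient_wavelet_transform(img, small_scales)
        chains = extract_wtmm_chains(f, 4)
        assert len(chains) == 1
        assert np.all(np.abs(chains[0].cols - 47.5) <= 1)  # traces the edge

    def test_gaussian_bump_one_ring_chain(self, small_scales):
        s0 = 6.0
        rr, cc = np.mgrid[0:128, 0:128]
        bump = np.exp(-((rr - 64) ** 2 + (cc - 64) ** 2) / (2 * s0**2))
        f = gradient_wavelet_transform(bump, small_scales)
        chains = extract_wtmm_chains(f, 5)
        assert len(chains) == 1
        a = f.scales[5]
        radii = np.hypot(chains[0].rows - 64.0, chains[0].cols - 64.0)
        assert np.all(np.abs(radii - np.sqrt(s0**2 + a**2)) < 2.0)

    def test_maxima_mask_matches_bruteforce_definition(self, noise_field):
        """Criterion oracle: pixel-by-pixel re-scan of the WTMM definition
        (strict maximum along the gradient, bilinear interpolation)."""
        from mammofractal.wtmm import _modulus_floor, border_exclusion

        for i in (0, 4, 9):
            m = noise_field.modulus[i]
            phi = noise_field.argument[i]
            floor = _modulus_floor(noise_field, i)
            b = border_exclusion(noise_field.scales[i])
            n_r, n_c = m.shape
            expected = np.zeros_like(m, dtype=bool)

            def interp(r, c):
                r = min(max(r, 0.0), n_r - 1.0)
                c = min(max(c, 0.0), n_c - 1.0)
                r0, c0 = int(np.floor(r)), int(np.floor(c))
                r1, c1 = min(r0 + 1, n_r - 1), min(c0 + 1, n_c - 1)
                fr, fc = r - r0, c - c0
                return (
                    m[r0, c0] * (1 - fr) * (1 - fc)
                    + m[r1, c0] * fr * (1 - fc)
                    + m[r0, c1] * (1 - fr) * fc
                    + m[r1, c1] * fr * fc
                )

            for r in range(b, n_r - b):
                for c in range(b, n_c - b):
                    dr, dc = np.sin(phi[r, c]), np.cos(phi[r, c])
                    ahead = interp(r + dr, c + dc)
                    behind = interp(r - dr, c - dc)
                    expected[r, c] = (
                        m[r, c] > ahead and m[r, c] >= behind and m[r, c] > floor
                    )
            assert np.array_equal(wtmm_mask(noise_field, i), expected)

    def test_chain_maxima_match_bruteforce_rescan(self, noise_field):
        """Along-chain maxima equal a direct re-scan of the definition."""
        chains = extract_wtmm_chains(noise_field, 2)
        rows, cols, mods = chain_maxima_points(chains)
        got = set(zip(rows.tolist(), cols.tolist()))

        expected = set()
        for ch in chains:
            pix = {(r, c): m for r, c, m in zip(ch.rows, ch.cols, ch.modulus)}
            cand = []
            for (r, c), m in pix.items():
                neigh = [
                    pix[(r + dr, c + dc)]
                    for dr in (-1, 0, 1)
                    for dc in (-1, 0, 1)
                    if (dr, dc) != (0, 0) and (r + dr, c + dc) in pix
                ]
                if all(m >= v for v in neigh):
                    cand.append((r, c, m))
            # plateau: first raster pixel of each equal-valued connected run
            cand.sort()
            taken = []
            for r, c, m in cand:
                if any(abs(r - r2) <= 1 and abs(c - c2) <= 1 and m == m2 for r2, c2, m2 in taken):
                    continue
                taken.append((r, c, m))
            expected |= {(r, c) for r, c, _ in taken}
        assert got == expected

    def test_min_chain_length_filter(self, noise_field):
        short = extract_wtmm_chains(noise_field, 0, min_chain_len=1)
        long = extract_wtmm_chains(noise_field, 0, min_chain_len=5)
        assert len(short) >= len(long)
        assert all(len(c) >= 5 for c in long)


class TestSkeleton:
    def test_isolated_cusp_single_line_converges(self):
        """A |r - r0|^0.5 cusp produces maxima lines that home in on r0."""
        rr, cc = np.mgrid[0:128, 0:128]
        img = np.sqrt(np.hypot(rr - 64.0, cc - 64.0))
        fam = ScaleFamily.log_spaced(2, 12, 12)
        f = gradient_wavelet_transform(img, fam)
        chains = [extract_wtmm_chains(f, i) for i in range(len(fam))]
        skel = build_skeleton(chains, fam.scales)
        long_lines = [ln for ln in skel.lines if ln.first_scale_index == 0 and len(ln.rows) >= 8]
        assert long_lines
        d0 = min(np.hypot(ln.rows[0] - 64, ln.cols[0] - 64) for ln in long_lines)
        assert d0 < 4.0

    def test_two_distant_bumps_two_line_clusters(self):
        rr, cc = np.mgrid[0:192, 0:192]
        img = np.exp(-((rr - 48.0) ** 2 + (cc - 48.0) ** 2) / 18.0) + np.exp(
            -((rr - 144.0) ** 2 + (cc - 144.0) ** 2) / 18.0
        )
        fam = ScaleFamily.log_spaced(2, 8, 10)
        f = gradient_wavelet_transform(img, fam)
        chains = [extract_wtmm_chains(f, i) for i in range(len(fam))]
        skel = build_skeleton(chains, fam.scales)
        roots = np.array([[ln.rows[0], ln.cols[0]] for ln in skel.lines if ln.first_scale_index == 0])
        near_a = np.hypot(roots[:, 0] - 48, roots[:, 1] - 48) < 30
        near_b = np.hypot(roots[:, 0] - 144, roots[:, 1] - 144) < 30
        assert near_a.any() and near_b.any()
        assert np.all(near_a | near_b)

    def test_line_count_equals_maxima_at_smallest_scale(self, noise_field, small_scales):
        chains = [extract_wtmm_chains(noise_field, i) for i in range(len(small_scales))]
        skel = build_skeleton(chains, small_scales.scales)
        r, c, _ = chain_maxima_points(chains[0])
        n_root = sum(1 for ln in skel.lines if ln.first_scale_index == 0)
        assert n_root == r.size


class TestPartitionFunctions:
    def test_q0_counts_lines(self, small_scales):
        skel = make_skeleton([(0, [2] * 10), (0, [4] * 10), (0, [8] * 10)], small_scales.scales)
        pfs = compute_partition_functions(skel)
        i0 = np.argmin(np.abs(pfs.q_grid))
        assert np.allclose(2.0 ** pfs.log2_z[i0], 3.0)

    def test_hand_built_moduli_q2(self, small_scales):
        skel = make_skeleton([(0, [2] * 10), (0, [4] * 10), (0, [8] * 10)], small_scales.scales)
        pfs = compute_partition_functions(skel)
        assert pfs.z(2.0, 0) == pytest.approx(4 + 16 + 64)

    def test_single_line_power(self, small_scales):
        skel = make_skeleton([(0, [5.0] * 10)], small_scales.scales)
        pfs = compute_partition_functions(skel)
        for q in (-2.0, -1.0, 1.0, 3.0):
            assert pfs.z(q, 3) == pytest.approx(5.0**q)

    def test_sup_statistic_uses_running_maximum(self, small_scales):
        skel = make_skeleton([(0, [2.0, 1.0, 3.0] + [3.0] * 7)], small_scales.scales)
        sup = compute_partition_functions(skel, line_statistic="sup")
        inst = compute_partition_functions(skel, line_statistic="modulus")
        assert sup.z(1.0, 1) == pytest.approx(2.0)  # sup of {2, 1}
        assert inst.z(1.0, 1) == pytest.approx(1.0)  # value at the scale

    def test_non_root_lines_excluded_by_default(self, small_scales):
        skel = make_skeleton([(0, [2.0] * 10), (3, [9.0] * 7)], small_scales.scales)
        pfs = compute_partition_functions(skel)
        i0 = np.argmin(np.abs(pfs.q_grid))
        assert np.allclose(2.0 ** pfs.log2_z[i0], 1.0)
        pfs_all = compute_partition_functions(skel, require_root=False)
        assert 2.0 ** pfs_all.log2_z[i0, 5] == pytest.approx(2.0)

    def test_generalized_mean_monotone_in_q(self, small_scales):
        """(1/q) log Z is non-decreasing in q (power-mean inequality) on any
        skeleton with at least two distinct line values."""
        skel = make_skeleton(
            [(0, [1.0] * 10), (0, [3.0] * 10), (0, [7.5] * 10)], small_scales.scales
        )
        pfs = compute_partition_functions(skel)
        q = pfs.q_grid
        nz = q != 0
        # power mean: (1/q) log2( Z(q)/Z(0) ) is non-decreasing in q
        gm = (pfs.log2_z[nz, 4] - np.log2(3.0)) / q[nz]
        assert np.all(np.diff(gm) > -1e-9)

    def test_empty_scales_dropped_with_warning(self, small_scales):
        skel = make_skeleton([(0, [2.0] * 5)], small_scales.scales)  # dies mid-way
        with pytest.warns(UserWarning, match="empty"):
            pfs = compute_partition_functions(skel)
        assert pfs.scales.size == 5

    def test_z0_equals_line_count_on_real_surface(self, fbm_half, small_scales):
        f = gradient_wavelet_transform(fbm_half.values[:128, :128], small_scales)
        chains = [extract_wtmm_chains(f, i) for i in range(len(small_scales))]
        skel = build_skeleton(chains, small_scales.scales)
        pfs = compute_partition_functions(skel)
        i0 = np.argmin(np.abs(pfs.q_grid))
        counts = 2.0 ** pfs.log2_z[i0]
        for col, a_idx in enumerate(range(pfs.scales.size)):
            assert counts[col] == pytest.approx(skel.n_lines_at(a_idx), abs=1e-9)


class TestScalingRange:
    scales = np.geomspace(2, 32, 16)

    def test_exact_power_law_full_range(self):
        pfs = make_pfs(self.scales, lambda q, a: (0.5 * q - 2) * np.log2(a))
        sel = select_scaling_range(pfs)
        assert sel.status == "ok"
        assert sel.i_lo == 0 and sel.i_hi == self.scales.size - 1

    def test_piecewise_fixture_selects_upper_half(self):
        # scaling only above a = 8; below, a non-linear plateau with wiggles
        def lz(q, a):
            if a >= 8.0:
                return (0.5 * q - 2) * np.log2(a)
            return (0.5 * q - 2) * np.log2(8.0) + 0.4 * np.sin(7.0 * a) * (1 + abs(q))

        pfs = make_pfs(self.scales, lz)
        sel = select_scaling_range(pfs)
        assert sel.status == "ok"
        assert sel.a_lo >= 8.0 * 0.99

    def test_shuffled_noise_rejected(self):
        rng = np.random.default_rng(3)
        noise = rng.permutation(16) * 1.0
        pfs = make_pfs(self.scales, lambda q, a: noise[np.searchsorted(self.scales, a)] * (1 + abs(q)))
        sel = select_scaling_range(pfs)
        assert sel.status == "rejected"
        assert sel.reason == "no-scaling"

    def test_low_statistics_scales_excluded(self):
        pfs = make_pfs(self.scales, lambda q, a: (0.5 * q - 2) * np.log2(a))
        pfs.n_lines = np.array([1000] * 10 + [5] * 6)
        sel = select_scaling_range(pfs)
        assert sel.status == "ok"
        assert sel.i_hi <= 9


class TestTauFit:
    scales = np.geomspace(2, 32, 16)

    def test_exact_power_law_machine_precision(self):
        pfs = make_pfs(self.scales, lambda q, a: (0.5 * q - 2) * np.log2(a))
        fit = fit_tau(pfs, select_scaling_range(pfs))
        assert fit.status == "ok"
        assert np.allclose(fit.tau, 0.5 * fit.q_grid - 2, atol=1e-12)
        assert np.allclose(fit.stderr, 0.0, atol=1e-12)

    def test_short_range_rejected(self):
        from mammofractal.wtmm import RangeSelection

        pfs = make_pfs(self.scales, lambda q, a: (0.5 * q - 2) * np.log2(a))
        sel = RangeSelection(status="ok", i_lo=0, i_hi=2, a_lo=2.0, a_hi=2.9)
        fit = fit_tau(pfs, sel)
        assert fit.status == "rejected"


class TestLegendre:
    def make_fit(self, tau_fn):
        from mammofractal.wtmm import ScalingFit

        q = default_q_grid()
        tau = np.array([tau_fn(qq) for qq in q])
        return ScalingFit(q, tau, np.zeros_like(q), np.ones_like(q), (2.0, 32.0), "ok")

    def test_linear_tau_single_point(self):
        spec = legendre_spectrum(self.make_fit(lambda q: 0.5 * q - 2))
        assert np.allclose(spec.h, 0.5, atol=1e-12)
        assert np.allclose(spec.d, 2.0, atol=1e-12)

    def test_kinked_tau_spans_h_range(self):
        spec = legendre_spectrum(self.make_fit(lambda q: -2 + (0.3 if q < 0 else 0.7) * q))
        assert spec.h.min() == pytest.approx(0.3, abs=1e-9)
        assert spec.h.max() == pytest.approx(0.7, abs=1e-9)

    def test_quadratic_tau_parabolic_spectrum(self):
        spec = legendre_spectrum(self.make_fit(lambda q: -2 + 0.5 * q - 0.05 * q * q))
        # analytic Legendre: h = 0.5 - 0.1 q, D = 2 - 0.05 q^2 = 2 - 5 (h - 0.5)^2
        interior = slice(1, -1)
        assert np.allclose(spec.h[interior], 0.5 - 0.1 * spec.q_grid[interior], atol=1e-9)
        assert np.allclose(
            spec.d[interior], 2 - 5 * (spec.h[interior] - 0.5) ** 2, atol=1e-9
        )
        assert spec.d.max() <= 2.0 + 1e-9
        assert spec.concave


class TestMonofractality:
    def make_fit(self, tau_fn, stderr=0.0):
        from mammofractal.wtmm import ScalingFit

        q = default_q_grid()
        tau = np.array([tau_fn(qq) for qq in q])
        return ScalingFit(
            q, tau, np.full_like(q, stderr), np.ones_like(q), (2.0, 32.0), "ok"
        )

    def test_linear_tau_accepted_with_slope(self):
        est = assess_monofractality(self.make_fit(lambda q: 0.62 * q - 2))
        assert est.status == "ok" and est.monofractal
        assert est.hurst == pytest.approx(0.62, abs=1e-9)

    def test_strong_curvature_rejected(self):
        est = assess_monofractality(self.make_fit(lambda q: -2 + 0.5 * q - 0.2 * q * q))
        assert est.status == "rejected"
        assert est.reason == "multifractal"

    def test_fbm_patch_accepted_in_band(self):
        img = generate_fbm_surface(256, 0.7, seed=12345)
        est = estimate_hurst(img)
        assert est.status == "ok"
        assert 0.6 <= est.hurst <= 0.8
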