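"""Metrics and quantification against brute-force and analytic oracles."""

import numpy as np
import pytest

from scarseg.core import VoxelGeometry
from scarseg.phantom import PhantomSpec, analytic_scar_area_mm2, generate_slice
from scarseg.quantify import (
    MYOCARDIAL_DENSITY_G_PER_CM3,
    boundary_pixels,
    dsc,
    fwhm_segment,
    hausdorff_mm,
    mass_error,
    scar_mass,
)


def brute_dsc(a, b):
    inter = sum(
        1 for i in range(a.shape[0]) for j in range(a.shape[1]) if a[i, j] and b[i, j]
    )
    sa = int(a.sum())
    sb = int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * inter / (sa + sb)


def brute_hausdorff(a, b, sr, sc):
    """All-pairs directed max-min over boundary pixels."""

    def boundary(m):
        pts = []
        for i in range(m.shape[0]):
            for j in range(m.shape[1]):
                if not m[i, j]:
                    continue
                nb = [
                    m[i - 1, j] if i > 0 else False,
                    m[i + 1, j] if i < m.shape[0] - 1 else False,
                    m[i, j - 1] if j > 0 else False,
                    m[i, j + 1] if j < m.shape[1] - 1 else False,
                ]
                if not all(nb):
                    pts.append((i * sr, j * sc))
        return pts

    pa, pb = boundary(a), boundary(b)
    d_ab = max(min(np.hypot(x1 - x2, y1 - y2) for x2, y2 in pb) for x1, y1 in pa)
    d_ba = max(min(np.hypot(x1 - x2, y1 - y2) for x2, y2 in pa) for x1, y1 in pb)
    return max(d_ab, d_ba)


class TestDsc:
    def test_identical_nonempty_is_one(self, clean_slice):
        assert dsc(clean_slice.scar_mask, clean_slice.scar_mask) == 1.0

    def test_half_overlap(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[:5, :20] = True  # 100
        b[2:7, :20] = True  # 100, overlap rows 2..4 = 60... construct exact 50
        a[:] = False
        b[:] = False
        a[0:5, 0:20] = True
        b[0:5, 10:20] = True
        b[5:10, 0:10] = True
        assert dsc(a, b) == pytest.approx(0.5)

    def test_empty_cases(self):
        z = np.zeros((8, 8), bool)
        o = np.ones((8, 8), bool)
        assert dsc(z, z) == 1.0
        assert dsc(z, o) == 0.0

    def test_matches_pixel_loop_oracle(self, rng):
        for _ in range(25):
            a = rng.random((32, 32)) > 0.7
            b = rng.random((32, 32)) > 0.7
            assert dsc(a, b) == pytest.approx(brute_dsc(a, b), abs=1e-12)

    def test_symmetry(self, rng):
        a = rng.random((16, 16)) > 0.6
        b = rng.random((16, 16)) > 0.6
        assert dsc(a, b) == dsc(b, a)


class TestHausdorff:
    def test_identical_masks_zero(self, unit_geometry):
        m = np.zeros((16, 16), bool)
        m[4:9, 4:9] = True
        assert hausdorff_mm(m, m, unit_geometry) == 0.0

    def test_three_four_five(self, unit_geometry):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = True
        b[3, 4] = True
        assert hausdorff_mm(a, b, unit_geometry) == pytest.approx(5.0)

    def test_anisotropic_spacing(self):
        g = VoxelGeometry(2.0, 0.5, 8.0)
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = True
        b[1, 4] = True  # 2 mm down, 2 mm right
        assert hausdorff_mm(a, b, g) == pytest.approx(np.hypot(2.0, 2.0))

    def test_empty_mask_is_undefined(self, unit_geometry):
        m = np.zeros((8, 8), bool)
        n = m.copy()
        n[2, 2] = True
        assert hausdorff_mm(m, n, unit_geometry) is None

    def test_matches_all_pairs_oracle(self, rng, unit_geometry):
        for _ in range(15):
            a = rng.random((24, 24)) > 0.8
            b = rng.random((24, 24)) > 0.8
            if not a.any() or not b.any():
                continue
            assert hausdorff_mm(a, b, unit_geometry) == pytest.approx(
                brute_hausdorff(a, b, 1.0, 1.0), abs=1e-9
            )

    def test_symmetric_and_triangle_inequality(self, rng, unit_geometry):
        masks = [rng.random((16, 16)) > 0.75 for _ in range(3)]
        if all(m.any() for m in masks):
            a, b, c = masks
            dab = hausdorff_mm(a, b, unit_geometry)
            dba = hausdorff_mm(b, a, unit_geometry)
            dac = hausdorff_mm(a, c, unit_geometry)
            dcb = hausdorff_mm(c, b, unit_geometry)
            assert dab == dba
            assert dab <= dac + dcb + 1e-9


class TestScarMass:
    def test_empty_mask_zero_mass(self, unit_geometry):
        assert scar_mass(np.zeros((8, 8), bool), unit_geometry) == 0.0

    def test_printed_example(self):
        # 1000 px at 1.5 x 1.5 mm, 8 mm thick = 18 cm^3 -> 18.9 g
        g = VoxelGeometry(1.5, 1.5, 8.0)
        m = np.zeros((40, 40), bool)
        m.ravel()[:1000] = True
        assert scar_mass(m, g) == pytest.approx(18.9, abs=1e-12)

    def test_linear_and_translation_invariant(self, unit_geometry, rng):
        m = np.zeros((32, 32), bool)
        m[4:10, 4:10] = True
        shifted = np.roll(m, (7, 5), axis=(0, 1))
        assert scar_mass(m, unit_geometry) == scar_mass(shifted, unit_geometry)
        double = m | np.roll(m, 16, axis=0)
        assert scar_mass(double, unit_geometry) == pytest.approx(
            2 * scar_mass(m, unit_geometry)
        )

    def test_phantom_wedge_matches_analytic_mass(self):
        # high-resolution rendering so boundary quantization stays well
        # below the 2% geometric tolerance
        rng = np.random.default_rng(42)
        for _ in range(10):
            spec = PhantomSpec(
                grid_size=176,
                pixel_spacing_mm=0.5,
                r_endo_mm=rng.uniform(15, 19),
                r_epi_mm=rng.uniform(27, 33),
                scar_start_deg=rng.uniform(0, 360),
                scar_extent_deg=rng.uniform(60, 180),
                scar_transmurality=rng.uniform(0.5, 1.0),
                noise_sd=0.0,
                bias_amplitude=0.0,
            )
            rec = generate_slice(spec)
            analytic_g = (
                analytic_scar_area_mm2(spec)
                * spec.slice_thickness_mm
                * MYOCARDIAL_DENSITY_G_PER_CM3
                * 1e-3
            )
            measured_g = scar_mass(rec.scar_mask, rec.geometry)
            assert abs(measured_g - analytic_g) / analytic_g < 0.02


class TestMassError:
    def test_exact_and_percent(self):
        assert mass_error(10.0, 10.0, 100.0) == (0.0, 0.0)
        err, pct = mass_error(12.0, 10.0, 100.0)
        assert err == pytest.approx(2.0)
        assert pct == pytest.approx(2.0)

    def test_undefined_percent_without_lv_mass(self):
        err, pct = mass_error(5.0, 3.0)
        assert err == pytest.approx(2.0)
        assert pct is None

    def test_random_triples_match_arithmetic(self, rng):
        for _ in range(20):
            a, b, lv = rng.uniform(0.1, 50, 3)
            err, pct = mass_error(a, b, lv)
            assert err == pytest.approx(abs(a - b))
            assert pct == pytest.approx(100 * abs(a - b) / lv)


class TestFwhm:
    def _roi(self, rec):
        roi = np.zeros_like(rec.scar_mask)
        r, c = np.argwhere(rec.scar_mask).mean(axis=0).astype(int)
        roi[r - 1 : r + 2, c - 1 : c + 2] = True
        return roi & rec.scar_mask

    def test_recovers_two_level_phantom_exactly(self, clean_slice):
        roi = self._roi(clean_slice)
        out = fwhm_segment(clean_slice.image, clean_slice.myo_mask, roi)
        assert np.array_equal(out, clean_slice.scar_mask)

    def test_scale_invariance(self, clean_slice):
        roi = self._roi(clean_slice)
        base = fwhm_segment(clean_slice.image, clean_slice.myo_mask, roi)
        scaled = fwhm_segment(clean_slice.image * 3.7, clean_slice.myo_mask, roi)
        assert np.array_equal(base, scaled)

    def test_min_baseline_full_affine_invariance(self, clean_slice):
        roi = self._roi(clean_slice)
        base = fwhm_segment(clean_slice.image, clean_slice.myo_mask, roi, baseline="min")
        moved = fwhm_segment(
            2.5 * clean_slice.image + 40.0, clean_slice.myo_mask, roi, baseline="min"
        )
        assert np.array_equal(base, moved)

    def test_exclusion_zone_subtracts(self, clean_slice):
        roi = self._roi(clean_slice)
        scar = clean_slice.scar_mask
        rows = np.argwhere(scar)[:, 0]
        excl = np.zeros_like(scar)
        excl[rows.min() : int(rows.mean()), :] = True
        out = fwhm_segment(clean_slice.image, clean_slice.myo_mask, roi, exclusion=excl)
        assert np.array_equal(out, scar & ~excl)

    def test_single_peak_pixel(self):
        img = np.full((10, 10), 10.0)
        myo = np.ones((10, 10), bool)
        img[5, 5] = 100.0
        roi = np.zeros((10, 10), bool)
        roi[5, 5] = True
        out = fwhm_segment(img, myo, roi)
        assert out.sum() == 1 and out[5, 5]

    def test_errors(self, clean_slice):
        empty = np.zeros_like(clean_slice.scar_mask)
        with pytest.raises(Exception):
            fwhm_segment(clean_slice.image, clean_slice.myo_mask, empty)
        outside = ~clean_slice.myo_mask
        with pytest.raises(Exception):
            fwhm_segment(clean_slice.image, clean_slice.myo_mask, outside)


def test_boundary_pixels_of_solid_square():
    m = np.zeros((10, 10), bool)
    m[2:7, 2:7] = True
    b = boundary_pixels(m)
    assert len(b) == 16  # 5x5 square has 16 border pixels
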