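"""Rotational averaging, coverage filtering, and profile classification."""

import numpy as np
import pytest

from conftest import MODERATE_NOISE
from zdiscquant.image import BinaryMask, CalibratedImage
from zdiscquant.synthgen import CrossSectionParams, NoiseParams, make_crosssection_image
from zdiscquant.xsection import (
    DiscSelection,
    classify_profile,
    coverage_filter,
    diameter_profile,
    rotational_average,
)


def _selection(params: CrossSectionParams) -> DiscSelection:
    return DiscSelection(
        center_px=params.disc_center_px,
        radius_px=params.disc_radius_um / params.pixel_size_um,
    )


class TestRotationalAverage:
    def test_identity_on_symmetric_disc(self, center_peaked_params):
        img, _ = make_crosssection_image(center_peaked_params)
        sel = _selection(center_peaked_params)
        avg = rotational_average(img, sel)
        inside = np.isfinite(avg.pixels)
        dev = np.abs(avg.pixels - img.pixels)[inside].max()
        assert dev <= 0.01 * center_peaked_params.signal_level
        assert avg.meta["n_rotations"] == 180
        assert avg.meta["step_deg"] == 2.0

    def test_masks_outside_selection_circle(self, center_peaked_params):
        img, _ = make_crosssection_image(center_peaked_params)
        sel = _selection(center_peaked_params)
        avg = rotational_average(img, sel)
        cx, cy = sel.center_px
        corner = avg.pixels[0, 0]
        assert np.isnan(corner)
        assert np.isfinite(avg.pixels[int(cy), int(cx)])

    def test_noise_variance_reduced_at_every_radius(self):
        # white noise of SD sigma: averaging over rotations shrinks the
        # per-pixel spread at every radius off-centre
        rng_master = np.random.default_rng(1234)
        sigma, n_img = 10.0, 60
        size, radius = 40, 16.0
        cx = cy = (size - 1) / 2
        sel = DiscSelection((cx, cy), radius)
        Y, X = np.mgrid[0:size, 0:size]
        r = np.hypot(X - cx, Y - cy)
        in_var, out_var = [], []
        annuli = [(2, 5), (5, 9), (9, 13), (13, 15.5)]
        in_samples = {a: [] for a in annuli}
        out_samples = {a: [] for a in annuli}
        for _ in range(n_img):
            noise = 100.0 + rng_master.normal(0, sigma, (size, size))
            img = CalibratedImage(np.clip(noise, 0, None), 0.1)
            avg = rotational_average(img, sel)
            for a in annuli:
                ring = (r >= a[0]) & (r < a[1])
                in_samples[a].extend(img.pixels[ring])
                out_samples[a].extend(avg.pixels[ring])
        for a in annuli:
            assert np.var(out_samples[a]) < np.var(in_samples[a])

    def test_idempotent_within_interpolation_tolerance(self, center_peaked_params):
        params = CrossSectionParams(
            profile_kind="center_peaked",
            profile_scale_um=0.6,
            noise=NoiseParams(seed=5, **MODERATE_NOISE),
        )
        img, _ = make_crosssection_image(params)
        sel = _selection(params)
        once = rotational_average(img, sel)
        twice = rotational_average(once, sel)
        inner = np.isfinite(once.pixels) & np.isfinite(twice.pixels)
        dev = np.abs(once.pixels - twice.pixels)[inner].max()
        assert dev <= 0.02 * params.signal_level

    def test_linearity(self, center_peaked_params):
        img, _ = make_crosssection_image(center_peaked_params)
        sel = _selection(center_peaked_params)
        a, b = 1.7, 4.0
        scaled = CalibratedImage(a * img.pixels + b, img.pixel_size_um)
        lhs = rotational_average(scaled, sel).pixels
        rhs = a * rotational_average(img, sel).pixels + b
        inner = np.isfinite(lhs) & np.isfinite(rhs)
        assert np.abs(lhs - rhs)[inner].max() < 1e-9 * a * center_peaked_params.signal_level

    def test_partial_rotation_set_warns(self, center_peaked_params):
        img, _ = make_crosssection_image(center_peaked_params)
        sel = _selection(center_peaked_params)
        with pytest.warns(UserWarning, match="partial"):
            rotational_average(img, sel, step_deg=2.0, n_rotations=90)

    def test_selection_outside_image_rejected(self, center_peaked_params):
        img, _ = make_crosssection_image(center_peaked_params)
        with pytest.raises(ValueError, match="outside"):
            rotational_average(img, DiscSelection((2.0, 2.0), 50.0))


class TestCoverageFilter:
    def _mask(self, arr):
        return BinaryMask(np.asarray(arr, bool), 0.0)

    def test_identical_masks_pass(self):
        m = np.zeros((8, 8), bool)
        m[2:6, 2:6] = True
        assert coverage_filter(self._mask(m), self._mask(m), 1.0)

    def test_disjoint_masks_fail(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0:2], b[4:6] = True, True
        assert not coverage_filter(self._mask(a), self._mask(b))

    def test_half_coverage_boundary(self):
        actin = np.zeros((8, 8), bool)
        actin[0:4] = True
        zdisc = np.zeros((8, 8), bool)
        zdisc[0:2] = True  # covers exactly half of actin
        assert not coverage_filter(self._mask(zdisc), self._mask(actin), 0.9)
        assert coverage_filter(self._mask(zdisc), self._mask(actin), 0.5)

    def test_empty_actin_rejected_with_warning(self):
        z = np.ones((4, 4), bool)
        with pytest.warns(UserWarning, match="empty actin"):
            assert not coverage_filter(self._mask(z), self._mask(np.zeros((4, 4), bool)))


class TestDiameterProfile:
    def test_uniform_disc_flat_profile(self):
        px = np.full((64, 64), 80.0)
        img = CalibratedImage(px, 0.1)
        sel = DiscSelection((31.5, 31.5), 20.0)
        prof = diameter_profile(img, sel, n_samples=41)
        assert np.allclose(prof.rel_intensity, 1.0)
        assert prof.positions_um[0] == pytest.approx(-prof.positions_um[-1])

    def test_center_peaked_max_at_zero(self, center_peaked_params):
        img, _ = make_crosssection_image(center_peaked_params)
        prof = diameter_profile(img, _selection(center_peaked_params), n_samples=57)
        assert prof.positions_um[np.argmax(prof.rel_intensity)] == pytest.approx(0.0)
        assert prof.rel_intensity.max() == 1.0

    def test_ring_maxima_at_ring_radius(self, ring_params):
        img, _ = make_crosssection_image(ring_params)
        prof = diameter_profile(img, _selection(ring_params), n_samples=57)
        spacing = prof.positions_um[1] - prof.positions_um[0]
        left = prof.positions_um < 0
        pos_left = prof.positions_um[left][np.argmax(prof.rel_intensity[left])]
        pos_right = prof.positions_um[~left][np.argmax(prof.rel_intensity[~left])]
        assert pos_left == pytest.approx(-ring_params.profile_scale_um, abs=spacing)
        assert pos_right == pytest.approx(ring_params.profile_scale_um, abs=spacing)

    def test_profile_symmetry_noise_free(self, ring_params):
        img, _ = make_crosssection_image(ring_params)
        prof = diameter_profile(img, _selection(ring_params), n_samples=57)
        assert np.abs(prof.rel_intensity - prof.rel_intensity[::-1]).max() <= 0.02

    def test_even_sample_count_rejected(self, ring_params):
        img, _ = make_crosssection_image(ring_params)
        with pytest.raises(ValueError, match="odd"):
            diameter_profile(img, _selection(ring_params), n_samples=56)

    def test_degenerate_selection_rejected(self, ring_params):
        img, _ = make_crosssection_image(ring_params)
        with pytest.raises(ValueError, match="radius"):
            diameter_profile(img, DiscSelection((48, 48), 1.0))


class TestClassifyProfile:
    @pytest.mark.parametrize(
        "kind,scale,expected",
        [("center_peaked", 0.6, "center_peaked"), ("ring", 1.0, "bimodal")],
    )
    def test_calls_on_noisy_averaged_discs(self, kind, scale, expected):
        hits = 0
        n = 8
        for seed in range(n):
            params = CrossSectionParams(
                profile_kind=kind,
                profile_scale_um=scale,
                noise=NoiseParams(seed=seed, **MODERATE_NOISE),
            )
            img, _ = make_crosssection_image(params)
            sel = _selection(params)
            avg = rotational_average(img, sel)
            prof = diameter_profile(avg, sel, n_samples=57)
            if classify_profile(prof).call == expected:
                hits += 1
        assert hits >= n - 1

    def test_flat_profile_ambiguous(self):
        from zdiscquant.xsection import DiameterProfile

        prof = DiameterProfile(
            positions_um=np.linspace(-2, 2, 41), rel_intensity=np.ones(41)
        )
        assert classify_profile(prof).call == "ambiguous"

    def test_off_center_single_peak_not_center_peaked(self):
        from zdiscquant.xsection import DiameterProfile

        pos = np.linspace(-2, 2, 81)
        y = np.exp(-((pos - 1.5) ** 2) / (2 * 0.2**2))
        prof = DiameterProfile(positions_um=pos, rel_intensity=y / y.max())
        assert classify_profile(prof).call == "ambiguous"
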