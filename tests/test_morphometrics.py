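"""Morphometrics: closed-form shape oracles, profile recovery, orientation
and normalization rules, kymographs."""

import numpy as np
import pytest

from gastruquant import morphometrics as mm
from gastruquant import synth

from conftest import (
    disk_mask,
    ellipse_mask,
    linear_profile,
    make_sample,
    raster_moment_eccentricity,
    rect_mask,
)


class TestAreaPerimeter:
    def test_filled_square_area_is_pixel_count(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        area, _ = mm.measure_area_perimeter(m, pixel_size_um=1.0)
        assert area == 100

    def test_disk_area_and_perimeter_match_circle(self):
        m = disk_mask(50)
        area, perim = mm.measure_area_perimeter(m)
        assert area == pytest.approx(np.pi * 50**2, rel=0.01)
        assert perim == pytest.approx(2 * np.pi * 50, rel=0.03)

    def test_pixel_size_scales_units(self):
        m = disk_mask(30)
        a1, p1 = mm.measure_area_perimeter(m)
        a2, p2 = mm.measure_area_perimeter(m, pixel_size_um=0.5)
        assert a2 == pytest.approx(a1 * 0.25) and p2 == pytest.approx(p1 * 0.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mm.measure_area_perimeter(np.zeros((10, 10), bool))


class TestMidline:
    def test_rectangle_midline_length_and_width(self):
        ml = mm.extract_midline(rect_mask(200, 40))
        assert ml.length == pytest.approx(200, abs=2)
        assert np.median(ml.local_width) == pytest.approx(40, abs=1)
        # central row: all vertices near the rectangle's axis
        assert np.abs(ml.vertices[:, 0] - ml.vertices[:, 0].mean()).max() < 2.0

    def test_disk_is_degenerate_with_short_midline(self):
        ml = mm.extract_midline(disk_mask(50))
        assert ml.degenerate and "degenerate_axis" in ml.flags
        assert ml.length <= 0.2 * 100

    def test_bent_sample_close_to_generator_truth(self, bent_sample):
        from scipy.spatial.distance import directed_hausdorff
        ml = mm.extract_midline(bent_sample.true_mask)
        # recovered midline spans pole to pole; the generating spine must lie
        # within 3 px of it
        d = directed_hausdorff(bent_sample.true_midline.vertices, ml.vertices)[0]
        assert d <= 3.0

    def test_thin_mask_rejected(self):
        m = np.zeros((50, 50), bool)
        m[10:12, 5:45] = True
        with pytest.raises(ValueError, match="thinner"):
            mm.extract_midline(m)


class TestStraightenAndEccentricity:
    def test_straight_rectangle_is_fixed_point(self):
        m = rect_mask(200, 40)
        st = mm.straighten(m, mm.extract_midline(m))
        # compare overlap after aligning centroids of the two rasters
        a = st.mask.sum()
        inter_frac = min(a, m.sum()) / max(a, m.sum())
        assert inter_frac >= 0.98
        assert st.grid.shape[0] - 1 == pytest.approx(200, abs=4)

    def test_bent_capsule_conserves_length_and_area(self, bent_sample):
        mask = bent_sample.true_mask
        st = mm.straighten(mask, mm.extract_midline(mask))
        expected = 300.0 + 60.0   # spine plus two half-width caps
        assert st.grid.shape[0] - 1 == pytest.approx(expected, rel=0.02)
        assert st.mask.sum() == pytest.approx(mask.sum(), rel=0.05)

    def test_ellipse_eccentricity_closed_form(self):
        m = ellipse_mask(100, 60)
        st = mm.straighten(m, mm.extract_midline(m))
        assert mm.eccentricity(st) == pytest.approx(0.800, abs=0.01)

    def test_circleish_eccentricity_zero(self):
        # a disk has no axis; second moments of the (degenerate) straightened
        # disk would be arbitrary, so check the un-straightened moments route
        assert raster_moment_eccentricity(disk_mask(40)) == pytest.approx(0.0, abs=0.05)

    def test_capsule_eccentricity_matches_raster_moment_oracle(self):
        for seed, L, w in [(1, 160, 80), (2, 200, 70), (3, 240, 60)]:
            s = make_sample(seed, length_px=float(L), width_px=float(w),
                            bend_curvature=0.0, orientation_deg=0.0)
            st = mm.straighten(s.true_mask, mm.extract_midline(s.true_mask))
            assert mm.eccentricity(st) == pytest.approx(
                raster_moment_eccentricity(s.true_mask), abs=0.02)

    def test_elongation_increases_eccentricity(self):
        eccs = []
        for L in (120, 160, 200, 240):
            s = make_sample(4, length_px=float(L), width_px=60.0,
                            bend_curvature=0.0, orientation_deg=0.0)
            st = mm.straighten(s.true_mask, mm.extract_midline(s.true_mask))
            eccs.append(mm.eccentricity(st))
        assert np.all(np.diff(eccs) > 0)


class TestAPProfile:
    def test_uniform_intensity_gives_flat_profile(self):
        m = rect_mask(150, 40)
        img = np.where(m, 123.0, 0.0)
        ml = mm.extract_midline(m)
        _, vals = mm.ap_profile(img, m, ml)
        np.testing.assert_allclose(vals, 123.0)

    def test_noise_free_recovery_within_2pct_rms(self, bent_sample):
        s = bent_sample
        ml = mm.extract_midline(s.true_mask)
        pos, vals = mm.ap_profile(s.image.channels["T"], s.true_mask, ml)
        (ap,) = mm.orient_and_normalize(
            [mm.RawProfile("s", pos, {"T": vals})], "T",
            length_grid_n=100, intensity_norm="none")
        p_true, v_true = s.axis_profile("T", n=100)
        rms = np.sqrt(np.mean((ap.intensities["T"] - v_true) ** 2))
        assert rms <= 0.02 * (v_true.max() - v_true.min())

    def test_polar_intensity_concentrates_in_matching_half(self):
        s = make_sample(5, bend_curvature=0.0, orientation_deg=0.0)
        ml = mm.extract_midline(s.true_mask)
        pos, vals = mm.ap_profile(s.image.channels["T"], s.true_mask, ml)
        half = len(vals) // 2
        lo, hi = sorted([vals[:half].sum(), vals[half:].sum()])
        assert hi > 2 * lo


class TestOrientAndNormalize:
    def _raw(self, vals, sid="x", group=""):
        return mm.RawProfile(sid, np.arange(len(vals), dtype=float),
                             {"T": np.asarray(vals, float)}, group=group)

    def test_increasing_kept_decreasing_flipped(self):
        inc = self._raw(np.linspace(0, 10, 50), "inc")
        dec = self._raw(np.linspace(10, 0, 50), "dec")
        out = mm.orient_and_normalize([inc, dec], "T", intensity_norm="none")
        assert not out[0].flipped and out[1].flipped
        for ap in out:
            # posterior half carries the reference maximum
            assert np.argmax(ap.intensities["T"]) >= len(ap.positions) // 2

    def test_orientation_idempotent(self):
        dec = self._raw(np.linspace(10, 0, 50))
        (once,) = mm.orient_and_normalize([dec], "T", intensity_norm="none")
        again_raw = mm.RawProfile("x", once.positions, dict(once.intensities))
        (twice,) = mm.orient_and_normalize([again_raw], "T", intensity_norm="none")
        assert not twice.flipped
        np.testing.assert_allclose(twice.intensities["T"], once.intensities["T"])

    def test_symmetric_profile_tie_flagged_not_flipped(self):
        sym = self._raw(np.concatenate([np.arange(25), np.arange(25)[::-1]]))
        (ap,) = mm.orient_and_normalize([sym], "T", intensity_norm="none")
        assert "orientation_tie" in ap.flags and not ap.flipped

    def test_global_norm_divides_by_overall_max(self):
        p1 = self._raw(np.full(20, 10.0), "a")
        p2 = self._raw(np.full(20, 20.0), "b")
        out = mm.orient_and_normalize([p1, p2], "T", intensity_norm="global")
        assert out[0].intensities["T"].max() == pytest.approx(0.5)
        assert out[1].intensities["T"].max() == pytest.approx(1.0)

    def test_per_group_norm_divides_within_group(self):
        p1 = self._raw(np.full(20, 10.0), "a", group="g1")
        p2 = self._raw(np.full(20, 20.0), "b", group="g2")
        out = mm.orient_and_normalize([p1, p2], "T", intensity_norm="per_group")
        assert out[0].intensities["T"].max() == pytest.approx(1.0)
        assert out[1].intensities["T"].max() == pytest.approx(1.0)

    def test_positions_span_unit_interval(self):
        (ap,) = mm.orient_and_normalize([self._raw(np.arange(30.0))], "T")
        assert ap.positions[0] == 0.0 and ap.positions[-1] == 1.0
        assert np.all(np.diff(ap.positions) > 0)

    def test_missing_reference_channel_rejected(self):
        rp = mm.RawProfile("x", np.arange(5.0), {"Sox2": np.ones(5)})
        with pytest.raises(ValueError, match="reference channel"):
            mm.orient_and_normalize([rp], "T")


class TestAverageProfiles:
    def _ap(self, vals, sid="x"):
        v = np.asarray(vals, float)
        return mm.APProfile(sid, np.linspace(0, 1, len(v)), {"T": v}, "T", "none")

    def test_identical_profiles_zero_sd(self):
        band = mm.average_profiles([self._ap(np.arange(10.0))] * 3)
        np.testing.assert_allclose(band.sd["T"], 0.0)

    def test_two_constant_profiles_sample_sd(self):
        band = mm.average_profiles([self._ap(np.zeros(10)), self._ap(np.ones(10))])
        np.testing.assert_allclose(band.mean["T"], 0.5)
        np.testing.assert_allclose(band.sd["T"], np.sqrt(0.5), rtol=1e-12)
        assert band.sd["T"][0] == pytest.approx(0.70710678, abs=1e-6)

    def test_single_profile_mean_is_profile(self):
        band = mm.average_profiles([self._ap(np.arange(10.0))])
        np.testing.assert_allclose(band.mean["T"], np.arange(10.0))
        np.testing.assert_allclose(band.sd["T"], 0.0)


class TestKymograph:
    def _frames(self, n, scale=lambda t: 1.0):
        out = []
        for t in range(n):
            vals = np.linspace(0, 10, 60) * scale(t) + 1.0
            out.append(mm.RawProfile(f"t{t}", np.arange(60.0), {"T": vals}))
        return out

    def test_time_constant_movie_rows_equal(self):
        k = mm.kymograph(self._frames(5), "T")
        for row in k.matrix[1:]:
            np.testing.assert_allclose(row, k.matrix[0])

    def test_intensifying_pole_posterior_mean_increases(self):
        k = mm.kymograph(self._frames(6, scale=lambda t: 1.0 + t), "T")
        post = k.matrix[:, k.positions >= 0.5].mean(axis=1)
        assert np.all(np.diff(post) > 0)

    def test_missing_frame_becomes_nan_row(self):
        frames = self._frames(4)
        frames[2] = None
        k = mm.kymograph(frames, "T")
        assert np.isnan(k.matrix[2]).all()
        assert np.isfinite(k.matrix[1]).all()

    def test_replicate_average_of_identical_movies_is_identity(self):
        k1 = mm.kymograph(self._frames(5), "T")
        k2 = mm.kymograph(self._frames(5), "T")
        avg = mm.average_kymographs([k1, k2])
        np.testing.assert_allclose(avg.matrix, k1.matrix)

    def test_orientation_locked_from_final_frame(self):
        # early frame polarized the other way must not flip its own row
        frames = self._frames(4)
        rev = np.linspace(10, 0, 60) + 1.0
        frames[0] = mm.RawProfile("t0", np.arange(60.0), {"T": rev})
        k = mm.kymograph(frames, "T")
        assert not k.flipped
        # the reversed first row stays reversed (peak anterior)
        assert np.argmax(k.matrix[0]) < 30


class TestMultichannel:
    def test_every_channel_peaks_at_exactly_one(self):
        s = make_sample(6, bend_curvature=0.0, orientation_deg=0.0)
        mask = s.true_mask
        chans = {
            "T": s.image.channels["T"],
            "Sox2": np.where(mask, 77.0, 0.0),
            "Foxa2": np.where(mask, 1234.5, 0.0),
        }
        ap = mm.multichannel_profile(chans, {"T": mask}, reference_channel="T")
        for ch in chans:
            assert ap.intensities[ch].max() == 1.0

    def test_channel_identical_to_reference_gives_same_profile(self):
        s = make_sample(6, bend_curvature=0.0, orientation_deg=0.0)
        chans = {"T": s.image.channels["T"], "T2": s.image.channels["T"].copy()}
        ap = mm.multichannel_profile(chans, {"T": s.true_mask})
        np.testing.assert_allclose(ap.intensities["T"], ap.intensities["T2"])

    def test_opposing_gradients_peak_on_opposite_halves(self):
        spec = synth.ShapeSpec(200.0, 70.0, 0.0, 0.0)
        t = synth.PolarizationSpec("T", linear_profile(0, 6000), background_level=100)
        sox = synth.PolarizationSpec("Sox2", lambda s: 6000 * (1 - np.asarray(s)),
                                     background_level=100)
        s = synth.make_gastruloid_image(spec, [t, sox], seed=1)
        ap = mm.multichannel_profile(
            {"T": s.image.channels["T"], "Sox2": s.image.channels["Sox2"]},
            {"T": s.true_mask})
        i_t = ap.positions[np.argmax(ap.intensities["T"])]
        i_s = ap.positions[np.argmax(ap.intensities["Sox2"])]
        assert i_t > 0.5 > i_s

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            mm.multichannel_profile({"Sox2": np.ones((10, 10))},
                                    {"Sox2": np.ones((10, 10), bool)})


class TestEquivariance:
    def test_rot90_leaves_measures_unchanged(self, straight_sample):
        s = straight_sample
        mask, img = s.true_mask, s.image.channels["T"]
        area, perim = mm.measure_area_perimeter(mask)
        st = mm.straighten(mask, mm.extract_midline(mask))
        ecc = mm.eccentricity(st)
        pos, vals = mm.ap_profile(img, mask, mm.extract_midline(mask))
        (ap,) = mm.orient_and_normalize([mm.RawProfile("o", pos, {"T": vals})],
                                        "T", intensity_norm="per_channel_max")

        mask_r, img_r = np.rot90(mask).copy(), np.rot90(img).copy()
        area_r, perim_r = mm.measure_area_perimeter(mask_r)
        st_r = mm.straighten(mask_r, mm.extract_midline(mask_r))
        ecc_r = mm.eccentricity(st_r)
        pos_r, vals_r = mm.ap_profile(img_r, mask_r, mm.extract_midline(mask_r))
        (ap_r,) = mm.orient_and_normalize([mm.RawProfile("r", pos_r, {"T": vals_r})],
                                          "T", intensity_norm="per_channel_max")

        assert area_r == area
        assert perim_r == pytest.approx(perim, rel=0.01)
        assert ecc_r == pytest.approx(ecc, abs=0.01)
        rms = np.sqrt(np.mean((ap.intensities["T"] - ap_r.intensities["T"]) ** 2))
        assert rms <= 0.02


def test_morphometrics_row_summary(straight_sample):
    row = mm.morphometrics_row(straight_sample.true_mask, sample_id="s0")
    assert row["degenerate_flag"] is False
    assert row["midline_length"] == pytest.approx(270, abs=8)
    assert 0 < row["eccentricity"] < 1
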