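"""Puncta detection, photometry, line profiles, and PSF verification."""

import numpy as np
import pytest
from scipy.special import jn_zeros

from stellatrack import simcilia as sc
from stellatrack.puncta import (
    Profile,
    PsfModel,
    average_aligned_profiles,
    detect_puncta,
    fwhm,
    line_profile,
    profile_match,
    psf_in_focus,
    sum_intensity,
)


def render_emitters(scene, positions, photons, seed=None, background=10.0,
                    shot_noise=True, n_fluor=None):
    """Render one frame with emitters at the given (y, x) positions."""
    tracks = []
    for i, (y, x) in enumerate(positions):
        tracks.append(
            sc.GroundTruthTrack(
                molecule_id=i, kind="stationary",
                n_fluorophores=1 if n_fluor is None else n_fluor[i],
                stereocilium=0, frames=np.array([0]),
                x_px=np.array([x]), y_px=np.array([y]),
                s_um=np.array([0.0]), visible=np.array([True]),
            )
        )
    photo = sc.Photophysics(photons_per_frame=photons, bleach_half_life=float("inf"))
    camera = sc.CameraModel(
        gain=1.0, offset=100.0, read_noise_sd=1.5 if shot_noise else 0.0
    )
    # emitters over a spatially flat background so the tests probe
    # detection and photometry semantics, not scene structure
    stack = sc.render_movie(
        scene, tracks, photo, camera, n_frames=1, seed=seed,
        background_photons=0.0, apply_shot_noise=shot_noise, quantize=False,
    )
    img = stack.data[0]
    if background > 0:
        if shot_noise:
            img = img + np.random.default_rng(
                0 if seed is None else seed + 10_000
            ).poisson(background, img.shape)
        else:
            img = img + background
    return img


class TestDetectPuncta:
    def test_blank_noise_frames_nearly_no_detections(self):
        # flat Poisson background + Gaussian read noise, quantized like the
        # camera output; 100 seeded frames
        n_false = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            img = np.round(
                100.0 + (rng.poisson(20.0, (128, 128)) - 20.0
                         + rng.normal(0.0, 1.5, (128, 128))) / 2.0
            )
            n_false += len(detect_puncta(img, 1.3, 5.0))
        assert n_false <= 1  # < 0.01 false positives per frame

    def test_single_emitter_localized_within_02px(self, default_scene):
        pos = (60.35, 70.62)
        img = render_emitters(default_scene, [pos], 1000.0, seed=3)
        dets = detect_puncta(img, 1.3, 5.0)
        assert len(dets) == 1
        assert np.hypot(dets[0].y - pos[0], dets[0].x - pos[1]) < 0.2

    def test_two_emitters_ten_px_apart(self, default_scene):
        img = render_emitters(default_scene, [(50.0, 50.0), (50.0, 60.0)], 1000.0, seed=4)
        dets = detect_puncta(img, 1.3, 5.0)
        assert len(dets) == 2

    def test_recall_and_precision_at_snr8(self, default_scene):
        rng = np.random.default_rng(5)
        tp = fp = fn = 0
        for rep in range(20):
            truth = [(rng.uniform(20, 100), rng.uniform(20, 100)) for _ in range(4)]
            # reject pairs closer than 8 px
            if min(
                [np.hypot(a[0] - b[0], a[1] - b[1])
                 for i, a in enumerate(truth) for b in truth[i + 1:]] or [99]
            ) < 8:
                continue
            img = render_emitters(default_scene, truth, 1200.0, seed=100 + rep)
            dets = detect_puncta(img, 1.3, 5.0)
            matched = set()
            for t in truth:
                hit = [i for i, d in enumerate(dets)
                       if np.hypot(d.y - t[0], d.x - t[1]) < 2 and i not in matched]
                if hit:
                    matched.add(hit[0])
                    tp += 1
                else:
                    fn += 1
            fp += len(dets) - len(matched)
        assert tp / (tp + fn) >= 0.95  # recall
        assert tp / (tp + fp) >= 0.95  # precision


class TestSumIntensity:
    def test_uniform_image_gives_zero(self):
        img = np.full((31, 31), 7.5)
        s, bg, edge = sum_intensity(img, (15.0, 15.0), 3.0)
        assert s == pytest.approx(0.0, abs=1e-9)
        assert bg == pytest.approx(7.5)
        assert not edge

    def test_noise_free_punctum_recovers_photons(self, default_scene):
        # a wide aperture is needed to capture the Airy rings; the rendered
        # kernel support has radius 10 px, so r=12 with a far annulus
        # integrates essentially all of it
        img = render_emitters(default_scene, [(60.0, 100.0)], 2000.0,
                              background=10.0, shot_noise=False)
        s, _, _ = sum_intensity(img, (60.0, 100.0), 15.0, bg_annulus=(1.5, 1.8))
        assert s == pytest.approx(2000.0, rel=0.01)

    def test_two_to_one_fluorophore_ratio(self, default_scene):
        rng = np.random.default_rng(6)
        ones, twos = [], []
        for rep in range(60):
            y, x = rng.uniform(30, 100, 2)
            img1 = render_emitters(default_scene, [(y, x)], 816.0, seed=200 + rep,
                                   n_fluor=[1])
            img2 = render_emitters(default_scene, [(y, x)], 816.0, seed=400 + rep,
                                   n_fluor=[2])
            ones.append(sum_intensity(img1, (y, x), 4.0)[0])
            twos.append(sum_intensity(img2, (y, x), 4.0)[0])
        ratio = np.mean(twos) / np.mean(ones)
        assert ratio == pytest.approx(2.0, abs=0.1)

    def test_photometric_linearity(self, default_scene):
        photons = np.array([100.0, 1000.0, 10000.0])
        sums = []
        for p in photons:
            img = render_emitters(default_scene, [(60.0, 100.0)], p,
                                  background=5.0, shot_noise=False)
            sums.append(sum_intensity(img, (60.0, 100.0), 15.0, bg_annulus=(1.5, 1.8))[0])
        slope = np.polyfit(photons, sums, 1)[0]
        assert slope == pytest.approx(1.0, rel=0.02)

    def test_bad_annulus_rejected(self):
        with pytest.raises(ValueError):
            sum_intensity(np.zeros((21, 21)), (10, 10), 3.0, bg_annulus=(0.5, 0.8))

    def test_edge_aperture_flagged(self):
        img = np.random.default_rng(0).normal(10, 1, (31, 31))
        _, _, edge = sum_intensity(img, (1.0, 15.0), 3.0)
        assert edge


class TestLineProfile:
    def test_flat_row_profile(self):
        img = np.tile(np.arange(40.0), (20, 1)) * 0 + 5.0
        poly = np.array([[10.0, 2.0], [10.0, 30.0]])
        prof = line_profile(img, poly, width_px=1, pixel_size_um=0.1)
        np.testing.assert_allclose(prof.values, 5.0)

    def test_peak_at_emitter_arclength(self, default_scene):
        img = render_emitters(default_scene, [(60.0, 64.0)], 2000.0,
                              background=0.0, shot_noise=False)
        poly = np.array([[60.0, 44.0], [60.0, 84.0]])
        prof = line_profile(img, poly, width_px=1, pixel_size_um=1.0)
        peak_pos = prof.positions[np.argmax(prof.values)]
        assert peak_pos == pytest.approx(20.0, abs=0.1)

    def test_width_invariance_on_uniform_image(self):
        img = np.full((30, 30), 3.0)
        poly = np.array([[15.0, 3.0], [15.0, 27.0]])
        p1 = line_profile(img, poly, width_px=1)
        p3 = line_profile(img, poly, width_px=3)
        np.testing.assert_allclose(p1.values, p3.values)

    def test_polyline_outside_image_rejected(self):
        with pytest.raises(ValueError):
            line_profile(np.zeros((20, 20)), np.array([[5.0, -3.0], [5.0, 10.0]]))


class TestAverageAlignedProfiles:
    def test_identical_profiles_average_to_input(self):
        x = np.linspace(-2, 2, 81)
        v = np.exp(-(x**2))
        profs = [Profile(x, v) for _ in range(10)]
        avg = average_aligned_profiles(profs)
        assert avg.n_averaged == 10
        np.testing.assert_allclose(avg.sd, 0.0, atol=1e-12)
        assert avg.values.max() == pytest.approx(1.0)

    def test_shifted_profiles_realign_at_zero(self):
        x = np.linspace(-3, 3, 121)
        profs = [Profile(x, np.exp(-((x - c) ** 2))) for c in (-0.4, 0.0, 0.4)]
        avg = average_aligned_profiles(profs)
        assert avg.positions[np.argmax(avg.values)] == pytest.approx(0.0, abs=0.06)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        x = np.linspace(-2, 2, 81)
        profs = [Profile(x, np.exp(-((x - c) ** 2) / 0.5) + rng.normal(0, 0.01, 81))
                 for c in rng.uniform(-0.5, 0.5, 6)]
        a = average_aligned_profiles(profs)
        b = average_aligned_profiles(profs[::-1])
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_monotone_profile_excluded(self):
        x = np.linspace(0, 1, 50)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                average_aligned_profiles([Profile(x, x)])


class TestPsfInFocus:
    def test_peak_normalized_to_one(self):
        prof = psf_in_focus(np.array([0.0, 0.1, 0.2]))
        assert prof.values[0] == 1.0

    def test_first_zero_matches_bessel_oracle(self):
        model = PsfModel(wavelength=0.576, na=0.8)
        r_zero = jn_zeros(1, 1)[0] / (2 * np.pi) * model.wavelength / model.na
        assert r_zero == pytest.approx(0.439, abs=0.001)
        val = psf_in_focus(np.array([r_zero]), model).values[0]
        assert abs(val) < 1e-6

    def test_wavelength_doubling_dilates_profile(self):
        r = np.linspace(0.01, 1.5, 200)
        a = psf_in_focus(r, PsfModel(wavelength=0.5, na=0.8))
        b = psf_in_focus(2 * r, PsfModel(wavelength=1.0, na=0.8))
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_energy_integral_finite(self):
        r = np.linspace(1e-4, 30.0, 200000)
        vals = psf_in_focus(r).values
        integral = 2 * np.pi * np.trapezoid(vals * r, r)
        assert np.isfinite(integral) and integral > 0


class TestProfileMatch:
    @pytest.fixture(scope="class")
    def theoretical(self):
        r = np.arange(-1.5, 1.5001, 0.005)
        return psf_in_focus(r)

    def test_self_match(self, theoretical):
        m = profile_match(theoretical, theoretical)
        assert m["rms"] == pytest.approx(0.0, abs=1e-12)
        assert m["fwhm_ratio"] == pytest.approx(1.0)
        assert m["point_source"]

    def test_extended_source_rejected(self, theoretical):
        # convolve with a 3-px box (~0.49 um at default pixel size)
        v = theoretical.values
        box = np.ones(98) / 98  # 0.49 um on the 0.005-um grid
        widened = np.convolve(v, box, mode="same")
        widened /= widened.max()
        measured = Profile(theoretical.positions, widened)
        direct_ratio = fwhm(measured) / fwhm(theoretical)
        m = profile_match(measured, theoretical)
        assert m["fwhm_ratio"] == pytest.approx(direct_ratio, rel=1e-6)
        assert m["fwhm_ratio"] > 1.25
        assert not m["point_source"]

    def test_pure_noise_not_a_point_source(self, theoretical):
        rng = np.random.default_rng(8)
        noise = Profile(theoretical.positions, rng.random(len(theoretical.positions)))
        m = profile_match(noise, theoretical)
        assert not m["point_source"]

    def test_rendered_puncta_match_theory_within_3sd(self, default_scene):
        # average of noisy rendered single-fluorophore profiles vs Airy theory
        rng = np.random.default_rng(9)
        profs = []
        for rep in range(10):
            y, x = rng.uniform(40, 90, 2)
            img = render_emitters(default_scene, [(y, x)], 3000.0, seed=700 + rep,
                                  background=5.0)
            poly = np.array([[y, x - 12.0], [y, x + 12.0]])
            profs.append(line_profile(img, poly, width_px=1,
                                      pixel_size_um=default_scene.pixel_size))
        avg = average_aligned_profiles(profs)
        theory = psf_in_focus(avg.positions)
        sel = np.abs(avg.positions) <= 0.8
        band = np.maximum(3 * avg.sd[sel], 0.05)
        assert (np.abs(avg.values[sel] - theory.values[sel]) <= band).mean() > 0.95
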