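import numpy as np
import pytest

from stellatrack import simcilia as sc


@pytest.fixture(scope="session")
def smooth_image():
    """64x64 image of well-separated Gaussian blobs (registration target)."""
    rng = np.random.default_rng(42)
    img = np.zeros((64, 64))
    yy, xx = np.mgrid[0:64, 0:64]
    for y, x in rng.uniform(10, 54, (12, 2)):
        img += np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * 1.6**2))
    return img


@pytest.fixture(scope="session")
def default_scene():
    return sc.make_scene(1, (10.0, 10.0), (128, 128), 0.1625, seed=1)


@pytest.fixture(scope="session")
def noise_free_emitter(default_scene):
    """One stationary emitter rendered without any noise, plus its truth."""
    scene = default_scene
    photo = sc.Photophysics(photons_per_frame=1000.0, bleach_half_life=float("inf"))
    camera = sc.CameraModel(gain=1.0, offset=0.0, read_noise_sd=0.0)
    track = sc.GroundTruthTrack(
        molecule_id=0,
        kind="stationary",
        n_fluorophores=1,
        stereocilium=0,
        frames=np.array([0]),
        x_px=np.array([64.3]),
        y_px=np.array([60.7]),
        s_um=np.array([2.0]),
        visible=np.array([True]),
    )
    stack = sc.render_movie(
        scene, [track], photo, camera, n_frames=1, apply_shot_noise=False, quantize=False
    )
    return stack, track


def fourier_shift(img, dy, dx):
    """Subpixel-shift an image via its Fourier transform (test utility)."""
    ky = np.fft.fftfreq(img.shape[0])[:, None]
    kx = np.fft.fftfreq(img.shape[1])[None, :]
    return np.real(
        np.fft.ifft2(np.fft.fft2(img) * np.exp(-2j * np.pi * (ky * dy + kx * dx)))
    )
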