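import numpy as np
import pytest
from scipy import ndimage
from skimage.transform import rotate

from pactherm.signal import (ImpulseResponse, deconvolve_eir, lowpass,
                             register_rigid, select_frame)


@pytest.fixture(scope="module")
def eir():
    return ImpulseResponse.gaussian_pulse(center_frequency=5.0,
                                          fractional_bandwidth=0.7,
                                          sampling_rate=40.0)


class TestDeconvolveEIR:
    def test_self_deconvolution_gives_impulse(self, eir):
        # the recovered impulse is band-limited by the kernel passband, so
        # the sharpness check compares the peak against everything outside
        # the (short) main lobe
        x = np.zeros(1024)
        x[200:200 + len(eir.kernel)] = eir.kernel
        out = deconvolve_eir(x, eir, noise_reg=1e-6)
        peak_idx = int(np.argmax(np.abs(out)))
        assert peak_idx == 200 + eir.center
        # main lobe width ~ reciprocal of the recovered bandwidth
        lobe = slice(peak_idx - 24, peak_idx + 25)
        outside = np.abs(np.concatenate([out[:lobe.start], out[lobe.stop:]]))
        assert np.abs(out[peak_idx]) / outside.max() > 100

    def test_delta_kernel_is_identity(self):
        delta = ImpulseResponse(kernel=np.array([1.0]), sampling_rate=40.0)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 512))
        out = deconvolve_eir(x, delta, noise_reg=1e-12)
        assert np.allclose(out, x, atol=1e-10)

    def test_round_trip_recovers_broadband_source(self, eir):
        rng = np.random.default_rng(1)
        src = ndimage.gaussian_filter1d(rng.normal(size=2048), 4)
        blurred = eir.convolve(src)
        rec = deconvolve_eir(blurred, eir, noise_reg=1e-6)
        # correlation over the interior (edge effects excluded)
        a, b = src[100:-100], rec[100:-100]
        r = np.corrcoef(a, b)[0, 1]
        assert r > 0.99

    def test_zero_kernel_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ImpulseResponse(kernel=np.zeros(16), sampling_rate=40.0)

    def test_linearity(self, eir):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 512))
        lhs = deconvolve_eir(x + 2 * y, eir)
        rhs = deconvolve_eir(x, eir) + 2 * deconvolve_eir(y, eir)
        assert np.allclose(lhs, rhs, atol=1e-10)


class TestLowpass:
    def test_dc_gain_unity(self):
        x = np.full((2, 400), 3.0)
        out = lowpass(x, cutoff=0.5, sampling_rate=40.0)
        assert np.allclose(out, 3.0, atol=1e-9)

    def test_stopband_5mhz_tone(self):
        t = np.arange(4000) / 40.0
        x = np.sin(2 * np.pi * 5.0 * t)[None, :]
        out = lowpass(x, cutoff=0.5, sampling_rate=40.0)
        assert np.sqrt((out ** 2).mean()) < 0.01 * np.sqrt((x ** 2).mean())

    def test_passband_flat(self):
        t = np.arange(40000) / 40.0
        x = np.sin(2 * np.pi * 0.05 * t)[None, :]
        out = lowpass(x, cutoff=0.5, sampling_rate=40.0)
        inner = slice(2000, -2000)
        rms_in = np.sqrt((x[0, inner] ** 2).mean())
        rms_out = np.sqrt((out[0, inner] ** 2).mean())
        assert abs(rms_out - rms_in) < 0.01 * rms_in

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass(np.zeros((1, 64)), cutoff=30.0, sampling_rate=40.0)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 512))
        lhs = lowpass(x + 2 * y, sampling_rate=40.0)
        rhs = lowpass(x, sampling_rate=40.0) + 2 * lowpass(y, sampling_rate=40.0)
        assert np.allclose(lhs, rhs, atol=1e-10)


class TestSelectFrame:
    def test_exact_copy_wins(self, smooth_image):
        ref = smooth_image
        rng = np.random.default_rng(4)
        cands = [ndimage.shift(ref, (3, 0), order=1), ref.copy(),
                 rng.normal(size=ref.shape)]
        assert select_frame(cands, ref) == 1

    def test_single_candidate(self, smooth_image):
        assert select_frame([smooth_image * 2], smooth_image) == 0

    def test_empty_candidates_rejected(self, smooth_image):
        with pytest.raises(ValueError, match="empty"):
            select_frame([], smooth_image)

    def test_smallest_jitter_selected(self, smooth_image):
        # candidates shifted by fixed magnitudes in random directions at
        # SNR 10: the least-jittered frame should win almost always
        hits = 0
        n_trials = 100
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            jitters = [0.2, 1.5, 3.0, 5.0]
            rng.shuffle(jitters)
            cands = []
            for j in jitters:
                ang = rng.uniform(0, 2 * np.pi)
                sh = (j * np.cos(ang), j * np.sin(ang))
                c = ndimage.shift(smooth_image, sh, order=1)
                c = c + 0.1 * smooth_image.std() * rng.normal(size=c.shape)
                cands.append(c)
            if jitters[select_frame(cands, smooth_image)] == min(jitters):
                hits += 1
        assert hits >= 95


class TestRegisterRigid:
    def test_identity(self, smooth_image):
        tf, reg = register_rigid(smooth_image, smooth_image)
        assert abs(tf.rotation) < 0.1
        assert abs(tf.translation[0]) < 0.1 and abs(tf.translation[1]) < 0.1

    def test_known_shift_recovered(self, smooth_image):
        mov = ndimage.shift(smooth_image, (-2.0, 3.0), order=1)
        tf, _ = register_rigid(mov, smooth_image)
        # moving sits at (dx, dy) = (3, -2) relative to fixed
        assert tf.translation[0] == pytest.approx(-3.0, abs=0.25)
        assert tf.translation[1] == pytest.approx(2.0, abs=0.25)
        assert abs(tf.rotation) < 0.25

    def test_known_rotation_recovered(self, smooth_image):
        mov = rotate(smooth_image, 2.0, order=1, preserve_range=True)
        tf, _ = register_rigid(mov, smooth_image)
        assert tf.rotation == pytest.approx(2.0, abs=0.25)

    def test_flat_image_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            register_rigid(np.zeros((32, 32)), np.ones((32, 32)))

    def test_random_rigid_recovery_property(self):
        # 50 seeded random transforms at SNR 20: median errors < 0.25 px / deg
        rot_err, reg_ncc = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            base = ndimage.gaussian_filter(rng.normal(size=(96, 96)), 3)
            th = rng.uniform(-5, 5)
            sh = rng.uniform(-5, 5, 2)
            mov = ndimage.shift(rotate(base, th, order=1, preserve_range=True),
                                sh, order=1)
            mov = mov + 0.05 * base.std() * rng.normal(size=mov.shape)
            tf, reg = register_rigid(mov, base)
            rot_err.append(abs(tf.rotation - th))
            inner = (slice(10, -10),) * 2
            a = reg[inner] - reg[inner].mean()
            b = base[inner] - base[inner].mean()
            reg_ncc.append((a * b).sum() / np.linalg.norm(a) / np.linalg.norm(b))
        assert np.median(rot_err) < 0.25
        assert np.median(reg_ncc) > 0.99
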