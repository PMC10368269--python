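"""Speckle-video generator: flow statistics, clutter, artifacts, cohorts."""

import numpy as np
import pytest

from speckleflow.decomposition import cpd_als
from speckleflow.io_video import as_tensor, crop_roi
from speckleflow.spectral import detect_transient_peaks, high_frequency_ratio, spectrogram
from speckleflow.synthetic import (
    DISTURBED_PRESET,
    LAMINAR_PRESET,
    CohortConfig,
    FlowParams,
    add_clutter,
    generate_cohort,
    generate_speckle_video,
    inject_artifact,
    mean_signal,
)

FS = 60.0


def quick_cpd(loop, seed=0):
    return cpd_als(as_tensor(loop), rank=3, tol=1e-5, max_iter=100, seed=seed)


class TestGenerateSpeckleVideo:
    def test_static_limit_frames_identical(self):
        p = FlowParams(class_label="laminar", advect_speed=0.0,
                       decorrelation_rate=0.0, modulation_freq=0.0,
                       modulation_depth=0.0, noise_sd=0.0)
        loop = generate_speckle_video(p, shape=(12, 12), n_frames=20, seed=1)
        assert (loop.frames == loop.frames[:, :, :1]).all()

    def test_static_limit_with_noise_differs_only_by_noise(self):
        p = FlowParams(class_label="laminar", advect_speed=0.0,
                       decorrelation_rate=0.0, modulation_freq=0.0,
                       modulation_depth=0.0, noise_sd=0.02)
        loop = generate_speckle_video(p, shape=(12, 12), n_frames=30, seed=1)
        spread = loop.frames.std(axis=2)
        assert spread.max() < 5 * 0.02

    def test_values_in_unit_interval_and_shape(self):
        loop = generate_speckle_video(DISTURBED_PRESET, shape=(10, 14),
                                      n_frames=50, frame_rate=FS, seed=2)
        assert loop.shape == (10, 14, 50)
        assert loop.frames.min() >= 0.0 and loop.frames.max() <= 1.0
        assert loop.frame_rate == FS

    def test_laminar_dominant_frequency_below_disturbed(self, laminar_loop, disturbed_loop):
        doms = []
        for loop in (laminar_loop, disturbed_loop):
            S = spectrogram(mean_signal(loop), fs=FS)
            doms.append(S.freqs[np.argmax(S.power.sum(axis=1))])
        assert doms[0] < doms[1]

    def test_disturbed_decorrelates_faster(self, laminar_loop, disturbed_loop):
        def lag1_corr(loop):
            flat = loop.frames.reshape(-1, loop.n_frames)
            a, b = flat[:, :-1].ravel(), flat[:, 1:].ravel()
            return np.corrcoef(a, b)[0, 1]

        assert lag1_corr(disturbed_loop) < lag1_corr(laminar_loop)

    def test_seed_determinism(self):
        a = generate_speckle_video(LAMINAR_PRESET, shape=(8, 8), n_frames=20, seed=9)
        b = generate_speckle_video(LAMINAR_PRESET, shape=(8, 8), n_frames=20, seed=9)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FlowParams(class_label="turbulent")
        with pytest.raises(ValueError):
            FlowParams(class_label="laminar", decorrelation_rate=1.5)
        with pytest.raises(ValueError):
            FlowParams(class_label="laminar", speckle_grain=0.0)


class TestAddClutter:
    LUMEN = (14, 14, 26, 26)

    def make_full(self, seed=5):
        loop = generate_speckle_video(DISTURBED_PRESET, shape=(40, 40),
                                      n_frames=400, frame_rate=FS, seed=seed)
        return loop, add_clutter(loop, self.LUMEN, seed=seed + 1)

    def test_lumen_pixels_untouched(self):
        loop, full = self.make_full()
        np.testing.assert_array_equal(
            crop_roi(full, self.LUMEN).frames, crop_roi(loop, self.LUMEN).frames
        )

    def test_clutter_temporal_variance_well_below_lumen(self):
        """Tissue pixels vary several-fold less over time than flow pixels,
        even though the tissue dynamics are spatially coherent."""
        _, full = self.make_full()
        r0, c0, r1, c1 = self.LUMEN
        lumen_var = full.frames[r0:r1, c0:c1, :].var(axis=2).mean()
        mask = np.ones(full.shape[:2], dtype=bool)
        mask[r0:r1, c0:c1] = False
        clutter_var = full.frames[mask, :].var(axis=1).mean()
        assert clutter_var < lumen_var / 2

    def test_leading_temporal_factor_diluted_by_clutter(self):
        """Clutter >= 75% of pixels flattens the leading temporal factor."""
        loop, full = self.make_full()
        frac_clutter = 1 - 12 * 12 / (40 * 40)
        assert frac_clutter >= 0.75
        hfr_full = high_frequency_ratio(
            spectrogram(quick_cpd(full).factor_C[:, 0], fs=FS), cutoff=FS / 8
        )
        hfr_crop = high_frequency_ratio(
            spectrogram(quick_cpd(crop_roi(full, self.LUMEN)).factor_C[:, 0], fs=FS),
            cutoff=FS / 8,
        )
        assert hfr_full < hfr_crop

    def test_lumen_outside_frame_rejected(self):
        loop = generate_speckle_video(LAMINAR_PRESET, shape=(10, 10), n_frames=10, seed=0)
        with pytest.raises(ValueError):
            add_clutter(loop, (2, 2, 12, 12))


class TestInjectArtifact:
    def test_gain_one_is_identity(self, laminar_loop):
        out = inject_artifact(laminar_loop, 100, 10, 1.0)
        np.testing.assert_array_equal(out.frames, laminar_loop.frames)

    def test_burst_detected_near_injection_time(self, laminar_loop):
        """A one-second brightness transient is flagged as fleeting on a
        temporal component, at time bins covering the injected frames."""
        start, span = 200, 60
        loop = inject_artifact(laminar_loop, start, span, 3.0)
        d = quick_cpd(loop)
        flagged = set()
        for r in range(3):
            S = spectrogram(d.factor_C[:, r] * d.weights[r], fs=FS,
                            window_len=64, overlap=32)
            flagged.update(detect_transient_peaks(S))
        assert flagged, "burst must be flagged on some temporal component"
        # every flagged bin overlaps the injected frame range (+/- one bin)
        hop = 32
        for b in flagged:
            centre = (b + 1) * hop  # first window is centred at one hop
            assert start - 2 * hop <= centre <= start + span + 2 * hop

    def test_whole_video_gain_not_fleeting(self, laminar_loop):
        loop = inject_artifact(laminar_loop, 0, laminar_loop.n_frames, 1.8)
        d = quick_cpd(loop)
        for r in range(3):
            S = spectrogram(d.factor_C[:, r] * d.weights[r], fs=FS,
                            window_len=64, overlap=32)
            assert detect_transient_peaks(S) == []

    def test_bounds_errors(self, laminar_loop):
        with pytest.raises(ValueError):
            inject_artifact(laminar_loop, 390, 20, 2.0)
        with pytest.raises(ValueError):
            inject_artifact(laminar_loop, 0, 10, 0.0)


class TestGenerateCohort:
    def small_config(self, **kw):
        defaults = dict(n_videos=12, frame_shape=(16, 16), n_frames=40,
                        lumen=(4, 4, 12, 12), seed=3)
        defaults.update(kw)
        return CohortConfig(**defaults)

    def test_bookkeeping_counts(self):
        cohort = generate_cohort(self.small_config())
        labels = [lab for _, lab, _ in cohort]
        sites = [site for _, _, site in cohort]
        assert labels.count(1) == labels.count(0) == 6
        from collections import Counter

        per_stratum = Counter(zip(sites, labels))
        assert all(v == 2 for v in per_stratum.values())

    def test_same_seed_byte_identical(self):
        a = generate_cohort(self.small_config())
        b = generate_cohort(self.small_config())
        for (la, ya, sa), (lb, yb, sb) in zip(a, b):
            assert (ya, sa) == (yb, sb)
            np.testing.assert_array_equal(la.frames, lb.frames)

    def test_labels_match_flow_class(self):
        # disturbed loops decorrelate faster, so lag-1 correlation
        # separates the classes without using the labels
        cohort = generate_cohort(self.small_config(n_frames=120))
        def lag1(loop):
            flat = loop.frames.reshape(-1, loop.n_frames)
            return np.corrcoef(flat[:, :-1].ravel(), flat[:, 1:].ravel())[0, 1]
        cors = {0: [], 1: []}
        for loop, lab, _ in cohort:
            cors[lab].append(lag1(loop))
        assert max(cors[1]) < min(cors[0])

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            self.small_config(n_videos=2)
        with pytest.raises(ValueError):
            self.small_config(lumen=(4, 4, 20, 12))
        with pytest.raises(ValueError):
            self.small_config(n_frames=2000)
        with pytest.raises(ValueError):
            CohortConfig(laminar=DISTURBED_PRESET, disturbed=DISTURBED_PRESET)

    def test_preset_ordering_invariant(self):
        assert DISTURBED_PRESET.decorrelation_rate > LAMINAR_PRESET.decorrelation_rate
        assert DISTURBED_PRESET.modulation_freq > LAMINAR_PRESET.modulation_freq


def test_class_conditional_high_frequency_separation():
    """Mean high-frequency ratio gap between the flow classes exceeds 0.1
    at a quarter-Nyquist cutoff (the stenosis signature the classifier
    exploits)."""
    ratios = {0: [], 1: []}
    for preset, lab in ((LAMINAR_PRESET, 0), (DISTURBED_PRESET, 1)):
        for s in range(6):
            loop = generate_speckle_video(preset, shape=(16, 16), n_frames=400,
                                          frame_rate=FS, seed=50 + s)
            S = spectrogram(mean_signal(loop), fs=FS)
            ratios[lab].append(high_frequency_ratio(S, cutoff=FS / 8))
    assert np.mean(ratios[1]) - np.mean(ratios[0]) > 0.1
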