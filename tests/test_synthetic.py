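"""Synthetic cohort generator: kernel shape, rendering arithmetic, determinism."""

import numpy as np
import pytest

from skinrems.config import CohortConfig, KernelParams
from skinrems.errors import ConfigurationError, InputError
from skinrems.synthetic import (
    SubjectMetadata,
    flush_kernel,
    generate_cohort,
    metadata_frame,
    render_frame,
)
from conftest import tiny_config, tiny_layout, uniform_amplitudes


class TestFlushKernel:
    params = KernelParams(peak_time=240.0, width=0.6)

    def test_onset_is_zero(self):
        assert flush_kernel(0.0, self.params) == 0.0

    def test_peak_is_one(self):
        assert flush_kernel(240.0, self.params) == pytest.approx(1.0)

    def test_monotone_rise_then_decay(self):
        rise = flush_kernel(np.linspace(1.0, 240.0, 100), self.params)
        decay = flush_kernel(np.linspace(240.0, 900.0, 100), self.params)
        assert np.all(np.diff(rise) > 0)
        assert np.all(np.diff(decay) < 0)
        assert np.all((rise >= 0) & (rise <= 1))

    def test_negative_time_rejected(self):
        with pytest.raises(InputError):
            flush_kernel(-1.0, self.params)


class TestRenderFrame:
    def test_noise_free_arithmetic(self, rng):
        layout = tiny_layout()
        masks = layout.patch_masks()
        frame = render_frame((120, 120, 120), masks, [(30, -10, 5)] * 3, 0.0, rng)
        patch_px = frame.pixels[masks[0]]
        assert np.all(patch_px == [150, 110, 125])
        outside = frame.pixels[~(masks[0] | masks[1] | masks[2])]
        assert np.all(outside == 120)

    def test_clipping(self, rng):
        layout = tiny_layout()
        masks = layout.patch_masks()
        frame = render_frame((250, 10, 10), masks, [(30, -30, 0)] * 3, 0.0, rng)
        patch_px = frame.pixels[masks[0]]
        assert np.all(patch_px[:, 0] == 255)
        assert np.all(patch_px[:, 1] == 0)

    def test_noise_sd_recovered(self, rng):
        layout = tiny_layout()
        masks = layout.patch_masks()
        frame = render_frame((120, 120, 120), masks, [(0, 0, 0)] * 3, 2.0, rng)
        sample = frame.pixels.astype(float).ravel()
        assert sample.size > 10_000
        assert abs(sample.std() - 2.0) / 2.0 < 0.10  # rounding inflates/deflates mildly

    def test_mask_shape_mismatch_errors(self, rng):
        good = np.zeros((10, 10), dtype=bool)
        good[2:4, 2:4] = True
        bad = np.zeros((12, 12), dtype=bool)
        bad[2:4, 2:4] = True
        with pytest.raises(InputError):
            render_frame((1, 2, 3), [good, bad], [(0, 0, 0)] * 2, 0.0, rng)


class TestGenerateCohort:
    def test_default_group_sizes_total_120(self):
        cfg = CohortConfig()
        assert sum(cfg.group_sizes.values()) == 120
        assert cfg.group_sizes == {"FEP": 33, "BD": 22, "SA": 13, "CS": 13, "HC": 39}
        assert cfg.n_frames == 15

    def test_sequences_and_frames_per_subject(self, tiny_cohort):
        cfg, (meta, seqs, truths) = tiny_cohort
        assert len(meta) == 8
        assert len(seqs) == 8 * 3  # one per concentration
        assert all(len(s) == cfg.n_frames for s in seqs)
        assert len(truths) == 8

    def test_determinism(self):
        a = generate_cohort(tiny_config(seed=11))
        b = generate_cohort(tiny_config(seed=11))
        for sa, sb in zip(a[1], b[1]):
            for fa, fb in zip(sa.frames, sb.frames):
                assert np.array_equal(fa.pixels, fb.pixels)
        assert metadata_frame(a[0]).equals(metadata_frame(b[0]))

    def test_null_cohort_frames_equal_baseline(self):
        cfg = tiny_config(amplitude_map=uniform_amplitudes((0, 0, 0)), noise_sd=0.0, baseline_sd=0.0)
        _, seqs, truths = generate_cohort(cfg)
        truth = truths[0]
        baseline = np.rint(truth.baseline_color)
        for frame in seqs[0].frames:
            assert np.all(frame.pixels == baseline)

    def test_trajectories_match_kernel(self, tiny_cohort):
        cfg, (_, _, truths) = tiny_cohort
        from skinrems.synthetic import flush_kernel

        k = flush_kernel(cfg.frame_times, cfg.kernel)
        for truth in truths:
            for conc, traj in truth.amplitude_trajectories.items():
                assert traj.shape == (cfg.n_frames, 3)
                peak = np.abs(traj).max(axis=1)
                if peak.max() > 0:
                    np.testing.assert_allclose(peak / peak.max(), k / k.max(), atol=1e-12)

    def test_mean_patch_color_tracks_truth_monte_carlo(self):
        """Rendered patch mean = baseline + amplitude*kernel within 3 sd/sqrt(n)."""
        cfg = tiny_config(group_sizes={"FEP": 0, "BD": 0, "SA": 0, "CS": 0, "HC": 2}, noise_sd=2.0)
        _, seqs, truths = generate_cohort(cfg)
        truth = truths[0]
        seq = next(s for s in seqs if s.subject_id == truth.subject_id and s.concentration == 0.1)
        mask = truth.patch_masks[0]
        n_px = mask.sum()
        tol = 3 * cfg.noise_sd / np.sqrt(n_px) + 0.5 / np.sqrt(n_px)  # noise + rounding
        for k, frame in enumerate(seq.frames):
            expected = truth.baseline_color + truth.amplitude_trajectories[0.1][k]
            observed = frame.pixels[mask].mean(axis=0)
            assert np.all(np.abs(observed - expected) < tol + 0.5)

    def test_masks_disjoint(self, tiny_cohort):
        _, (_, _, truths) = tiny_cohort
        t = truths[0]
        total = sum(m.astype(int) for m in t.patch_masks) + t.control_mask.astype(int)
        assert total.max() == 1

    def test_non_integral_frame_count_rejected(self):
        with pytest.raises(ConfigurationError):
            tiny_config(duration=890.0)

    def test_hc_metadata_has_no_disease_fields(self, tiny_cohort):
        _, (meta, _, _) = tiny_cohort
        df = metadata_frame(meta)
        hc = df[df["group"] == "HC"]
        pat = df[df["group"] != "HC"]
        assert hc[["duration_of_illness", "hospitalizations", "olanzapine_equiv", "panss_total"]].isna().all().all()
        assert pat[["duration_of_illness", "hospitalizations", "olanzapine_equiv", "panss_total"]].notna().all().all()
        assert np.isfinite(pat[["age", "bmi", "physical_activity"]].to_numpy()).all()

    def test_hc_with_disease_field_rejected(self):
        with pytest.raises(ConfigurationError):
            SubjectMetadata(
                subject_id="X",
                group="HC",
                age=30,
                gender=1,
                bmi=22,
                smoking=0,
                physical_activity=60,
                chronic_disease=0,
                family_history=0,
                panss_total=80.0,
            )
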