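import numpy as np
import pytest
from scipy.signal import find_peaks, hilbert, periodogram

from deglutio import simulate as sim
from deglutio.labels import CLASS_LABELS, SWALLOW_LABELS


class TestDefaultTemplate:
    def test_rest_is_baseline_only(self):
        tpl = sim.default_template("rest")
        assert tpl.emg1_amplitude_uV == 0.0
        assert tpl.emg2_amplitude_uV == 0.0

    @pytest.mark.parametrize("label", SWALLOW_LABELS)
    def test_normal_swallow_sequence(self, label):
        tpl = sim.default_template(label)
        o1, o2, o3 = tpl.ssw_onsets_s
        assert o1 < o2 < o3
        assert tpl.emg1_onset_s <= o1
        assert o1 <= tpl.emg2_onset_s <= o2

    def test_aspiration_slower_than_liquid(self):
        asp = sim.default_template("silent_aspiration")
        liq = sim.default_template("liquid")
        assert asp.transit_scale > liq.transit_scale
        assert asp.transit_scale >= 1.5
        assert asp.desync_jitter_s > 0

    def test_consistency_monotonicity(self):
        liq = sim.default_template("liquid")
        soft = sim.default_template("soft_food")
        dense = sim.default_template("dense_food")
        for attr in ("emg1_duration_s", "emg2_duration_s",
                     "emg1_amplitude_uV", "emg2_amplitude_uV"):
            assert getattr(liq, attr) < getattr(soft, attr) < getattr(dense, attr)

    def test_unknown_label_lists_valid_ones(self):
        with pytest.raises(ValueError, match="rest, liquid"):
            sim.default_template("nectar")

    def test_all_classes_have_templates(self):
        for lab in CLASS_LABELS:
            assert sim.default_template(lab).class_label == lab


class TestTemplateInvariants:
    def test_rejects_nonpositive_duration(self):
        with pytest.raises(ValueError, match="duration"):
            sim.SwallowTemplate("rest", 0, -1.0, 0, 0, 0.5, 0,
                                (0.1, 0.2, 0.3), (0.1, 0.1, 0.1))

    def test_rejects_unordered_ssw_for_swallow(self):
        with pytest.raises(ValueError, match="increasing"):
            sim.SwallowTemplate("liquid", 0.1, 0.5, 40, 0.4, 0.5, 34,
                                (0.9, 0.5, 0.2), (0.1, 0.1, 0.1))

    def test_aspiration_requires_stretch_and_jitter(self):
        with pytest.raises(ValueError, match="transit_scale"):
            sim.SwallowTemplate("silent_aspiration", 0.1, 0.5, 40, 0.4, 0.5, 15,
                                (0.2, 0.5, 0.9), (0.1, 0.1, 0.1),
                                desync_jitter_s=0.1, transit_scale=1.0)


class TestRenderEvent:
    def test_rest_sound_is_baseline(self):
        noise = sim.NoiseSpec()
        rec = sim.render_event(sim.default_template("rest"), 2000, seed=3, noise=noise)
        rms = np.sqrt(np.mean(rec.sound**2))
        assert rms <= noise.sound_white * 1.5

    def test_seeded_determinism(self):
        tpl = sim.default_template("liquid")
        a = sim.render_event(tpl, 2000, seed=7)
        b = sim.render_event(tpl, 2000, seed=7)
        assert np.array_equal(a.emg_ch1, b.emg_ch1)
        assert np.array_equal(a.emg_ch2, b.emg_ch2)
        assert np.array_equal(a.sound, b.sound)

    def test_different_seeds_differ(self):
        tpl = sim.default_template("liquid")
        a = sim.render_event(tpl, 2000, seed=1)
        b = sim.render_event(tpl, 2000, seed=2)
        assert not np.array_equal(a.sound, b.sound)

    def test_chewing_rhythm(self):
        rec = sim.render_event(sim.default_template("chewing"), 2000, seed=5)
        env = np.abs(hilbert(rec.emg_ch1))
        # smooth the envelope to one value per 50 ms
        k = 100
        smooth = np.convolve(env, np.ones(k) / k, mode="same")
        peaks, _ = find_peaks(smooth, height=0.4 * smooth.max(), distance=600)
        assert len(peaks) >= 3
        gaps = np.diff(peaks) / rec.fs_hz
        assert np.all((gaps >= 0.5) & (gaps <= 1.0))

    def test_chewing_sound_faint(self):
        chew = sim.render_event(sim.default_template("chewing"), 2000, seed=5)
        liq = sim.render_event(sim.default_template("liquid"), 2000, seed=5)
        assert np.max(np.abs(chew.sound)) < 0.5 * np.max(np.abs(liq.sound))

    def test_cough_single_loud_burst(self):
        rec = sim.render_event(sim.default_template("cough"), 2000, seed=9)
        liq = sim.render_event(sim.default_template("liquid"), 2000, seed=9)
        assert np.max(np.abs(rec.sound)) > np.max(np.abs(liq.sound))

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="2000"):
            sim.render_event(sim.default_template("liquid"), 1000, seed=0)

    def test_annotation_covers_event(self):
        rec = sim.render_event(sim.default_template("dense_food"), 2000, seed=1)
        assert len(rec.annotations) == 1
        ann = rec.annotations[0]
        assert ann.start_s == 0.0
        assert abs(ann.end_s - rec.duration_s) < 1e-9
        assert ann.realized is not None


class TestSequenceProperty:
    def test_normal_swallows_always_coherent(self):
        # timing realization oracle over 1000 seeded draws
        for label in SWALLOW_LABELS:
            tpl = sim.default_template(label)
            for seed in range(1000 // len(SWALLOW_LABELS)):
                truth = sim._realize_timing(tpl, np.random.default_rng(seed))
                assert sim.is_sequence_coherent(truth)

    def test_aspiration_majority_violated(self):
        tpl = sim.default_template("silent_aspiration")
        violated = sum(
            not sim.is_sequence_coherent(sim._realize_timing(tpl, np.random.default_rng(s)))
            for s in range(1000)
        )
        assert violated >= 500

    def test_rendered_aspiration_truth_matches_realization(self):
        rec = sim.render_event(sim.default_template("silent_aspiration"), 2000, seed=4)
        assert rec.annotations[0].realized.class_label == "silent_aspiration"


class TestGenerateSession:
    def test_all_liquid_counts(self):
        recs = sim.generate_session(1, 5, {"liquid": 1.0}, seed=1, gap_s=3.0)
        assert len(recs) == 1
        anns = recs[0].annotations
        assert len(anns) == 5
        assert all(a.class_label == "liquid" for a in anns)

    def test_total_annotation_count(self, uniform_mix):
        recs = sim.generate_session(4, 10, uniform_mix, seed=3, gap_s=2.0)
        assert len(recs) == 4
        assert sum(len(r.annotations) for r in recs) == 40

    def test_powerline_toggle_changes_60hz_power(self):
        quiet = sim.NoiseSpec(powerline_uV=0.0)
        loud = sim.NoiseSpec(powerline_uV=1.0)
        r0 = sim.generate_session(1, 0, {"liquid": 1.0}, noise=quiet, seed=5, gap_s=12.0)[0]
        r1 = sim.generate_session(1, 0, {"liquid": 1.0}, noise=loud, seed=5, gap_s=12.0)[0]
        f0, p0 = periodogram(r0.emg_ch1, fs=r0.fs_hz)
        f1, p1 = periodogram(r1.emg_ch1, fs=r1.fs_hz)
        band = (f0 >= 59) & (f0 <= 61)
        ratio_db = 10 * np.log10(p1[band].max() / p0[band].max())
        assert ratio_db >= 20

    def test_determinism_across_calls(self, uniform_mix):
        a = sim.generate_session(2, 3, uniform_mix, seed=42, gap_s=2.0)
        b = sim.generate_session(2, 3, uniform_mix, seed=42, gap_s=2.0)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.emg_ch1, rb.emg_ch1)
            assert np.array_equal(ra.sound, rb.sound)
            assert [x.class_label for x in ra.annotations] == \
                   [x.class_label for x in rb.annotations]

    def test_annotations_disjoint_and_bounded(self, small_session):
        for rec in small_session:
            anns = sorted(rec.annotations, key=lambda a: a.start_s)
            for a, b in zip(anns, anns[1:]):
                assert a.end_s <= b.start_s + 1e-9
            assert all(0 <= a.start_s < a.end_s <= rec.duration_s + 1e-9 for a in anns)

    def test_bad_mix_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sim.generate_session(1, 2, {"liquid": 0.4}, seed=0)
        with pytest.raises(ValueError, match="empty"):
            sim.generate_session(1, 2, {}, seed=0)
        with pytest.raises(ValueError, match="n_participants"):
            sim.generate_session(0, 2, {"liquid": 1.0}, seed=0)

    def test_participant_gains_vary(self, uniform_mix):
        recs = sim.generate_session(4, 2, uniform_mix, seed=8, gap_s=2.0)
        rms = [np.sqrt(np.mean(r.emg_ch1**2)) for r in recs]
        assert np.ptp(rms) > 0.01


class TestRecordingInvariants:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            sim.MultimodalRecording(np.zeros(5), np.zeros(5), np.zeros(4), 2000, "x")

    def test_overlapping_annotations_rejected(self):
        anns = [sim.EventAnnotation(0.0, 2.0, "liquid"),
                sim.EventAnnotation(1.0, 3.0, "cough")]
        with pytest.raises(ValueError, match="overlap"):
            sim.MultimodalRecording(np.zeros(8000), np.zeros(8000), np.zeros(8000),
                                    2000, "x", anns)

    def test_annotation_outside_rejected(self):
        anns = [sim.EventAnnotation(0.0, 99.0, "liquid")]
        with pytest.raises(ValueError, match="outside"):
            sim.MultimodalRecording(np.zeros(8000), np.zeros(8000), np.zeros(8000),
                                    2000, "x", anns)
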