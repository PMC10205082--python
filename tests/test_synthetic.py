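"""Synthetic cohort generator: determinism, template fidelity, planted effects."""

import numpy as np
import pytest

from conftest import subject_envelope_matrix
from tkagait import emg, kinematics as kin, synergies as syn, synthetic as sd


def _spec(**kw):
    base = dict(group_label="stable", n_subjects=1, cycles_per_subject=1,
                activity="level", seed=1)
    base.update(kw)
    return sd.CohortSpec(**base)


class TestSpecs:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            _spec(group_label="wobbly")
        with pytest.raises(ValueError):
            _spec(n_subjects=0)
        with pytest.raises(ValueError):
            _spec(activity="sprint")
        with pytest.raises(ValueError):
            sd.InstabilityEventSpec(onset_pct=float("nan"),
                                    posterior_amplitude_mm=1, anterior_amplitude_mm=1)
        with pytest.raises(ValueError):
            sd.InstabilityEventSpec(onset_pct=60, posterior_amplitude_mm=-1,
                                    anterior_amplitude_mm=1)

    def test_truth_rejects_negative_entries(self, level_truth):
        bad = level_truth.modules.copy()
        bad[0, 0] = -0.1
        with pytest.raises(ValueError):
            sd.GroundTruthSynergies(modules=bad, patterns=level_truth.patterns, k=4)


class TestDeterminismAndStreams:
    def test_bit_identical_regeneration(self):
        spec = _spec(n_subjects=2, cycles_per_subject=2)
        a = sd.generate_kinematics(spec)
        b = sd.generate_kinematics(spec)
        assert np.array_equal(a[1][1].poses.frames, b[1][1].poses.frames)
        ea = sd.generate_emg(spec, sd.default_truth("level"))
        eb = sd.generate_emg(spec, sd.default_truth("level"))
        assert np.array_equal(ea[0][1].raw.signals, eb[0][1].raw.signals)

    def test_adding_a_subject_preserves_existing_ones(self):
        small = sd.generate_kinematics(_spec(n_subjects=2))
        large = sd.generate_kinematics(_spec(n_subjects=3))
        assert np.array_equal(small[0][0].poses.frames, large[0][0].poses.frames)
        assert np.array_equal(small[1][0].poses.frames, large[1][0].poses.frames)


class TestKinematicsGeneration:
    def test_noise_free_angles_equal_templates(self):
        """With zero subject/cycle noise the decomposed pose angles reproduce
        the activity template curves to numerical tolerance."""
        kt = sd.generate_kinematics(_spec(), subject_noise=0.0, cycle_noise=0.0)[0][0]
        tracks = kin.pose_tracks(kt.poses, kt.geometry)
        tmpl = sd.template_curves("level", "stable", kt.truth["pct"],
                                  kt.truth["toe_off_pct"])
        for name in ("flexion", "abduction", "internal"):
            assert np.allclose(tracks[name], tmpl[name], atol=1e-9)
        assert np.allclose(tracks["medial_ap"], tmpl["medial_ap"], atol=1e-9)

    def test_level_stance_flexion_rom_in_published_band(self):
        """Generated stable level-walking cohorts keep stance flexion RoM
        within the published 47.2 +- 4.9 deg band (subject draws are centred
        on that mean)."""
        trials = sd.generate_kinematics(_spec(n_subjects=8, seed=23))
        roms = []
        for subj in trials:
            kt = subj[0]
            tracks = kin.pose_tracks(kt.poses, kt.geometry)
            cycle = kin.time_normalize_cycle(kt.poses, tracks)
            roms.append(kin.rom_summary(cycle).stance["flexion"])
        assert abs(np.mean(roms) - 47.2) < 4.9

    @pytest.mark.parametrize("condyles", ["medial", "lateral", "both"])
    def test_event_confined_to_swing_window(self, condyles):
        """The instability excursion changes the A-P tracks only inside the
        55-80% window, by brute-force pointwise comparison with a no-event
        run."""
        spec = _spec()
        base = sd.generate_kinematics(spec, subject_noise=0.0, cycle_noise=0.0)[0][0]
        ev = sd.InstabilityEventSpec(60.0, 4.0, 4.0, condyles)
        pert = sd.generate_kinematics(spec, event=ev, subject_noise=0.0,
                                      cycle_noise=0.0)[0][0]
        t0 = kin.pose_tracks(base.poses, base.geometry)
        t1 = kin.pose_tracks(pert.poses, pert.geometry)
        pct = base.truth["pct"]
        outside = (pct < 55.0) | (pct > 80.0)
        for track in ("medial_ap", "lateral_ap"):
            assert np.abs(t1[track] - t0[track])[outside].max() < 1e-9
        affected = "medial_ap" if condyles != "lateral" else "lateral_ap"
        assert np.abs(t1[affected] - t0[affected]).max() > 2.0

    def test_pose_frames_orthonormal_and_finite(self):
        kt = sd.generate_kinematics(_spec(seed=9))[0][0]
        assert np.isfinite(kt.poses.frames).all()  # PoseSeries also validates


class TestEMGGeneration:
    def test_zero_patterns_give_pure_noise(self, level_truth):
        zero = sd.GroundTruthSynergies(
            modules=level_truth.modules, patterns=np.zeros_like(level_truth.patterns), k=4
        )
        trials = sd.generate_emg(_spec(), zero)
        tr = trials[0][0]
        env = emg.filter_chain(tr.raw.signals, tr.raw.rate)
        assert np.abs(tr.raw.signals).max() < 0.05      # only the tiny noise floor
        assert env.max() < 0.01

    def test_chain_recovers_square_envelope(self):
        """Noiseless single-muscle square envelope: the conditioning chain
        recovers it with correlation > 0.95."""
        patterns = np.zeros((1, 200))
        patterns[0, 40:120] = 1.0
        truth = sd.GroundTruthSynergies(
            modules=np.eye(8)[:, :1], patterns=patterns + 0.0, k=1
        )
        trials = sd.generate_emg(_spec(seed=5), truth, noise_pct=0.0,
                                 module_jitter_sd=0.0, amp_jitter_sd=0.0,
                                 noise_floor=0.0)
        tr = trials[0][0]
        env = emg.filter_chain(tr.raw.signals, tr.raw.rate)
        e200 = emg.time_normalize_200(env, tr.raw.events)
        r = np.corrcoef(e200[0], tr.envelope_200[0])[0, 1]
        assert r > 0.95

    def test_envelopes_finite_and_non_negative(self, level_truth):
        trials = sd.generate_emg(_spec(n_subjects=2, cycles_per_subject=2), level_truth)
        for subj in trials:
            for tr in subj:
                assert np.isfinite(tr.raw.signals).all()
                assert tr.envelope_200.min() >= 0.0

    def test_nmf_recovers_planted_rank_and_modules(self, level_truth):
        """k=4 truth at the default 5% noise: rank selection returns 4 and
        matched module cosine similarity exceeds 0.90."""
        from scipy.optimize import linear_sum_assignment

        spec = _spec(n_subjects=2, cycles_per_subject=4, seed=31)
        for s in range(2):
            V = subject_envelope_matrix(spec, level_truth, subject=s)
            k, fits = syn.rank_scan(V, seed=100 + s)
            assert k == 4
            W = fits[4].modules / np.linalg.norm(fits[4].modules, axis=0)
            Wt = level_truth.modules / np.linalg.norm(level_truth.modules, axis=0)
            C = Wt.T @ W
            rows, cols = linear_sum_assignment(-C)
            assert C[rows, cols].mean() >= 0.90


class TestForceGeneration:
    def test_noise_free_detection_exact(self):
        trials = sd.generate_force(_spec(n_subjects=2, cycles_per_subject=2))
        for subj in trials:
            for tr in subj:
                assert kin.detect_heelstrike(tr.force_n) == tr.heelstrike_index

    def test_sensor_noise_within_one_pose_frame(self):
        clean = sd.generate_force(_spec(n_subjects=3, cycles_per_subject=3))
        noisy = sd.generate_force(_spec(n_subjects=3, cycles_per_subject=3), noise_n=5.0)
        for cs, ns in zip(clean, noisy):
            for ct, nt in zip(cs, ns):
                det = kin.detect_heelstrike(nt.force_n)
                err_s = abs(det - ct.heelstrike_index) / nt.rate
                assert err_s <= 1.0 / 30.0  # one fluoroscopy frame

    def test_all_zero_trace_gives_no_event(self):
        assert kin.detect_heelstrike(np.zeros(500)) is None


class TestPlantedFlexorWidening:
    def test_width_scale_widens_flexor_pattern_fwhm(self):
        narrow = sd.default_truth("stair", flexor_width_scale=1.0)
        wide = sd.default_truth("stair", flexor_width_scale=1.75)
        i = narrow.labels.index("dorsi_knee_flexors")
        assert syn.fwhm(wide.patterns[i]) > 1.5 * syn.fwhm(narrow.patterns[i])
        j = narrow.labels.index("knee_extensors")
        assert syn.fwhm(wide.patterns[j]) == syn.fwhm(narrow.patterns[j])
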