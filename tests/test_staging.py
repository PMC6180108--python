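"""Vigilance stage classification: cascade rules, adaptive thresholds, round trip."""

import numpy as np
import pytest

from vigikit import (EEGRecording, RegulationProfile, classify_recording,
                     simulate_stage_sequence, synthesize_eeg)
from vigikit.features import EpochFeatures, extract_features
from vigikit.staging import (StagingConfig, StagingThresholds,
                             adaptive_thresholds, classify_epoch)
from vigikit.stages import Stage

from conftest import agreement


def make_features(alpha_occ=10.0, alpha_ant=5.0, delta=5.0, theta=5.0,
                  total=None, rms=15.0, sem=False, spindle=False,
                  kcomplex=False, artifact=False):
    bp = {
        "delta": {"occipital": delta, "anterior": delta, "other": delta},
        "theta": {"occipital": theta, "anterior": theta, "other": theta},
        "alpha": {"occipital": alpha_occ, "anterior": alpha_ant,
                  "other": (alpha_occ + alpha_ant) / 2},
        "sigma": {"occipital": 1.0, "anterior": 1.0, "other": 1.0},
    }
    if total is None:
        total = {r: bp["delta"][r] + bp["theta"][r] + bp["alpha"][r] + 5.0
                 for r in ("occipital", "anterior", "other")}
    share = {r: bp["alpha"][r] / total[r] if total[r] else 0.0 for r in total}
    return EpochFeatures(
        index=0, bp=bp, total=total, alpha_share=share,
        anteriorization=alpha_ant / alpha_occ if alpha_occ else float("inf"),
        rms=rms, sem=sem, spindle=spindle, kcomplex=kcomplex, artifact=artifact)


THR = StagingThresholds(alpha_power_floor=10.0, rms_median=15.0,
                        config=StagingConfig())


class TestClassifyEpoch:
    def test_occipital_alpha_dominance_is_a1(self):
        f = make_features(alpha_occ=60.0, alpha_ant=24.0, delta=2, theta=2)
        assert f.best_alpha_share >= 0.45 and f.anteriorization == 0.4
        assert classify_epoch(f, THR) is Stage.A1

    def test_anteriorized_alpha_is_a23(self):
        f = make_features(alpha_occ=30.0, alpha_ant=45.0, delta=2, theta=2)
        assert classify_epoch(f, THR) is Stage.A23

    def test_spindle_overrides_alpha(self):
        f = make_features(alpha_occ=60.0, alpha_ant=10.0, spindle=True)
        assert classify_epoch(f, THR) is Stage.C

    def test_kcomplex_is_stage_c(self):
        f = make_features(kcomplex=True)
        assert classify_epoch(f, THR) is Stage.C

    def test_theta_delta_dominance_is_b23(self):
        f = make_features(alpha_occ=2.0, alpha_ant=2.0, delta=60.0, theta=60.0)
        assert classify_epoch(f, THR) is Stage.B23

    def test_sem_distinguishes_b1_from_stage0(self):
        low = dict(alpha_occ=1.0, alpha_ant=1.0, delta=3.0, theta=3.0, rms=8.0)
        assert classify_epoch(make_features(sem=True, **low), THR) is Stage.B1
        assert classify_epoch(make_features(sem=False, **low), THR) is Stage.ZERO

    def test_artifact_never_staged(self):
        f = make_features(artifact=True, spindle=True)
        assert classify_epoch(f, THR) is Stage.ARTIFACT

    def test_missing_eog_falls_back_to_amplitude(self):
        low = dict(alpha_occ=1.0, alpha_ant=1.0, delta=3.0, theta=3.0, sem=None)
        with pytest.warns(UserWarning, match="EOG"):
            assert classify_epoch(make_features(rms=5.0, **low), THR) is Stage.B1
        assert classify_epoch(make_features(rms=20.0, **low), THR) is Stage.ZERO


class TestAdaptiveThresholds:
    def test_identical_recordings_identical_thresholds(self, adaptive_pair):
        _, rec = adaptive_pair
        feats = extract_features(rec)
        a = adaptive_thresholds(feats)
        b = adaptive_thresholds(feats)
        assert a.alpha_power_floor == b.alpha_power_floor
        assert a.rms_median == b.rms_median

    def test_matches_independent_median_computation(self, adaptive_pair):
        """Oracle: thresholds recomputed directly from the feature arrays."""
        _, rec = adaptive_pair
        feats = extract_features(rec)
        cfg = StagingConfig()
        thr = adaptive_thresholds(feats, cfg)
        clean = [f for f in feats if not f.artifact]
        prov = [max(f.bp["alpha"].values()) for f in clean
                if max(f.alpha_share.values()) >= cfg.alpha_share_cut]
        assert thr.alpha_power_floor == pytest.approx(
            cfg.alpha_floor_frac * np.median(prov))
        assert thr.rms_median == pytest.approx(np.median([f.rms for f in clean]))

    def test_gain_change_leaves_labels_unchanged(self, adaptive_pair):
        tc, rec = adaptive_pair
        scaled = EEGRecording(data=rec.data * 0.9, fs=rec.fs,
                              ch_names=list(rec.ch_names), roles=list(rec.roles))
        a = classify_recording(rec)
        b = classify_recording(scaled)
        same = np.mean([x is y for x, y in zip(a.stages, b.stages)])
        assert same > 0.995

    def test_too_few_epochs_rejected(self):
        feats = [make_features() for _ in range(10)]
        with pytest.raises(ValueError, match="60"):
            adaptive_thresholds(feats)

    def test_degenerate_all_zero_rejected(self):
        zero = {r: 0.0 for r in ("occipital", "anterior", "other")}
        feats = [make_features(alpha_occ=0, alpha_ant=0, delta=0, theta=0,
                               total=dict(zero)) for _ in range(60)]
        with pytest.raises(ValueError, match="degenerate"):
            adaptive_thresholds(feats)


class TestClassifyRecording:
    def test_all_a1_recording_recovered(self, clean_signature):
        from vigikit.stages import VigilanceTimecourse
        tc = VigilanceTimecourse.from_labels([Stage.A1] * 900)
        rec = synthesize_eeg(tc, signature=clean_signature, seed=21)
        pred = classify_recording(rec)
        assert np.mean([s is Stage.A1 for s in pred.stages]) >= 0.95

    def test_adaptive_round_trip(self, adaptive_staged):
        tc, _, pred = adaptive_staged
        assert agreement(pred, tc) >= 0.90

    def test_every_epoch_receives_exactly_one_label(self, adaptive_staged):
        tc, _, pred = adaptive_staged
        assert pred.n_epochs == tc.n_epochs
        assert all(isinstance(s, Stage) for s in pred.stages)

    def test_square_wave_recording_is_all_artifact(self):
        fs = 250.0
        t = np.arange(int(120 * fs)) / fs
        sq = 150.0 * np.sign(np.sin(2 * np.pi * 5 * t) + 1e-9)
        rec = EEGRecording(data=np.vstack([sq] * 4), fs=fs,
                           ch_names=["Fz", "Cz", "Oz", "O1"])
        pred = classify_recording(rec)
        assert all(s is Stage.ARTIFACT for s in pred.stages)

    def test_nonadjacent_confusion_rare(self, adaptive_staged):
        """A-stage truth labelled C (or vice versa) must stay below 5%."""
        tc, _, pred = adaptive_staged
        a_stages = {Stage.ZERO, Stage.A1, Stage.A23}
        bad = sum(1 for t, p in zip(tc.stages, pred.stages)
                  if (t in a_stages and p is Stage.C)
                  or (t is Stage.C and p in a_stages))
        assert bad / tc.n_epochs < 0.05
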