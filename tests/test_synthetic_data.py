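"""Synthetic cohort generator: determinism, calibration, irradiance."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seizdyn import spectral as sp, synthetic_data as sd
from seizdyn.errors import ParameterError
from seizdyn.synthetic_data import (
    CohortConfig,
    draw_profile,
    fiber_irradiance,
    _subject_rng,
)


def _tiny_cfg(**kw):
    base = dict(
        group="sham_control",
        n_subjects=2,
        onset_mean_min=4.0,
        onset_sem_min=0.3,
        onset_n_printed=4,
        baseline_min=2.5,
        post_onset_min=1.5,
        seed=1,
    )
    base.update(kw)
    return CohortConfig(**base)


class TestProfiles:
    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**20), experimental=st.booleans())
    def test_envelope_zero_before_onset_and_nondecreasing_outside_remissions(
        self, seed, experimental
    ):
        cfg = _tiny_cfg(
            seed=seed,
            remission_rate_per_min=0.6 if experimental else 0.0,
            growth_tau_s=300.0 if experimental else 30.0,
        )
        profile = draw_profile(cfg, _subject_rng(cfg.seed, 0))
        t = np.arange(0.0, profile.onset_s + 900.0, 1.0)
        env = profile.envelope(t)
        assert np.all(env[t < profile.onset_s] == 0.0)
        in_remission = np.zeros(t.size, dtype=bool)
        for a, b in profile.remissions:
            in_remission |= (t >= a - 1.5) & (t < b + 1.5)
        outside = ~in_remission
        assert np.all(np.diff(env[outside]) >= -1e-12)
        assert np.all((env >= 0) & (env <= 1))

    def test_onset_sample_mean_converges(self):
        # law of large numbers at n=200 against the configured mean
        cfg = sd.default_cohorts(seed=404)[0]
        onsets = sd.sample_onsets(cfg, 200)
        sem200 = cfg.onset_sd_min / np.sqrt(200)
        assert abs(onsets.mean() - cfg.onset_mean_min) < 2 * sem200

    def test_onset_respects_floor(self):
        cfg = _tiny_cfg(onset_mean_min=2.2, onset_sem_min=1.0, onset_n_printed=4)
        assert sd.sample_onsets(cfg, 100).min() >= cfg.onset_floor_min


class TestGenerateSubject:
    def test_recording_layout_and_events(self):
        cfg = _tiny_cfg()
        rec, racine, profile = sd.generate_subject(cfg, 0)
        assert rec.channels == (
            "cortical_left", "cortical_right", "hippocampal_1", "hippocampal_2",
        )
        inj = rec.injection_time()
        assert inj == cfg.baseline_min * 60.0
        assert rec.events.times("pentobarbital").size == 1
        assert racine.scores.max() <= 5

    def test_determinism_per_subject(self):
        cfg = _tiny_cfg()
        rec1, _, prof1 = sd.generate_subject(cfg, 0)
        rec2, _, prof2 = sd.generate_subject(cfg, 0)
        np.testing.assert_array_equal(rec1.data, rec2.data)
        assert prof1 == prof2

    def test_duration_too_short_is_config_error(self):
        cfg = _tiny_cfg(duration_min=3.0)
        with pytest.raises(ParameterError):
            sd.generate_subject(cfg, 0)

    def test_no_suppression_keeps_first_bin_near_one(self):
        # light with suppression factor 1.0 leaves high-gamma untouched
        firsts = []
        for r in range(20):
            rec = sd.generate_pulse_session(n_pulses=5, suppression=1.0, seed=700 + r)
            for on in rec.events.times("light_on"):
                firsts.append(
                    sp.normalized_high_gamma(
                        rec, "hippocampal_1", float(on), n_bins=1
                    ).normalized[1]
                )
        assert np.mean(firsts) == pytest.approx(1.0, abs=0.1)

    def test_experimental_curves_lie_below_control_mean_early(self):
        # slow growth + remissions make experimental curves concave-up
        cfgs = {c.group: c for c in sd.default_cohorts(seed=42)}
        ctrl = sd.sample_llcum_curves(cfgs["sham_control"], 12)
        expe = sd.sample_llcum_curves(cfgs["experimental"], 12)
        early = slice(180, 600)  # minutes 3-10 of the seizure
        ctrl_mean = ctrl.mean(axis=0)[early]
        frac_below = np.mean(
            [np.mean(row[early] < ctrl_mean) > 0.5 for row in expe]
        )
        assert frac_below >= 0.8


class TestGenerateCohorts:
    def test_bundle_counts_and_determinism(self, tmp_path):
        cfgs = [_tiny_cfg(), _tiny_cfg(group="experimental", seed=2)]
        m1 = sd.generate_cohorts(cfgs, tmp_path / "a", seed=9)
        m2 = sd.generate_cohorts(cfgs, tmp_path / "b", seed=9)
        assert m1["manifest_sha1"] == m2["manifest_sha1"]
        files = list((tmp_path / "a").glob("*.csv"))
        # 4 subjects x (recording + events + racine)
        assert len(files) == 12
        assert (tmp_path / "a" / "manifest.json").exists()

    def test_different_seed_changes_bundle(self, tmp_path):
        cfgs = [_tiny_cfg()]
        m1 = sd.generate_cohorts(cfgs, tmp_path / "a", seed=1)
        m2 = sd.generate_cohorts(cfgs, tmp_path / "b", seed=2)
        assert m1["manifest_sha1"] != m2["manifest_sha1"]

    def test_duplicate_groups_rejected(self, tmp_path):
        with pytest.raises(ParameterError):
            sd.generate_cohorts([_tiny_cfg(), _tiny_cfg()], tmp_path)

    def test_zero_subjects_rejected(self):
        with pytest.raises(ParameterError):
            _tiny_cfg(n_subjects=0)


class TestPulseSession:
    def test_duration_arithmetic(self):
        rec = sd.generate_pulse_session(n_pulses=35, pulse_s=5.0, gap_s=30.0, lead_s=30.0)
        assert rec.duration_s == pytest.approx(30.0 + 35 * 35.0)
        assert rec.events.times("light_on").size == 35

    def test_bad_pulse_length_rejected(self):
        with pytest.raises(ParameterError):
            sd.generate_pulse_session(pulse_s=0.0)


class TestFiberIrradiance:
    def test_printed_fiber_parameters(self):
        # 18 mW out of a 200 µm core: ~573 mW/mm², i.e. 570 at 2 s.f.
        value = fiber_irradiance(18.0, 200.0)
        assert value == pytest.approx(572.96, rel=1e-3)
        assert float(f"{value:.2g}") == 570.0

    def test_zero_power(self):
        assert fiber_irradiance(0.0, 200.0) == 0.0

    def test_area_scaling(self):
        assert fiber_irradiance(18.0, 400.0) == pytest.approx(
            fiber_irradiance(18.0, 200.0) / 4.0
        )

    def test_bad_diameter(self):
        with pytest.raises(ParameterError):
            fiber_irradiance(18.0, 0.0)
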