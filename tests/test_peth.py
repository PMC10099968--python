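"""Trial filtering, PETH construction, z-scoring and latency detection."""

from __future__ import annotations

import numpy as np
import pytest

import microreach as mr
from microreach.synth import ClassProfile

from conftest import make_zprofile
from oracles import histogram_rate


def make_trial(i: int, door: float, rt_ms: float, dur_ms: float) -> mr.TrialEvents:
    lift = door + rt_ms / 1000.0
    entry = lift + dur_ms / 1000.0
    return mr.TrialEvents(i, door, lift, entry, entry + 0.5)


def make_unit(spikes, rf_class=1, cell_type="purkinje_simple") -> mr.UnitRecord:
    return mr.UnitRecord("u000", "cat01", cell_type, rf_class, np.asarray(spikes, float))


class TestReachDuration:
    def test_printed_mean_example(self):
        tr = mr.TrialEvents(0, 9.5, 10.0, 10.32, 10.9)
        assert mr.reach_duration(tr) == pytest.approx(320.0)

    def test_unordered_events_rejected(self):
        with pytest.raises(ValueError):
            mr.TrialEvents(0, 9.5, 10.0, 9.9, 10.9)


class TestFilterTrials:
    def test_duration_outlier_hand_computed(self):
        """7 × 300 ms + one 1200 ms trial: only the outlier is excluded.

        Mean 412.5 ms, population SD 297.6 ms; the 1200 ms trial deviates
        787.5 ms > 2.5 × SD ≈ 744 ms.
        """
        trials = [make_trial(i, 10.0 * (i + 1), 300.0, 300.0) for i in range(7)]
        trials.append(make_trial(7, 80.0, 300.0, 1200.0))
        kept, excluded = mr.filter_trials(trials)
        assert len(kept) == 7
        assert [(tr.trial_id, reason) for tr, reason in excluded] == [(7, "duration_outlier")]

    def test_short_reaction_time_excluded_regardless_of_duration(self):
        trials = [make_trial(i, 10.0 * (i + 1), 300.0, 300.0) for i in range(5)]
        trials.append(make_trial(5, 60.0, 100.0, 300.0))
        kept, excluded = mr.filter_trials(trials)
        assert len(kept) == 5
        assert [(tr.trial_id, r) for tr, r in excluded] == [(5, "reaction_time")]

    def test_identical_trials_all_kept(self):
        trials = [make_trial(i, 10.0 * (i + 1), 300.0, 320.0) for i in range(6)]
        kept, excluded = mr.filter_trials(trials)
        assert len(kept) == 6 and not excluded

    def test_fewer_than_three_trials_rejected(self):
        with pytest.raises(ValueError):
            mr.filter_trials([make_trial(0, 10.0, 300.0, 300.0)] * 2)

    def test_exclusion_accounting(self, default_profiles):
        _, _, kept, excluded, _ = default_profiles
        assert len(kept) + len(excluded) == 40
        assert all(r in ("reaction_time", "duration_outlier") for _, r in excluded)


class TestBuildZProfile:
    def test_hand_counted_histogram(self):
        """One spike at −950 ms (trial 1) and one at +50 ms (trial 2) → 50 Hz bins."""
        trials = [make_trial(0, 9.5, 500.0, 320.0), make_trial(1, 19.5, 500.0, 320.0)]
        # paw lifts at 10.0 s and 20.0 s
        unit = make_unit([10.0 - 0.945, 20.0 + 0.055])
        spec = mr.PethSpec()
        zp = mr.build_zprofile(unit, trials, spec)
        expected = np.zeros_like(zp.rate_raw)
        expected[np.flatnonzero(zp.bin_lefts == -950.0)[0]] = 50.0
        expected[np.flatnonzero(zp.bin_lefts == 50.0)[0]] = 50.0
        np.testing.assert_array_equal(zp.rate_raw, expected)

    def test_matches_pure_python_histogram_oracle(self):
        rng = np.random.default_rng(17)
        spec = mr.PethSpec()
        for _ in range(25):
            n_trials = int(rng.integers(1, 5))
            lifts = 10.0 + 10.0 * np.arange(n_trials)
            spikes = np.unique(rng.uniform(5.0, lifts[-1] + 5.0, size=rng.integers(5, 80)))
            trials = [make_trial(i, t0 - 0.5, 500.0, 320.0) for i, t0 in enumerate(lifts)]
            zp = mr.build_zprofile(make_unit(spikes), trials, spec)
            oracle = histogram_rate(spikes, lifts, spec.window, spec.bin_width)
            np.testing.assert_allclose(zp.rate_raw, oracle, atol=1e-9)

    def test_spike_count_conservation_exact(self):
        """Pre-smoothing, Σ rate × bin × n_trials equals the in-window spike count."""
        rng = np.random.default_rng(3)
        spec = mr.PethSpec()
        for _ in range(100):
            n_trials = int(rng.integers(1, 6))
            lifts = 10.0 + 10.0 * np.arange(n_trials)
            spikes = np.unique(rng.uniform(8.0, lifts[-1] + 2.0, size=rng.integers(1, 200)))
            trials = [make_trial(i, t0 - 0.5, 500.0, 320.0) for i, t0 in enumerate(lifts)]
            zp = mr.build_zprofile(make_unit(spikes), trials, spec)
            in_window = sum(
                int(np.sum((spikes >= t0 - 1.0) & (spikes < t0 + 1.0))) for t0 in lifts
            )
            total = zp.rate_raw.sum() * (spec.bin_width / 1000.0) * n_trials
            assert total == pytest.approx(in_window, abs=1e-6)

    def test_smoothing_conserves_interior_mass(self):
        spec = mr.PethSpec()
        trials = [make_trial(0, 9.5, 500.0, 320.0)]
        unit = make_unit([10.0 + 0.005 * k for k in range(-40, 41)])  # mass far from edges
        zp = mr.build_zprofile(unit, trials, spec)
        assert zp.rate.sum() == pytest.approx(zp.rate_raw.sum(), rel=1e-9)

    def test_baseline_z_identity(self, default_profiles):
        """Every generated profile has mean(z)=0 and SD(z)=1 over baseline bins."""
        spec, _, _, _, zps = default_profiles
        for zp in zps:
            assert not zp.flagged
            base = zp.z[(zp.bin_lefts >= -1000) & (zp.bin_lefts < -500)]
            assert base.mean() == pytest.approx(0.0, abs=1e-10)
            assert base.std(ddof=1) == pytest.approx(1.0, rel=1e-10)

    def test_silent_unit_flagged(self):
        trials = [make_trial(0, 9.5, 500.0, 320.0)]
        unit = make_unit([10.5])  # no baseline spikes
        zp = mr.build_zprofile(unit, trials, mr.PethSpec())
        assert zp.flagged
        assert not mr.detect_modulation(zp).significant


class TestDetectModulation:
    def test_single_bin_increase(self):
        """Literal single-bin rule: lone z=3 bin at −110 ms is the onset."""
        spec = mr.PethSpec(min_run_bins=1)
        z = np.zeros(len(spec.bin_lefts))
        z[np.flatnonzero(spec.bin_lefts == -110.0)[0]] = 3.0
        m = mr.detect_modulation(make_zprofile(spec, z), spec)
        assert m.significant
        assert m.direction == "increase"
        assert m.onset_latency == pytest.approx(-110.0)
        assert m.peak_latency == pytest.approx(-110.0)

    def test_first_crossing_sets_direction_peak_is_max_abs_z(self):
        spec = mr.PethSpec(min_run_bins=1)
        z = np.zeros(len(spec.bin_lefts))
        z[np.flatnonzero(spec.bin_lefts == -50.0)[0]] = -2.5
        z[np.flatnonzero(spec.bin_lefts == 100.0)[0]] = 4.0
        m = mr.detect_modulation(make_zprofile(spec, z), spec)
        assert m.direction == "decrease"
        assert m.onset_latency == pytest.approx(-50.0)
        assert m.peak_latency == pytest.approx(100.0)

    def test_sustained_run_requirement(self):
        """With min_run_bins=3 an isolated crossing is not significant."""
        spec = mr.PethSpec(min_run_bins=3)
        z = np.zeros(len(spec.bin_lefts))
        i = np.flatnonzero(spec.bin_lefts == 0.0)[0]
        z[i] = 3.0
        assert not mr.detect_modulation(make_zprofile(spec, z), spec).significant
        z[i : i + 3] = 3.0
        m = mr.detect_modulation(make_zprofile(spec, z), spec)
        assert m.significant and m.onset_latency == pytest.approx(0.0)

    def test_crossings_before_search_start_ignored(self):
        spec = mr.PethSpec(min_run_bins=1)
        z = np.zeros(len(spec.bin_lefts))
        z[np.flatnonzero(spec.bin_lefts == -700.0)[0]] = 5.0  # inside baseline window
        assert not mr.detect_modulation(make_zprofile(spec, z), spec).significant

    def test_onset_never_after_peak(self):
        rng = np.random.default_rng(8)
        for min_run in (1, 3, 7):
            spec = mr.PethSpec(min_run_bins=min_run)
            for _ in range(50):
                z = rng.normal(0, 1.3, size=len(spec.bin_lefts))
                m = mr.detect_modulation(make_zprofile(spec, z), spec)
                if m.significant:
                    assert m.onset_latency <= m.peak_latency


class TestClassPopulation:
    def test_single_unit_class_equals_unit_profile(self, default_profiles):
        spec, _, _, _, zps = default_profiles
        zp = zps[0]
        pop = mr.class_population_peth({zp.rf_class: [zp]}, spec)
        np.testing.assert_allclose(pop[zp.rf_class].z, zp.z, atol=1e-9)

    def test_identical_members_leave_profile_unchanged(self, default_profiles):
        spec, _, _, _, zps = default_profiles
        zp = zps[0]
        pop = mr.class_population_peth({zp.rf_class: [zp, zp]}, spec)
        np.testing.assert_allclose(pop[zp.rf_class].z, zp.z, atol=1e-9)

    def test_empty_class_skipped_with_warning(self, default_profiles):
        spec, *_ = default_profiles
        with pytest.warns(UserWarning, match="skipped"):
            pop = mr.class_population_peth({3: []}, spec)
        assert pop == {}

    def test_distal_population_onset_precedes_proximal(self, default_profiles):
        """Pooled distal classes (1,2,6) modulate before proximal ones (8,9,10)."""
        spec, _, _, _, zps = default_profiles
        by_class = {}
        for zp in zps:
            by_class.setdefault(zp.rf_class, []).append(zp)
        pop = mr.class_population_peth(by_class, spec)
        onsets = {c: mr.detect_modulation(zp, spec).onset_latency for c, zp in pop.items()}
        assert all(v is not None for v in onsets.values())
        distal = np.mean([onsets[c] for c in (1, 2, 6)])
        proximal = np.mean([onsets[c] for c in (8, 9, 10)])
        assert distal < proximal


class TestFastSlow:
    @staticmethod
    def _session(n_trials, profile, seed=31):
        cfg = mr.SessionConfig(units_per_class={profile.class_id: 1}, trials_per_unit=n_trials, rng_seed=seed)
        units, trials, _ = mr.simulate_session(cfg, [profile])
        return units[0], trials

    def test_requires_sixty_trials(self):
        p = ClassProfile(8, 30.0, 41.0, 0.0)
        unit, trials = self._session(20, p)
        with pytest.raises(ValueError, match="60"):
            mr.fast_slow_compare(unit, trials)

    def test_identical_durations_split_evenly(self):
        p = ClassProfile(8, 30.0, 0.0, 0.0)
        unit, _ = self._session(64, p)
        trials = [make_trial(i, 10.0 * (i + 1), 300.0, 320.0) for i in range(64)]
        res = mr.fast_slow_compare(unit, trials)
        assert len(res.fast_durations_ms) == len(res.slow_durations_ms) == 16

    def test_duration_coupled_modulation_separates_quartiles(self):
        """A bump anchored at tube entry peaks later on slow reaches."""
        p = ClassProfile(
            8, 30.0, 0.0, 0.0, amplitude=0.0, n_peaks=2,
            secondary_peaks=(("tube_entry", 0.0, 60.0),),
        )
        unit, trials = self._session(120, p)
        res = mr.fast_slow_compare(unit, trials)
        assert res.fast.significant and res.slow.significant
        assert res.slow.peak_latency > res.fast.peak_latency
        # and the split tracks the duration distribution itself
        assert res.slow_durations_ms.mean() > res.fast_durations_ms.mean()

    def test_duration_independent_modulation_similar_peaks(self):
        p = ClassProfile(8, 30.0, 0.0, 0.0, amplitude=60.0)
        unit, trials = self._session(120, p)
        res = mr.fast_slow_compare(unit, trials)
        assert res.fast.significant and res.slow.significant
        assert abs(res.fast.peak_latency - res.slow.peak_latency) <= 100.0
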