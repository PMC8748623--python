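import numpy as np
import pytest

from conftest import make_active_trial, make_passive_trial
from pfcplast.dataset import UnitSpikeTrain
from pfcplast.selection import (
    ScreeningError,
    best_location,
    epoch_rate,
    population_psth,
    screen_responsive_multi_location,
    screen_responsive_single_location,
)
from pfcplast.synthgen import PhaseEffects, SynthUnit, synthesize_unit_spikes


def _unit_from_counts(trials, counts_by_epoch, rng):
    """Build a spike train with the given per-trial counts placed
    uniformly inside each named epoch."""
    from pfcplast.selection import epoch_window
    spikes = {}
    for i, t in enumerate(trials):
        times = []
        for epoch, counts in counts_by_epoch.items():
            a, b = epoch_window(t, epoch)
            c = counts[i] if np.ndim(counts) else int(counts)
            times.append(rng.uniform(a, b, size=c))
        spikes[t.trial_id] = np.sort(np.concatenate(times))
    return UnitSpikeTrain(unit_id="u", kind="MUA", electrode=0, spikes=spikes)


class TestEpochRate:
    def test_rate_arithmetic(self):
        trial = make_passive_trial()
        # 5 spikes inside the 0.5 s cue epoch -> 10 spikes/s
        st = np.array([1.05, 1.1, 1.2, 1.3, 1.45])
        unit = UnitSpikeTrain("u", "MUA", 0, {0: st})
        assert epoch_rate(unit, trial, "cue") == pytest.approx(10.0)

    def test_empty_train_is_zero(self):
        trial = make_passive_trial()
        unit = UnitSpikeTrain("u", "MUA", 0, {0: np.array([])})
        assert epoch_rate(unit, trial, "cue") == 0.0

    def test_half_open_window_excludes_right_edge(self):
        trial = make_passive_trial()  # cue epoch [1.0, 1.5)
        unit = UnitSpikeTrain("u", "MUA", 0, {0: np.array([1.0, 1.5])})
        # left edge included, right edge excluded: exactly one spike
        assert epoch_rate(unit, trial, "cue") == pytest.approx(2.0)


class TestMultiLocationScreening:
    def test_planted_tuning_detected(self, rng):
        """2x cue gain at one location, 20 trials/location: high power."""
        eff = PhaseEffects(baseline_rate=10.0, cue_gain=2.0,
                           location_tuning_concentration=3.0)
        unit_params = SynthUnit("u", "MUA", 0, preferred_location=0,
                                match_preference=1,
                                responsive={"passive": True})
        trials = [make_passive_trial(trial_id=i, cue=i % 9)
                  for i in range(180)]
        hits = 0
        n_sim = 60
        for _ in range(n_sim):
            spikes = {t.trial_id: synthesize_unit_spikes(
                unit_params, t, eff, 1.0, rng) for t in trials}
            u = UnitSpikeTrain("u", "MUA", 0, spikes)
            if screen_responsive_multi_location(u, trials).is_responsive:
                hits += 1
        assert hits / n_sim > 0.95

    def test_degenerate_identical_rates_not_responsive(self, rng):
        trials = [make_passive_trial(trial_id=i, cue=i % 9)
                  for i in range(36)]
        unit = _unit_from_counts(trials, {"cue": 3, "delay1": 3}, rng)
        # deterministic equal counts: zero within- and between-group
        # variance must not crash and must not flag
        from pfcplast.selection import epoch_rates
        res = screen_responsive_multi_location(unit, trials)
        assert not res.is_responsive
        assert res.p_cue == 1.0

    def test_insufficient_trials_unevaluable(self, rng):
        trials = [make_passive_trial(trial_id=0, cue=0)]
        unit = _unit_from_counts(trials, {"cue": 2}, rng)
        with pytest.raises(ScreeningError):
            screen_responsive_multi_location(unit, trials)


class TestSingleLocationScreening:
    def _paired_unit(self, fix_rate, cue_rate, n, rng, kind="MUA",
                     delay_rate=None):
        trials = [make_active_trial(trial_id=i, cue=5, match=bool(i % 2),
                                    phase="I") for i in range(n)]
        fix = rng.poisson(fix_rate, size=n)  # 1 s fixation
        cue = rng.poisson(cue_rate * 0.5, size=n)  # 0.5 s cue
        d1 = rng.poisson((delay_rate if delay_rate is not None
                          else fix_rate) * 0.25, size=n)
        unit = _unit_from_counts(trials, {"fixation": fix, "cue": cue,
                                          "delay1": d1}, rng)
        unit.kind = kind
        return unit, trials

    def test_mua_fails_ten_percent_gate(self, rng):
        """8% increase, significant with n = 600: still not responsive."""
        unit, trials = self._paired_unit(50.0, 54.0, 600, rng, kind="MUA")
        res = screen_responsive_single_location(unit, trials)
        assert res.p_cue < 0.05
        assert not res.is_responsive

    def test_sua_exempt_from_ten_percent_gate(self, rng):
        unit, trials = self._paired_unit(50.0, 54.0, 600, rng, kind="SUA")
        res = screen_responsive_single_location(unit, trials)
        assert res.is_responsive

    def test_suppression_not_responsive(self, rng):
        unit, trials = self._paired_unit(50.0, 20.0, 200, rng)
        res = screen_responsive_single_location(unit, trials)
        assert res.p_cue < 0.05  # strongly modulated, but downward
        assert not res.is_responsive

    def test_delay_elevation_passes_without_gate(self, rng):
        unit, trials = self._paired_unit(10.0, 10.0, 300, rng, kind="MUA",
                                         delay_rate=16.0)
        res = screen_responsive_single_location(unit, trials)
        assert res.is_responsive

    def test_too_few_trials_unevaluable(self, rng):
        unit, trials = self._paired_unit(10.0, 20.0, 4, rng)
        with pytest.raises(ScreeningError):
            screen_responsive_single_location(unit, trials)


class TestBestLocation:
    def test_planted_preference_recovered(self, rng):
        eff = PhaseEffects(baseline_rate=8.0, cue_gain=3.0,
                           location_tuning_concentration=3.0)
        params = SynthUnit("u", "MUA", 0, preferred_location=2,
                           match_preference=1, responsive={"passive": True})
        trials = [make_passive_trial(trial_id=i, cue=i % 9)
                  for i in range(270)]  # 30 per location
        hits = 0
        for _ in range(40):
            spikes = {t.trial_id: synthesize_unit_spikes(
                params, t, eff, 1.0, rng) for t in trials}
            u = UnitSpikeTrain("u", "MUA", 0, spikes)
            hits += best_location(u, trials, "cue") == 2
        assert hits >= 39

    def test_single_location(self, rng):
        trials = [make_passive_trial(trial_id=i, cue=7) for i in range(5)]
        unit = _unit_from_counts(trials, {"cue": 3}, rng)
        assert best_location(unit, trials, "cue") == 7

    def test_tie_breaks_to_lowest_index(self, rng):
        trials = [make_passive_trial(trial_id=i, cue=c)
                  for i, c in enumerate([3, 5, 3, 5])]
        unit = _unit_from_counts(trials, {"cue": 2}, rng)
        assert best_location(unit, trials, "cue") == 3

    def test_permutation_equivariance(self, rng):
        rates = {0: 5, 1: 9, 2: 3}
        trials, counts = [], []
        for i in range(60):
            loc = i % 3
            trials.append(make_passive_trial(trial_id=i, cue=loc))
            counts.append(rng.poisson(rates[loc]))
        unit = _unit_from_counts(trials, {"cue": np.array(counts)}, rng)
        base = best_location(unit, trials, "cue")
        # relabel locations 0<->2 on the same counts
        perm = {0: 2, 1: 1, 2: 0}
        trials2 = [make_passive_trial(trial_id=t.trial_id,
                                      cue=perm[t.cue_location])
                   for t in trials]
        unit2 = UnitSpikeTrain("u", "MUA", 0, dict(unit.spikes))
        assert best_location(unit2, trials2, "cue") == perm[base]


class TestPopulationPsth:
    def test_flat_for_constant_rate(self, rng):
        eff = PhaseEffects(baseline_rate=15.0, cue_gain=0.0, delay_gain=0.0)
        params = SynthUnit("u", "MUA", 0, 0, 1, {"passive": False})
        trials = [make_passive_trial(trial_id=i, cue=0) for i in range(100)]
        spikes = {t.trial_id: synthesize_unit_spikes(params, t, eff, 1.0, rng)
                  for t in trials}
        unit = UnitSpikeTrain("u", "MUA", 0, spikes)
        res = population_psth([unit], [trials], -1.0, 2.0, bin_s=0.25,
                              best_location_epoch=None)
        assert np.all(np.abs(res["mean"] - 15.0) < 15.0 * 0.35)

    def test_count_conservation(self, rng):
        """PSTH integral x bin width equals the mean spike count."""
        trials = [make_passive_trial(trial_id=i, cue=0) for i in range(20)]
        spikes = {t.trial_id: np.sort(rng.uniform(0, t.end, size=40))
                  for t in trials}
        unit = UnitSpikeTrain("u", "MUA", 0, spikes)
        t_stop = trials[0].end - trials[0].cue_on
        res = population_psth([unit], [trials], -1.0, t_stop, bin_s=0.1,
                              best_location_epoch=None)
        total = res["psth"][0].sum() * 0.1
        assert total == pytest.approx(40.0, rel=0.02)

    def test_baseline_subtraction_zeroes_fixation(self, rng):
        trials = [make_passive_trial(trial_id=i, cue=0) for i in range(200)]
        spikes = {t.trial_id: np.sort(rng.uniform(0, t.end, size=30))
                  for t in trials}
        unit = UnitSpikeTrain("u", "MUA", 0, spikes)
        res = population_psth([unit], [trials], -1.0, 1.0, bin_s=0.25,
                              best_location_epoch=None,
                              baseline_subtract=True)
        fixation_bins = res["time"] < 0
        assert abs(res["psth"][0][fixation_bins].mean()) < 0.6

    def test_planted_ramp_recovered(self, rng):
        """Linear delay ramp of 3 spikes/s/s recovered within 10%."""
        slope = 3.0
        eff = PhaseEffects(baseline_rate=10.0, cue_gain=0.0, delay_gain=0.0,
                           ramp_slope=slope)
        trials = [make_active_trial(trial_id=i, cue=5, match=bool(i % 2),
                                    phase="III", delay=1.5)
                  for i in range(50)]
        units, tls = [], []
        for k in range(60):
            params = SynthUnit(f"u{k}", "MUA", 0, 5 if False else 0, 1,
                               {"active": True})
            spikes = {t.trial_id: synthesize_unit_spikes(
                params, t, eff, 1.0, rng) for t in trials}
            units.append(UnitSpikeTrain(f"u{k}", "MUA", 0, spikes))
            tls.append(trials)
        res = population_psth(units, tls, 0.6, 2.0, bin_s=0.1,
                              best_location_epoch=None)
        fit = np.polyfit(res["time"], res["mean"], 1)
        assert fit[0] == pytest.approx(slope, rel=0.10)

    def test_mixed_durations_rejected(self, rng):
        t1 = make_active_trial(trial_id=0, delay=0.25)
        t2 = make_active_trial(trial_id=1, delay=1.5)
        unit = UnitSpikeTrain("u", "MUA", 0,
                              {0: np.array([1.0]), 1: np.array([1.0])})
        with pytest.raises(ValueError, match="mixed|align"):
            population_psth([unit], [[t1, t2]], -1.0, 2.5,
                            best_location_epoch=None)
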