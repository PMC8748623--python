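import filecmp

import numpy as np
import pytest

from conftest import make_active_trial, make_passive_trial
from pfcplast.dataset import GridGeometry, write_dataset
from pfcplast.synthgen import (
    ConfigError,
    PhaseEffects,
    SynthConfig,
    SynthUnit,
    default_schedule,
    draw_shared_gains,
    generate_experiment,
    synthesize_lfp,
    synthesize_unit_spikes,
    unit_rate_function,
)


def _unit(preferred=0, responsive=True, kind="MUA"):
    return SynthUnit(unit_id="u0", kind=kind, electrode=0,
                     preferred_location=preferred, match_preference=1,
                     responsive={"passive": responsive, "active": responsive})


class TestConfig:
    def test_seed_mandatory(self):
        with pytest.raises(ConfigError, match="seed"):
            SynthConfig(seed=None)

    def test_zero_trials_rejected(self):
        with pytest.raises(ConfigError):
            SynthConfig(seed=1, n_trials_per_condition=0)

    def test_ramp_forbidden_in_phase_four(self):
        sched = default_schedule()
        bad = PhaseEffects(ramp_slope=2.0)
        sched[("IV", "active")] = bad
        with pytest.raises(ConfigError, match="ramp"):
            SynthConfig(seed=1, schedule=sched)


class TestDeterminism:
    def test_same_seed_same_bytes(self, tmp_path):
        kw = dict(n_units=6, n_trials_per_condition=2, sessions_per_phase=1,
                  n_lfp_electrodes=2, seed=11, phases=("pre", "I"))
        a = generate_experiment(SynthConfig(**kw))
        b = generate_experiment(SynthConfig(**kw))
        assert a == b
        write_dataset(a, tmp_path / "a")
        write_dataset(b, tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert filecmp.cmp(f, tmp_path / "b" / f.name, shallow=False), f

    def test_different_seed_differs(self):
        kw = dict(n_units=6, n_trials_per_condition=2, sessions_per_phase=1,
                  n_lfp_electrodes=0, phases=("pre",))
        a = generate_experiment(SynthConfig(seed=1, **kw))
        b = generate_experiment(SynthConfig(seed=2, **kw))
        assert a != b


@pytest.fixture(scope="module")
def experiment():
    cfg = SynthConfig(n_units=4, n_trials_per_condition=2,
                      sessions_per_phase=1, n_lfp_electrodes=0, seed=5)
    return generate_experiment(cfg)


class TestTrialStructure:

    def test_passive_block_precedes_active(self, experiment):
        for s in experiment.sessions:
            tasks = [t.task for t in s.trials]
            if "active" in tasks:
                assert tasks.index("active") > tasks.index("passive")
                first_active = tasks.index("active")
                assert all(x == "active" for x in tasks[first_active:])

    def test_early_phases_use_horizontal_locations_only(self, experiment):
        for s in experiment.sessions:
            active = s.trials_for_task("active")
            locs = {t.cue_location for t in active} | \
                {t.sample_location for t in active}
            if s.phase in ("I", "II"):
                assert locs <= {3, 5}
            elif s.phase in ("III", "IV"):
                assert {t.cue_location for t in active} == set(range(9))

    def test_phase_four_delays_in_range(self, experiment):
        for s in experiment.sessions_in_phase("IV"):
            for t in s.trials_for_task("active"):
                d1 = t.sample_on - t.cue_off
                assert 0.25 <= d1 <= 1.5
                assert t.targets_on - t.sample_off == pytest.approx(d1)

    def test_passive_delays_fixed(self, experiment):
        for s in experiment.sessions:
            for t in s.trials_for_task("passive"):
                assert t.sample_on - t.cue_off == pytest.approx(1.5)


class TestSpiking:
    def test_poisson_mean_rate(self, rng):
        """Constant 10 spikes/s: fixation-epoch counts have Poisson mean."""
        eff = PhaseEffects(baseline_rate=10.0, cue_gain=0.0, delay_gain=0.0)
        unit = _unit(responsive=False)
        trial = make_passive_trial()
        counts = []
        for _ in range(2000):
            st = synthesize_unit_spikes(unit, trial, eff, 1.0, rng)
            counts.append(np.count_nonzero(st < 1.0))  # 1 s fixation
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - 10.0) < 3 * se + 1e-9
        # Poisson: variance close to the mean
        assert np.var(counts) == pytest.approx(mean, rel=0.15)

    def test_no_tuning_means_equal_epoch_rates(self, rng):
        eff = PhaseEffects(baseline_rate=20.0, cue_gain=1.0, delay_gain=1.0)
        unit = _unit(responsive=False)  # planted effect off
        trial = make_passive_trial(cue=0)
        cue_counts, fix_counts = [], []
        for _ in range(1500):
            st = synthesize_unit_spikes(unit, trial, eff, 1.0, rng)
            fix_counts.append(np.count_nonzero(st < 1.0))
            cue_counts.append(np.count_nonzero((st >= 1.0) & (st < 1.5)))
        cue_rate = np.mean(cue_counts) / 0.5
        fix_rate = np.mean(fix_counts)
        se = np.std(cue_counts, ddof=1) / 0.5 / np.sqrt(1500)
        assert abs(cue_rate - fix_rate) < 4 * se

    def test_high_concentration_confines_tuning(self, rng):
        eff = PhaseEffects(baseline_rate=10.0, cue_gain=3.0,
                           location_tuning_concentration=50.0)
        unit = _unit(preferred=0)
        pref = make_passive_trial(cue=0)
        anti = make_passive_trial(cue=8)  # diametrically opposite
        pref_rates, anti_rates = [], []
        for _ in range(400):
            stp = synthesize_unit_spikes(unit, pref, eff, 1.0, rng)
            sta = synthesize_unit_spikes(unit, anti, eff, 1.0, rng)
            pref_rates.append(np.count_nonzero((stp >= 1.0) & (stp < 1.5)))
            anti_rates.append(np.count_nonzero((sta >= 1.0) & (sta < 1.5)))
        # preferred location carries the 4x cue response, opposite ~baseline
        assert np.mean(pref_rates) > 3.0 * np.mean(anti_rates)

    def test_ramp_only_before_targets(self):
        eff = PhaseEffects(baseline_rate=10.0, cue_gain=0.0, delay_gain=0.0,
                           ramp_slope=5.0)
        unit = _unit()
        trial = make_active_trial(delay=1.0)
        rate, peak = unit_rate_function(unit, trial, eff, 1.0)
        t_mid_delay = trial.cue_off + 0.5
        assert rate(np.array([t_mid_delay]))[0] == pytest.approx(12.5)
        assert rate(np.array([0.5]))[0] == pytest.approx(10.0)
        assert peak >= rate(np.array([trial.targets_on - 1e-6]))[0]


class TestSharedGains:
    grid = GridGeometry()

    def test_zero_noise_gives_independent_counts(self, rng):
        eff = PhaseEffects(shared_noise_sd=0.0)
        g = draw_shared_gains(np.array([0, 1, 8]), 1000, eff, self.grid, rng)
        assert np.all(g == 1.0)
        counts = rng.poisson(5.0 * g)
        r = np.corrcoef(counts.T)
        off = r[np.triu_indices(3, 1)]
        assert np.all(np.abs(off) < 3 / np.sqrt(1000))

    def test_infinite_corr_length_is_uniform(self, rng):
        eff = PhaseEffects(shared_noise_sd=0.3, spatial_corr_length_mm=1e9)
        g = draw_shared_gains(np.array([0, 63]), 4000, eff, self.grid, rng)
        # far-corner pair as correlated as any: kernel is constant
        r = np.corrcoef(np.log(g).T)[0, 1]
        assert r > 0.99

    def test_correlation_decays_with_distance(self, rng):
        """Mean pair correlation strictly decreasing over distance bins
        0, 0.75, 1.5, 3 mm at 1 mm correlation length."""
        eff = PhaseEffects(shared_noise_sd=0.4, spatial_corr_length_mm=1.0)
        # electrodes: two on col 0 row 0 (same), then 0.75/1.5/3 mm away
        electrodes = np.array([0, 0, 1, 2, 4])
        g = draw_shared_gains(electrodes, 10000, eff, self.grid, rng)
        counts = rng.poisson(8.0 * g)
        r = np.corrcoef(counts.T)
        by_distance = [r[0, 1], r[0, 2], r[0, 3], r[0, 4]]
        assert all(a > b for a, b in zip(by_distance, by_distance[1:]))

    def test_mean_gain_is_one(self, rng):
        eff = PhaseEffects(shared_noise_sd=0.5)
        g = draw_shared_gains(np.array([0, 9]), 20000, eff, self.grid, rng)
        assert g.mean(axis=0) == pytest.approx([1.0, 1.0], abs=0.02)


class TestLfp:
    def test_absent_band_stays_at_noise_floor(self, rng):
        from pfcplast.signals import multitaper_power
        eff = PhaseEffects(band_amp={"alpha": 0.0, "beta": 0.0, "gamma": 0.0})
        cfg = SynthConfig(seed=1, lfp_base_band_amp=0.0)
        trial = make_passive_trial()
        x = np.concatenate([
            synthesize_lfp(trial, eff, cfg, rng) for _ in range(10)
        ])
        sp = multitaper_power(x.astype(float), 500.0, window_s=1.0)
        psd = sp.power.mean(axis=0)
        beta = psd[(sp.freqs >= 20) & (sp.freqs <= 45)].mean()
        ref = psd[(sp.freqs >= 80) & (sp.freqs <= 100)].mean()
        # 1/f background only: beta power within a factor ~ (f2/f1) of the
        # high-frequency floor, no narrowband excess
        assert beta < 30 * ref

    def test_planted_cue_beta_visible(self, rng):
        from pfcplast.signals import STANDARD_BANDS, band_timecourse, \
            multitaper_power
        eff = PhaseEffects(band_amp={"alpha": 0.0, "beta": 2.0, "gamma": 0.0})
        cfg = SynthConfig(seed=1)
        trial = make_passive_trial()
        acc = None
        for _ in range(30):
            x = synthesize_lfp(trial, eff, cfg, rng).astype(float)
            sp = multitaper_power(x, 500.0, t0=-trial.cue_on)
            acc = sp.power if acc is None else acc + sp.power
        sp.power = acc / 30
        series = band_timecourse(sp, STANDARD_BANDS[1], (-1.0, -0.25))
        in_cue = (sp.times >= 0.05) & (sp.times < 0.45)
        far = sp.times > 1.5
        assert series[in_cue].mean() > 5 * abs(series[far].mean())

    def test_line_component_injected(self, rng):
        eff = PhaseEffects()
        cfg = SynthConfig(seed=1, line_amplitude=2.0)
        trial = make_passive_trial()
        x = synthesize_lfp(trial, eff, cfg, rng).astype(float)
        f = np.fft.rfftfreq(len(x), 1 / 500.0)
        spec = np.abs(np.fft.rfft(x))
        at60 = spec[np.argmin(np.abs(f - 60.0))]
        neighborhood = spec[(f > 62) & (f < 70)].mean()
        assert at60 > 5 * neighborhood


def test_zero_responsive_fraction_triggers_only_false_positives(rng):
    """With no planted tuning, ANOVA screening flags ~ the type-I rate."""
    from pfcplast.selection import screen_responsive_multi_location
    from pfcplast.dataset import UnitSpikeTrain
    eff = PhaseEffects(responsive_fraction=0.0, baseline_rate=8.0)
    trials = [make_passive_trial(trial_id=i, cue=i % 9) for i in range(90)]
    n_units, flagged = 150, 0
    unit = _unit(responsive=False)
    for _ in range(n_units):
        spikes = {
            t.trial_id: synthesize_unit_spikes(unit, t, eff, 1.0, rng)
            for t in trials
        }
        u = UnitSpikeTrain(unit_id="x", kind="MUA", electrode=0, spikes=spikes)
        if screen_responsive_multi_location(u, trials).is_responsive:
            flagged += 1
    # two-epoch OR rule: expected rate <= 1 - (1 - .05)^2 ~ 0.0975
    p = 1 - 0.95 ** 2
    se = np.sqrt(p * (1 - p) / n_units)
    assert flagged / n_units < p + 3 * se
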