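"""Synthetic multi-phase chronic-array experiments with planted effects.

The generator emulates the design of a staged working-memory training
study: daily sessions grouped into phases (pre-training, then I-IV), a
passive-fixation block followed by an active match/nonmatch block,
9 stimulus locations on a 3x3 grid, and spiking/LFP recorded from a
fixed 8x8 electrode grid. Each phase plants configurable effects —
responsive fraction, epoch rate gains, delay-period ramping, shared-gain
noise correlation decaying with electrode distance, and LFP band
amplitudes — that the downstream analysis stages must recover.

Spiking is an inhomogeneous Poisson process whose intensity is

    lambda(t) = g * [ b * (1 + tuning(t)) + ramp(t) ]

where ``g`` is a per-trial, per-unit multiplicative shared gain drawn
from a multivariate log-normal whose log-covariance decays exponentially
with inter-electrode distance (this is what produces distance-dependent
spike-count noise correlations), ``b`` the baseline rate, ``tuning`` a
von-Mises kernel over the 8 peripheral location angles applied in the
cue and first-delay epochs, and ``ramp`` a linear climb toward the
choice-target onset (phases I-III of the active task only).

LFP traces are 1/f-shaped Gaussian background plus band-limited alpha,
beta and gamma oscillations whose cue-epoch amplitudes follow the
per-phase effect schedule, with an optional 60 Hz line component for
exercising line removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .dataset import (
    CENTER_LOCATION,
    PERIPHERAL_LOCATIONS,
    PHASES,
    ExperimentDataset,
    GridGeometry,
    LfpTrace,
    SessionRecording,
    TaskTiming,
    TrialRecord,
    UnitSpikeTrain,
    config_digest,
    diametric_location,
    location_angle,
)

__all__ = [
    "PhaseEffects",
    "EffectSchedule",
    "SynthConfig",
    "SynthUnit",
    "default_schedule",
    "generate_experiment",
    "generate_session",
    "synthesize_unit_spikes",
    "synthesize_lfp",
    "draw_shared_gains",
    "unit_rate_function",
    "ConfigError",
    "GenerationError",
]

BANDS = ("alpha", "beta", "gamma")

# locations used for the early (single-location) active training phases:
# cue always right of fixation, nonmatch sample at the left
RIGHT_LOCATION = 5
LEFT_LOCATION = 3


class ConfigError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PhaseEffects:
    """Planted effect sizes for one (phase, task) cell.

    ``cue_gain`` and ``delay_gain`` are multiplicative rate increments at
    the preferred location; ``ramp_slope`` is in spikes/s per second;
    ``shared_noise_sd`` is the s.d. of the log shared gain;
    ``band_amp`` maps band name to the fractional cue-epoch amplitude
    increase of that oscillation over its fixation level.
    """

    responsive_fraction: float = 0.4
    baseline_rate: float = 5.0
    cue_gain: float = 1.0
    delay_gain: float = 0.5
    ramp_slope: float = 0.0
    shared_noise_sd: float = 0.3
    spatial_corr_length_mm: float = 1.0
    band_amp: Dict[str, float] = field(
        default_factory=lambda: {"alpha": 0.5, "beta": 1.0, "gamma": 0.5}
    )
    match_info_strength: float = 0.0
    location_tuning_concentration: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.responsive_fraction <= 1.0:
            raise ConfigError("responsive_fraction must be in [0, 1]")
        if self.baseline_rate < 0:
            raise ConfigError("baseline_rate must be nonnegative")
        for name in ("cue_gain", "delay_gain"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.match_info_strength <= 1.0:
            raise ConfigError("match_info_strength must be in [0, 1]")
        if self.location_tuning_concentration < 0:
            raise ConfigError("location_tuning_concentration must be >= 0")
        if set(self.band_amp) != set(BANDS):
            raise ConfigError(f"band_amp must define exactly {BANDS}")


#: (phase, task) -> PhaseEffects
EffectSchedule = Dict[Tuple[str, str], PhaseEffects]


def default_schedule() -> EffectSchedule:
    """Default effect schedule emulating the study's qualitative findings.

    Across active phases: responsive fraction and epoch gains rise; the
    delay ramp is present in phases I-III and absent in IV; shared-gain
    noise drops in phases III-IV (lower noise correlation); beta-band
    cue power declines while alpha rises. Passive-task values shadow the
    active ones at reduced effect size, with slightly higher shared
    noise (passive correlations exceed active ones) and no match
    information.
    """
    sched: EffectSchedule = {}

    def bands(alpha: float, beta: float, gamma: float) -> Dict[str, float]:
        return {"alpha": alpha, "beta": beta, "gamma": gamma}

    passive = {
        "pre": PhaseEffects(0.27, 5.0, 0.5, 0.2, 0.0, 0.40, 1.0,
                            bands(0.30, 1.00, 0.50), 0.0, 1.5),
        "I": PhaseEffects(0.30, 5.5, 0.6, 0.25, 0.0, 0.40, 1.0,
                          bands(0.40, 0.90, 0.48), 0.0, 1.5),
        "II": PhaseEffects(0.33, 6.0, 0.7, 0.3, 0.0, 0.38, 1.0,
                           bands(0.50, 0.75, 0.45), 0.0, 1.5),
        "III": PhaseEffects(0.38, 6.0, 0.8, 0.4, 0.0, 0.30, 1.0,
                            bands(0.65, 0.55, 0.42), 0.0, 1.5),
        "IV": PhaseEffects(0.40, 5.5, 0.8, 0.6, 0.0, 0.25, 1.0,
                           bands(0.80, 0.40, 0.40), 0.0, 1.5),
    }
    active = {
        "I": PhaseEffects(0.35, 6.5, 0.6, 0.3, 3.0, 0.35, 1.0,
                          bands(0.40, 1.00, 0.50), 0.2, 1.5),
        "II": PhaseEffects(0.45, 7.0, 0.9, 0.5, 3.0, 0.33, 1.0,
                           bands(0.55, 0.80, 0.46), 0.4, 1.5),
        "III": PhaseEffects(0.50, 8.0, 1.2, 0.7, 3.0, 0.25, 1.0,
                            bands(0.70, 0.55, 0.42), 0.5, 1.5),
        "IV": PhaseEffects(0.50, 8.0, 1.3, 1.0, 0.0, 0.20, 1.0,
                           bands(0.85, 0.35, 0.40), 0.5, 1.5),
    }
    for phase, eff in passive.items():
        sched[(phase, "passive")] = eff
    for phase, eff in active.items():
        sched[(phase, "active")] = eff
    return sched


def validate_schedule(sched: EffectSchedule) -> None:
    for (phase, task), eff in sched.items():
        if phase not in PHASES or task not in ("passive", "active"):
            raise ConfigError(f"unknown schedule cell {(phase, task)}")
        if phase == "IV" and eff.ramp_slope != 0.0:
            raise ConfigError("ramp_slope must be 0 in phase IV")
        if task == "passive" and eff.match_info_strength != 0.0:
            raise ConfigError("match information is active-task only")
    for phase in PHASES:
        if (phase, "passive") not in sched:
            raise ConfigError(f"schedule missing passive cell for phase {phase}")
        if phase != "pre" and (phase, "active") not in sched:
            raise ConfigError(f"schedule missing active cell for phase {phase}")


@dataclass
class SynthConfig:
    """Configuration of a synthetic experiment."""

    n_units: int = 60
    n_trials_per_condition: int = 10
    sessions_per_phase: int = 2
    phases: Sequence[str] = PHASES
    grid: GridGeometry = field(default_factory=GridGeometry)
    timing: TaskTiming = field(default_factory=TaskTiming)
    lfp_fs: float = 500.0
    n_lfp_electrodes: int = 12
    lfp_background_sd: float = 1.0
    lfp_base_band_amp: float = 0.5
    line_amplitude: float = 0.0  # 60 Hz component; 0 disables
    sua_fraction: float = 0.3
    active_accuracy: float = 0.85
    schedule: EffectSchedule = field(default_factory=default_schedule)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_units < 1 or self.n_trials_per_condition < 1 \
                or self.sessions_per_phase < 1:
            raise ConfigError("counts must be >= 1")
        unknown = set(self.phases) - set(PHASES)
        if unknown:
            raise ConfigError(f"unknown phases {sorted(unknown)}")
        if self.lfp_fs < 2 * 70:
            raise ConfigError("lfp_fs below twice the highest band edge")
        if not 0 <= self.n_lfp_electrodes <= self.grid.n_electrodes:
            raise ConfigError("n_lfp_electrodes out of range")
        validate_schedule(self.schedule)

    def digest(self) -> str:
        d = asdict(self)
        d["schedule"] = {f"{k[0]}/{k[1]}": asdict(v)
                         for k, v in sorted(self.schedule.items())}
        return config_digest(d)


@dataclass
class SynthUnit:
    """Latent parameters of one synthetic unit (per session)."""

    unit_id: str
    kind: str
    electrode: int
    preferred_location: int  # peripheral index; tuning peaks here
    match_preference: int  # +1 fires more on match, -1 on nonmatch
    responsive: Dict[str, bool]  # task -> planted responsiveness


# ---------------------------------------------------------------------------
# trial tables
# ---------------------------------------------------------------------------


def _passive_trial(tid: int, phase: str, cue: int, match: bool,
                   timing: TaskTiming) -> TrialRecord:
    sample = cue if match else diametric_location(cue)
    if cue == CENTER_LOCATION and not match:
        sample = 1  # center nonmatch goes to an adjacent location
    d = timing.passive_delay_s
    cue_on = timing.fixation_s
    cue_off = cue_on + timing.cue_s
    sample_on = cue_off + d
    sample_off = sample_on + timing.sample_s
    end = sample_off + d
    return TrialRecord(
        trial_id=tid, task="passive", phase=phase,
        cue_location=cue, sample_location=sample,
        is_match=(cue == sample), correct=True,
        fixation_on=0.0, cue_on=cue_on, cue_off=cue_off,
        sample_on=sample_on, sample_off=sample_off,
        targets_on=float("nan"), end=end,
    )


def _active_trial(tid: int, phase: str, cue: int, match: bool,
                  delay: float, correct: bool, timing: TaskTiming
                  ) -> TrialRecord:
    sample = cue if match else diametric_location(cue)
    if cue == CENTER_LOCATION and not match:
        sample = 1
    if phase in ("I", "II"):
        sample = cue if match else LEFT_LOCATION
    cue_on = timing.fixation_s
    cue_off = cue_on + timing.cue_s
    sample_on = cue_off + delay
    sample_off = sample_on + timing.sample_s
    targets_on = sample_off + delay
    end = targets_on + timing.post_sample_s
    return TrialRecord(
        trial_id=tid, task="active", phase=phase,
        cue_location=cue, sample_location=sample,
        is_match=(cue == sample), correct=correct,
        fixation_on=0.0, cue_on=cue_on, cue_off=cue_off,
        sample_on=sample_on, sample_off=sample_off,
        targets_on=targets_on, end=end,
    )


def build_trials(phase: str, cfg: SynthConfig, rng: np.random.Generator
                 ) -> List[TrialRecord]:
    """Trial table for one session: passive block, then (post-pre) active."""
    timing = cfg.timing
    k = cfg.n_trials_per_condition
    trials: List[TrialRecord] = []
    tid = 0
    # passive block: all 9 locations, match and nonmatch interleaved
    conds = [(cue, match) for cue in range(9) for match in (True, False)]
    order = rng.permutation(len(conds) * k)
    for idx in order:
        cue, match = conds[idx % len(conds)]
        trials.append(_passive_trial(tid, phase, cue, match, timing))
        tid += 1
    if phase == "pre":
        return trials
    # active block
    if phase in ("I", "II"):
        conds_a = [(RIGHT_LOCATION, True), (RIGHT_LOCATION, False)]
    else:
        conds_a = [(cue, match) for cue in range(9) for match in (True, False)]
    idxs = np.repeat(np.arange(len(conds_a)), k)
    if phase == "I":
        # blocked: all match trials, then all nonmatch
        idxs = np.sort(idxs)
    else:
        idxs = rng.permutation(idxs)
    for idx in idxs:
        cue, match = conds_a[idx]
        delay = (float(rng.uniform(timing.phase4_delay_min_s,
                                   timing.phase4_delay_max_s))
                 if phase == "IV" else timing.active_delay_s(phase))
        correct = bool(rng.random() < cfg.active_accuracy)
        trials.append(_active_trial(tid, phase, cue, match, delay,
                                    correct, timing))
        tid += 1
    return trials


# ---------------------------------------------------------------------------
# spiking
# ---------------------------------------------------------------------------


def _tuning_weight(location: int, preferred: int, concentration: float) -> float:
    """Von-Mises kernel over peripheral location angles; center is untuned."""
    if location == CENTER_LOCATION:
        return 0.0
    dtheta = location_angle(location) - location_angle(preferred)
    return float(np.exp(concentration * (np.cos(dtheta) - 1.0)))


def unit_rate_function(unit: SynthUnit, trial: TrialRecord,
                       effects: PhaseEffects, gain: float):
    """Return ``rate(t)`` (vectorized, spikes/s) and its maximum over the trial."""
    tuned = unit.responsive.get(trial.task, False)
    w = (_tuning_weight(trial.cue_location, unit.preferred_location,
                        effects.location_tuning_concentration)
         if tuned else 0.0)
    cue_mult = 1.0 + effects.cue_gain * w
    delay_mult = 1.0 + effects.delay_gain * w
    if tuned and trial.task == "active" and effects.match_info_strength > 0:
        m = 1.0 if trial.is_match else -1.0
        sample_mult = 1.0 + effects.match_info_strength * 0.5 * (
            1.0 + unit.match_preference * m
        )
    else:
        sample_mult = 1.0
    ramp_on = (tuned and trial.task == "active"
               and effects.ramp_slope > 0 and not np.isnan(trial.targets_on))
    b = effects.baseline_rate

    def rate(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        mult = np.ones_like(t)
        mult = np.where((t >= trial.cue_on) & (t < trial.cue_off),
                        cue_mult, mult)
        mult = np.where((t >= trial.cue_off) & (t < trial.sample_on),
                        delay_mult, mult)
        mult = np.where((t >= trial.sample_on) & (t < trial.end),
                        sample_mult, mult)
        lam = b * mult
        if ramp_on:
            ramp = effects.ramp_slope * (t - trial.cue_off)
            lam = lam + np.where(
                (t >= trial.cue_off) & (t < trial.targets_on),
                np.maximum(ramp, 0.0), 0.0,
            )
        return gain * lam

    peak_mult = max(1.0, cue_mult, delay_mult, sample_mult)
    peak = gain * b * peak_mult
    if ramp_on:
        peak = max(peak, gain * (b * max(delay_mult, sample_mult)
                                 + effects.ramp_slope
                                 * (trial.targets_on - trial.cue_off)))
    return rate, peak


def synthesize_unit_spikes(unit: SynthUnit, trial: TrialRecord,
                           effects: PhaseEffects, gain: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Draw one trial's spike train by thinning a homogeneous Poisson process."""
    rate, lam_max = unit_rate_function(unit, trial, effects, gain)
    if lam_max < 0:
        raise GenerationError("negative peak intensity")
    if lam_max == 0:
        return np.empty(0, dtype=np.float64)
    duration = trial.end
    n = rng.poisson(lam_max * duration)
    t = np.sort(rng.uniform(0.0, duration, size=n))
    lam = rate(t)
    if np.any(lam < 0):
        raise GenerationError("negative intensity after composition")
    keep = rng.uniform(0.0, lam_max, size=n) < lam
    return t[keep]


def draw_shared_gains(electrodes: np.ndarray, n_trials: int,
                      effects: PhaseEffects, grid: GridGeometry,
                      rng: np.random.Generator) -> np.ndarray:
    """(n_trials, n_units) multiplicative shared gains, unit mean.

    log-gains are multivariate normal with covariance
    ``sd^2 * exp(-d_ij / corr_length)`` over inter-electrode distances,
    so pairwise spike-count correlations decay exponentially with
    distance and are largest for same-electrode pairs.
    """
    sd = effects.shared_noise_sd
    n_units = len(electrodes)
    if sd == 0:
        return np.ones((n_trials, n_units))
    L = effects.spatial_corr_length_mm
    if L <= 0:
        raise ConfigError("spatial_corr_length_mm must be positive")
    pos = grid.all_positions_mm()[np.asarray(electrodes, dtype=int)]
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    cov = sd ** 2 * np.exp(-d / L)
    cov[np.diag_indices_from(cov)] += 1e-10 * sd ** 2
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise GenerationError("shared-gain covariance not positive definite") \
            from exc
    z = rng.standard_normal((n_trials, n_units)) @ chol.T
    return np.exp(z - 0.5 * sd ** 2)


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

_BAND_EDGES = {"alpha": (8.0, 14.0), "beta": (20.0, 45.0), "gamma": (46.0, 70.0)}


def _narrowband_noise(n: int, fs: float, lo: float, hi: float,
                      rng: np.random.Generator) -> np.ndarray:
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + 2 * int(fs)))
    x = x[int(fs):int(fs) + n]
    s = x.std()
    return x / s if s > 0 else x


def _pink_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with 1/f amplitude spectrum, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = 1.0 / np.sqrt(f[nz])
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    s = x.std()
    return x / s if s > 0 else x


def synthesize_lfp(trial: TrialRecord, effects: PhaseEffects,
                   cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """One trial's LFP: 1/f background + epoch-modulated band oscillations."""
    fs = cfg.lfp_fs
    nyq = fs / 2
    if any(hi >= nyq for _, hi in _BAND_EDGES.values()):
        raise ConfigError("band edges at or above Nyquist")
    n = int(round(trial.end * fs))
    t = np.arange(n) / fs
    x = cfg.lfp_background_sd * _pink_noise(n, fs, rng)
    in_cue = (t >= trial.cue_on) & (t < trial.cue_off)
    for band, (lo, hi) in _BAND_EDGES.items():
        osc = _narrowband_noise(n, fs, lo, hi, rng)
        envelope = np.where(in_cue, 1.0 + effects.band_amp[band], 1.0)
        x = x + cfg.lfp_base_band_amp * envelope * osc
    if cfg.line_amplitude > 0:
        x = x + cfg.line_amplitude * np.sin(
            2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi)
        )
    return x.astype(np.float32)


# ---------------------------------------------------------------------------
# sessions and experiments
# ---------------------------------------------------------------------------


def _make_units(phase: str, session_index: int, cfg: SynthConfig,
                rng: np.random.Generator) -> List[SynthUnit]:
    units = []
    peripherals = np.array(PERIPHERAL_LOCATIONS)
    for i in range(cfg.n_units):
        kind = "SUA" if rng.random() < cfg.sua_fraction else "MUA"
        responsive = {}
        for task in ("passive", "active"):
            key = (phase, task)
            if key in cfg.schedule:
                responsive[task] = bool(
                    rng.random() < cfg.schedule[key].responsive_fraction
                )
        units.append(
            SynthUnit(
                unit_id=f"s{session_index:03d}_u{i:03d}",
                kind=kind,
                electrode=int(rng.integers(cfg.grid.n_electrodes)),
                preferred_location=int(rng.choice(peripherals)),
                match_preference=int(rng.choice([-1, 1])),
                responsive=responsive,
            )
        )
    return units


def generate_session(phase: str, session_index: int, cfg: SynthConfig,
                     seed_seq: np.random.SeedSequence) -> SessionRecording:
    """One synthetic daily session, deterministically from its seed sequence."""
    ss_trials, ss_units, ss_gains, ss_spikes, ss_lfp = seed_seq.spawn(5)
    rng_trials = np.random.default_rng(ss_trials)
    trials = build_trials(phase, cfg, rng_trials)
    units = _make_units(phase, session_index, cfg, np.random.default_rng(ss_units))
    electrodes = np.array([u.electrode for u in units])

    # shared gains drawn per task block so the planted correlation level
    # can differ between passive and active
    rng_gains = np.random.default_rng(ss_gains)
    gains: Dict[int, np.ndarray] = {}
    for task in ("passive", "active"):
        key = (phase, task)
        if key not in cfg.schedule:
            continue
        block = [tr for tr in trials if tr.task == task]
        if not block:
            continue
        g = draw_shared_gains(electrodes, len(block), cfg.schedule[key],
                              cfg.grid, rng_gains)
        for j, tr in enumerate(block):
            gains[tr.trial_id] = g[j]

    spike_rngs = [np.random.default_rng(s) for s in ss_spikes.spawn(len(units))]
    out_units: List[UnitSpikeTrain] = []
    for i, u in enumerate(units):
        spikes = {}
        for tr in trials:
            eff = cfg.schedule[(phase, tr.task)]
            spikes[tr.trial_id] = synthesize_unit_spikes(
                u, tr, eff, float(gains[tr.trial_id][i]), spike_rngs[i]
            )
        out_units.append(
            UnitSpikeTrain(unit_id=u.unit_id, kind=u.kind,
                           electrode=u.electrode, spikes=spikes)
        )

    lfp: List[LfpTrace] = []
    if cfg.n_lfp_electrodes > 0:
        rng_pick = np.random.default_rng(ss_lfp)
        chosen = rng_pick.choice(cfg.grid.n_electrodes,
                                 size=cfg.n_lfp_electrodes, replace=False)
        lfp_rngs = [np.random.default_rng(s)
                    for s in ss_lfp.spawn(cfg.n_lfp_electrodes)]
        for e_idx, electrode in enumerate(np.sort(chosen)):
            samples = {
                tr.trial_id: synthesize_lfp(
                    tr, cfg.schedule[(phase, tr.task)], cfg, lfp_rngs[e_idx]
                )
                for tr in trials
            }
            lfp.append(LfpTrace(electrode=int(electrode), fs=cfg.lfp_fs,
                                samples=samples))

    return SessionRecording(
        session_index=session_index, phase=phase, trials=trials,
        units=out_units, lfp=lfp, grid=cfg.grid,
    )


def generate_experiment(cfg: SynthConfig) -> ExperimentDataset:
    """Full multi-phase synthetic experiment; deterministic given the seed."""
    master = np.random.SeedSequence(cfg.seed)
    phases = [p for p in PHASES if p in cfg.phases]
    n_sessions = len(phases) * cfg.sessions_per_phase
    session_seeds = master.spawn(n_sessions)
    sessions: List[SessionRecording] = []
    idx = 0
    for phase in phases:
        for _ in range(cfg.sessions_per_phase):
            sessions.append(
                generate_session(phase, idx, cfg, session_seeds[idx])
            )
            idx += 1
    ds = ExperimentDataset(sessions=sessions, seed=cfg.seed,
                           config_hash=cfg.digest())
    ds.validate()
    return ds
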