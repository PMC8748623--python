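"""Epoch firing rates, responsiveness screening, best location, PSTHs.

Responsiveness is screened two ways, mirroring the two task regimes:

* multi-location sessions: a one-way ANOVA of epoch firing rate across
  the available cue locations, run separately on the cue epoch and the
  first delay epoch; a unit is responsive if either p < alpha.
* single-location sessions (early active training): a paired t-test of
  cue-epoch (and delay1-epoch) rate against the fixation rate; the unit
  must fire above fixation, and multi-unit records must additionally
  show at least a 10% rate increase during the stimulus presentation
  (single units are exempt from the 10% gate).

Rate analyses use correct trials only. Half-open windows [start, end)
throughout, so a spike exactly at an epoch boundary counts once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .dataset import TrialRecord, UnitSpikeTrain

__all__ = [
    "EPOCH_NAMES",
    "EpochDefinition",
    "ResponsivenessResult",
    "ScreeningError",
    "epoch_window",
    "epoch_rate",
    "epoch_rates",
    "screen_responsive_multi_location",
    "screen_responsive_single_location",
    "best_location",
    "population_psth",
    "bin_spike_counts",
]

EPOCH_NAMES = ("fixation", "cue", "delay1", "sample", "delay2")


class ScreeningError(RuntimeError):
    """The unit cannot be evaluated (too few trials), as opposed to
    being evaluated and found unresponsive."""


@dataclass(frozen=True)
class EpochDefinition:
    """A named analysis window; ``start``/``end`` offsets are relative to
    the epoch's defining events taken from the trial record."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in EPOCH_NAMES:
            raise ValueError(f"unknown epoch {self.name!r}")


def epoch_window(trial: TrialRecord, epoch: str) -> Tuple[float, float]:
    """[start, end) window of a named epoch on one trial."""
    if epoch == "fixation":
        return (trial.fixation_on, trial.cue_on)
    if epoch == "cue":
        return (trial.cue_on, trial.cue_off)
    if epoch == "delay1":
        return (trial.cue_off, trial.sample_on)
    if epoch == "sample":
        return (trial.sample_on, trial.sample_off)
    if epoch == "delay2":
        end = trial.targets_on if not np.isnan(trial.targets_on) else trial.end
        return (trial.sample_off, end)
    raise ValueError(f"unknown epoch {epoch!r}")


def epoch_rate(unit: UnitSpikeTrain, trial: TrialRecord, epoch: str) -> float:
    """Firing rate (spikes/s) in one epoch of one trial."""
    start, end = epoch_window(trial, epoch)
    if end <= start:
        raise ValueError(f"zero-duration epoch {epoch!r}")
    st = unit.spikes.get(trial.trial_id)
    if st is None or st.size == 0:
        return 0.0
    count = int(np.count_nonzero((st >= start) & (st < end)))
    return count / (end - start)


def epoch_rates(unit: UnitSpikeTrain, trials: Sequence[TrialRecord],
                epoch: str) -> np.ndarray:
    return np.array([epoch_rate(unit, t, epoch) for t in trials])


@dataclass
class ResponsivenessResult:
    unit_id: str
    is_responsive: bool
    test: str  # "anova_locations" | "paired_vs_fixation"
    p_cue: float
    p_delay1: float
    percent_rate_increase: float  # cue epoch vs fixation, in %
    best_cue_location: Optional[int]
    best_delay1_location: Optional[int]


def _safe_anova(groups: List[np.ndarray]) -> float:
    """One-way ANOVA p-value; degenerate (zero-variance) data give p = 1."""
    concat = np.concatenate(groups)
    if np.ptp(concat) == 0:
        return 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = stats.f_oneway(*groups)
    return 1.0 if np.isnan(p) else float(p)


def _percent_increase(stim: np.ndarray, fix: np.ndarray) -> float:
    mfix = fix.mean()
    if mfix == 0:
        return np.inf if stim.mean() > 0 else 0.0
    return 100.0 * (stim.mean() - mfix) / mfix


def screen_responsive_multi_location(
    unit: UnitSpikeTrain,
    trials: Sequence[TrialRecord],
    alpha: float = 0.05,
) -> ResponsivenessResult:
    """ANOVA screening across cue locations (cue and delay1 epochs)."""
    by_loc: Dict[int, List[TrialRecord]] = {}
    for t in trials:
        by_loc.setdefault(t.cue_location, []).append(t)
    eligible = {loc: ts for loc, ts in by_loc.items() if len(ts) >= 2}
    if len(eligible) < 2:
        raise ScreeningError(
            f"unit {unit.unit_id}: need >= 2 locations with >= 2 trials"
        )
    p_by_epoch = {}
    for epoch in ("cue", "delay1"):
        groups = [epoch_rates(unit, ts, epoch) for ts in eligible.values()]
        p_by_epoch[epoch] = _safe_anova(groups)
    fix = epoch_rates(unit, list(trials), "fixation")
    cue = epoch_rates(unit, list(trials), "cue")
    return ResponsivenessResult(
        unit_id=unit.unit_id,
        is_responsive=(p_by_epoch["cue"] < alpha or p_by_epoch["delay1"] < alpha),
        test="anova_locations",
        p_cue=p_by_epoch["cue"],
        p_delay1=p_by_epoch["delay1"],
        percent_rate_increase=_percent_increase(cue, fix),
        best_cue_location=best_location(unit, trials, "cue"),
        best_delay1_location=best_location(unit, trials, "delay1"),
    )


def _paired_p(stim: np.ndarray, fix: np.ndarray) -> float:
    if np.ptp(stim - fix) == 0:
        return 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = stats.ttest_rel(stim, fix)
    return 1.0 if np.isnan(p) else float(p)


def screen_responsive_single_location(
    unit: UnitSpikeTrain,
    trials: Sequence[TrialRecord],
    alpha: float = 0.05,
    min_increase_frac: float = 0.10,
) -> ResponsivenessResult:
    """Paired screening against the fixation rate (single cue location).

    Responsive iff the cue-epoch path (p < alpha, elevated, and for MUA
    a >= 10% increase over fixation) or the delay1-epoch path (p < alpha
    and elevated) succeeds.
    """
    trials = list(trials)
    if len(trials) < 5:
        raise ScreeningError(f"unit {unit.unit_id}: fewer than 5 trials")
    fix = epoch_rates(unit, trials, "fixation")
    cue = epoch_rates(unit, trials, "cue")
    d1 = epoch_rates(unit, trials, "delay1")
    p_cue = _paired_p(cue, fix)
    p_d1 = _paired_p(d1, fix)
    pct = _percent_increase(cue, fix)
    cue_ok = p_cue < alpha and cue.mean() > fix.mean()
    if unit.kind == "MUA":
        cue_ok = cue_ok and cue.mean() >= (1.0 + min_increase_frac) * fix.mean()
    d1_ok = p_d1 < alpha and d1.mean() > fix.mean()
    return ResponsivenessResult(
        unit_id=unit.unit_id,
        is_responsive=bool(cue_ok or d1_ok),
        test="paired_vs_fixation",
        p_cue=p_cue,
        p_delay1=p_d1,
        percent_rate_increase=pct,
        best_cue_location=best_location(unit, trials, "cue"),
        best_delay1_location=best_location(unit, trials, "delay1"),
    )


def best_location(unit: UnitSpikeTrain, trials: Sequence[TrialRecord],
                  epoch: str) -> int:
    """Cue location with the maximal mean epoch rate (ties -> lowest index)."""
    by_loc: Dict[int, List[float]] = {}
    for t in trials:
        by_loc.setdefault(t.cue_location, []).append(epoch_rate(unit, t, epoch))
    if not by_loc:
        raise ScreeningError("no trials")
    means = {loc: float(np.mean(v)) for loc, v in by_loc.items()}
    best = max(sorted(means), key=lambda loc: (means[loc], -loc))
    return best


def bin_spike_counts(spike_times: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Counts in half-open bins [edges[i], edges[i+1]); right edge excluded."""
    idx = np.searchsorted(np.asarray(spike_times), edges, side="left")
    return np.diff(idx)


def population_psth(
    units: Sequence[UnitSpikeTrain],
    trials_per_unit: Sequence[Sequence[TrialRecord]],
    t_start: float,
    t_stop: float,
    bin_s: float = 0.05,
    align: str = "cue_on",
    best_location_epoch: Optional[str] = "cue",
    baseline_subtract: bool = False,
    smooth_sd_s: float = 0.0,
) -> Dict[str, np.ndarray]:
    """Population PSTH aligned to an event, one row per unit.

    Times are relative to the alignment event (cue onset by default).
    When ``best_location_epoch`` is set, each unit contributes only
    trials at its own best location for that epoch. Returns bin centers,
    the unit x bin rate matrix, and the population mean +/- s.e.m.
    """
    if len(units) != len(trials_per_unit):
        raise ValueError("units and trial lists must align")
    edges_rel = np.arange(t_start, t_stop + 1e-9, bin_s)
    centers = edges_rel[:-1] + bin_s / 2
    rows = []
    for unit, trials in zip(units, trials_per_unit):
        trials = list(trials)
        if best_location_epoch is not None:
            loc = best_location(unit, trials, best_location_epoch)
            trials = [t for t in trials if t.cue_location == loc]
        if not trials:
            raise ValueError(f"unit {unit.unit_id}: no trials after filtering")
        durations = {round(t.duration, 9) for t in trials}
        counts = np.zeros(len(centers))
        for t in trials:
            t0 = getattr(t, align)
            if np.isnan(t0):
                raise ValueError(f"trial {t.trial_id} lacks event {align!r}")
            if t0 + edges_rel[-1] > t.duration + 1e-9 and len(durations) > 1:
                raise ValueError(
                    "mixed trial durations: bins extend past the shortest "
                    "trial; align piecewise instead"
                )
            st = np.sort(unit.spikes.get(t.trial_id, np.empty(0)))
            counts += bin_spike_counts(st, t0 + edges_rel)
        rate = counts / (len(trials) * bin_s)
        if baseline_subtract:
            fix = float(np.mean(epoch_rates(unit, trials, "fixation")))
            rate = rate - fix
        rows.append(rate)
    psth = np.array(rows)
    if smooth_sd_s > 0:
        from scipy.ndimage import gaussian_filter1d
        psth = gaussian_filter1d(psth, sigma=smooth_sd_s / bin_s, axis=1,
                                 mode="nearest")
    mean = psth.mean(axis=0)
    sem = psth.std(axis=0, ddof=1) / np.sqrt(len(rows)) if len(rows) > 1 \
        else np.zeros_like(mean)
    return {"time": centers, "psth": psth, "mean": mean, "sem": sem}
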