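"""Spike-count noise correlation vs. electrode distance.

Noise correlation is computed exclusively from the fixation period,
which is identical across tasks and training phases and therefore free
of stimulus-driven rate differences. For every simultaneously recorded
pair the Pearson correlation of trial-by-trial fixation spike counts is
paired with the physical distance between the pair's electrodes, and
phase effects are assessed by an analysis of covariance with distance
as the continuous covariate (plus a 2-way phase x task factorial for
same-electrode pairs, where samples are largest).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import SessionRecording, TrialRecord, UnitSpikeTrain, \
    electrode_distance
from .selection import epoch_window

__all__ = [
    "PairCorrelationRecord",
    "UndefinedCorrelationError",
    "fixation_counts",
    "pair_correlation",
    "correlation_table",
    "records_to_frame",
    "phase_comparison_ancova",
    "same_electrode_two_way",
    "distance_bin_means",
]


class UndefinedCorrelationError(ValueError):
    """A count vector is constant, so Pearson r is undefined; the pair is
    excluded rather than assigned r = 0."""


@dataclass
class PairCorrelationRecord:
    unit_a: str
    unit_b: str
    session_index: int
    phase: str
    task: str
    r: float
    n_trials: int
    distance_mm: float


def fixation_counts(unit: UnitSpikeTrain, trials: Sequence[TrialRecord]
                    ) -> np.ndarray:
    """Per-trial spike counts in the fixation window, trial order preserved."""
    counts = []
    for t in trials:
        start, end = epoch_window(t, "fixation")
        st = unit.spikes.get(t.trial_id)
        if st is None:
            counts.append(0)
        else:
            counts.append(int(np.count_nonzero((st >= start) & (st < end))))
    return np.array(counts)


def pair_correlation(counts_a: np.ndarray, counts_b: np.ndarray,
                     min_trials: int = 20) -> float:
    """Pearson correlation of two spike-count vectors."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must have equal length")
    if len(a) < min_trials:
        raise ValueError(f"need >= {min_trials} trials, got {len(a)}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("constant count vector")
    return float(stats.pearsonr(a, b).statistic)


def correlation_table(session: SessionRecording, task: str,
                      min_trials: int = 20,
                      units: Optional[Sequence[UnitSpikeTrain]] = None
                      ) -> List[PairCorrelationRecord]:
    """Noise-correlation records for all simultaneously recorded pairs."""
    trials = session.trials_for_task(task)
    if units is None:
        units = session.units
    counts = {}
    for u in units:
        c = fixation_counts(u, trials)
        if len(c) >= min_trials and np.ptp(c) > 0:
            counts[u.unit_id] = (u, c)
    records = []
    for ida, idb in combinations(sorted(counts), 2):
        ua, ca = counts[ida]
        ub, cb = counts[idb]
        records.append(
            PairCorrelationRecord(
                unit_a=ida, unit_b=idb,
                session_index=session.session_index,
                phase=session.phase, task=task,
                r=pair_correlation(ca, cb, min_trials=min_trials),
                n_trials=len(trials),
                distance_mm=electrode_distance(session.grid, ua.electrode,
                                               ub.electrode),
            )
        )
    return records


def records_to_frame(records: Sequence[PairCorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "unit_a": r.unit_a, "unit_b": r.unit_b,
            "session_index": r.session_index, "phase": r.phase,
            "task": r.task, "r": r.r, "n_trials": r.n_trials,
            "distance_mm": r.distance_mm,
        } for r in records]
    )


def phase_comparison_ancova(records: Sequence[PairCorrelationRecord] | pd.DataFrame
                            ) -> Dict[str, float]:
    """ANCOVA ``r ~ C(phase) + distance_mm``; F-test on the phase factor.

    Returns the phase F statistic and p-value, the numerator/denominator
    degrees of freedom, and the fitted (continuous) distance slope.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df["phase"].nunique() < 2:
        raise ValueError("need >= 2 phases for the phase comparison")
    if df.groupby("phase")["distance_mm"].nunique().min() < 2:
        raise ValueError("each phase needs >= 2 distinct distances "
                         "(degenerate covariate)")
    model = smf.ols("r ~ C(phase) + distance_mm", data=df).fit()
    table = anova_lm(model, typ=2)
    return {
        "phase_F": float(table.loc["C(phase)", "F"]),
        "phase_p": float(table.loc["C(phase)", "PR(>F)"]),
        "phase_df": float(table.loc["C(phase)", "df"]),
        "resid_df": float(table.loc["Residual", "df"]),
        "distance_F": float(table.loc["distance_mm", "F"]),
        "distance_p": float(table.loc["distance_mm", "PR(>F)"]),
        "distance_slope": float(model.params["distance_mm"]),
    }


def same_electrode_two_way(records: Sequence[PairCorrelationRecord] | pd.DataFrame
                           ) -> Dict[str, float]:
    """2-way factorial (phase x task) ANOVA on same-electrode pairs."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df[df["distance_mm"] == 0.0]
    if df.empty:
        raise ValueError("no same-electrode pairs")
    for factor in ("phase", "task"):
        if df[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has a single level")
    model = smf.ols("r ~ C(phase) + C(task)", data=df).fit()
    table = anova_lm(model, typ=2)
    return {
        "phase_F": float(table.loc["C(phase)", "F"]),
        "phase_p": float(table.loc["C(phase)", "PR(>F)"]),
        "task_F": float(table.loc["C(task)", "F"]),
        "task_p": float(table.loc["C(task)", "PR(>F)"]),
        "resid_df": float(table.loc["Residual", "df"]),
    }


def distance_bin_means(records: Sequence[PairCorrelationRecord] | pd.DataFrame,
                       edges: Sequence[float] = (0.0, 0.375, 1.05, 1.6, np.inf)
                       ) -> pd.DataFrame:
    """Mean r per distance bin (display binning; statistics stay continuous).

    Default bins separate same-electrode (0), adjacent (0.75), the
    1.06-1.5 mm diagonal/next-nearest group, and everything farther.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    edges = np.asarray(edges, dtype=float)
    idx = np.searchsorted(edges, df["distance_mm"].to_numpy(), side="right") - 1
    out = (
        df.assign(distance_bin=idx)
        .groupby("distance_bin")
        .agg(mean_r=("r", "mean"), sem_r=("r", "sem"), n=("r", "size"),
             mean_distance_mm=("distance_mm", "mean"))
        .reset_index()
    )
    return out
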