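"""Sliding-window three-way ANOVA and the selective-fraction binomial test.

For every unit and every sliding time bin (200 ms windows, 50 ms steps)
a linear model with the three task factors — first-stimulus (cue)
location, second-stimulus (sample) location, and decision type
(match/nonmatch) — is fit to the binned firing rates, and each factor's
main effect is tested by a drop-one-factor F test (Type II: each factor
adjusted for the others; interactions are not included because the
match label is a deterministic function of the two locations, making a
fully crossed model aliased). The fraction of units selective per bin
is then compared against the 5% chance level with an exact two-sided
binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .dataset import TrialRecord, UnitSpikeTrain
from .selection import bin_spike_counts

__all__ = [
    "FACTORS",
    "SlidingAnovaResult",
    "sliding_three_way_anova",
    "three_way_anova_bins",
    "selective_fraction_test",
]

FACTORS = ("cue_location", "sample_location", "decision")


@dataclass
class SlidingAnovaResult:
    bin_centers: np.ndarray
    p_values: np.ndarray  # (n_units, n_bins, n_factors)
    unit_ids: List[str]
    alpha: float = 0.05

    def selective_fraction(self) -> np.ndarray:
        """(n_bins, n_factors) fraction of units with p < alpha."""
        flags = self.p_values < self.alpha
        return np.nanmean(flags, axis=0)


def _dummy(codes: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (reference level dropped)."""
    levels = np.unique(codes)
    return (codes[:, None] == levels[None, 1:]).astype(float)


def _factor_designs(trials: Sequence[TrialRecord]
                    ) -> Tuple[Dict[str, np.ndarray], np.ndarray]:
    labels = {
        "cue_location": np.array([t.cue_location for t in trials]),
        "sample_location": np.array([t.sample_location for t in trials]),
        "decision": np.array([int(t.is_match) for t in trials]),
    }
    intercept = np.ones((len(labels["decision"]), 1))
    return labels, intercept


def _rss_all_bins(design: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, int]:
    """Residual sum of squares of OLS for every column of y, plus rank.

    Uses an SVD with rank truncation so that partially aliased designs
    (rank-deficient dummy blocks) project onto the true column space.
    """
    u, s, _ = np.linalg.svd(design, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0
    proj = u[:, :rank].T @ y
    rss = np.sum(y ** 2, axis=0) - np.sum(proj ** 2, axis=0)
    return np.maximum(rss, 0.0), rank


def three_way_anova_bins(trials: Sequence[TrialRecord],
                         y: np.ndarray) -> np.ndarray:
    """Main-effect p-values for all bins of one unit at once.

    ``y`` is (n_trials, n_bins) binned rates. Returns (n_bins, 3)
    p-values ordered as :data:`FACTORS`. A factor with a single level
    (or aliased by the others) yields NaN for that factor.
    """
    labels, intercept = _factor_designs(trials)
    blocks = {f: _dummy(labels[f]) for f in FACTORS}
    full = np.hstack([intercept] + [blocks[f] for f in FACTORS])
    n = full.shape[0]
    rss_full, rank_full = _rss_all_bins(full, y)
    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    out = np.full((y.shape[1], len(FACTORS)), np.nan)
    for j, f in enumerate(FACTORS):
        if blocks[f].shape[1] == 0:
            continue  # single level: factor dropped
        reduced = np.hstack([intercept]
                            + [blocks[g] for g in FACTORS if g != f])
        rss_red, rank_red = _rss_all_bins(reduced, y)
        df_f = rank_full - rank_red
        if df_f <= 0:
            continue  # aliased by the remaining factors
        mse = rss_full / df_resid
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ((rss_red - rss_full) / df_f) / mse
        p = np.where(mse > 0, stats.f.sf(F, df_f, df_resid), 1.0)
        out[:, j] = p
    return out


def sliding_three_way_anova(
    units: Sequence[UnitSpikeTrain],
    trials_per_unit: Sequence[Sequence[TrialRecord]],
    bin_s: float = 0.2,
    step_s: float = 0.05,
    t_start: float = -1.0,
    t_stop: float = 2.25,
    alpha: float = 0.05,
) -> SlidingAnovaResult:
    """Sliding three-way ANOVA over cue-aligned bins for many units.

    Windows are [t, t + bin_s) advanced by ``step_s``, with t relative
    to cue onset. Trials must carry all three factor labels; a unit's
    factor with a single level is dropped (NaN p-values), the unit is
    not discarded.
    """
    if len(units) != len(trials_per_unit):
        raise ValueError("units and trial lists must align")
    starts = np.arange(t_start, t_stop - bin_s + 1e-9, step_s)
    centers = starts + bin_s / 2
    all_p = np.full((len(units), len(starts), len(FACTORS)), np.nan)
    for i, (unit, trials) in enumerate(zip(units, trials_per_unit)):
        trials = list(trials)
        if len(trials) < 2:
            continue
        edges_cat = np.concatenate([starts, [starts[-1] + bin_s]])
        y = np.empty((len(trials), len(starts)))
        for j, t in enumerate(trials):
            st = np.sort(unit.spikes.get(t.trial_id, np.empty(0))) - t.cue_on
            # overlapping windows: count each window independently
            y[j] = [
                bin_spike_counts(st, np.array([s, s + bin_s]))[0] / bin_s
                for s in starts
            ]
        all_p[i] = three_way_anova_bins(trials, y)
    return SlidingAnovaResult(bin_centers=centers, p_values=all_p,
                              unit_ids=[u.unit_id for u in units],
                              alpha=alpha)


def selective_fraction_test(result: SlidingAnovaResult,
                            alpha: Optional[float] = None,
                            chance: float = 0.05) -> Dict[str, np.ndarray]:
    """Per-bin selective fraction and exact two-sided binomial p vs 5%.

    The two-sided p sums the probabilities of all outcomes no more
    likely than the observed count under Binomial(n, chance) (the
    "minlike" convention of the exact binomial test).
    """
    a = result.alpha if alpha is None else alpha
    flags = result.p_values < a  # NaN compares False -> not selective
    tested = ~np.isnan(result.p_values)
    n_bins, n_factors = result.p_values.shape[1:]
    frac = np.full((n_bins, n_factors), np.nan)
    pvals = np.full((n_bins, n_factors), np.nan)
    for b in range(n_bins):
        for f in range(n_factors):
            n = int(tested[:, b, f].sum())
            if n == 0:
                continue
            k = int(flags[:, b, f].sum())
            frac[b, f] = k / n
            pvals[b, f] = stats.binomtest(k, n, chance,
                                          alternative="two-sided").pvalue
    return {"bin_centers": result.bin_centers, "fraction": frac,
            "binomial_p": pvals, "factors": list(FACTORS)}
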