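"""Pseudo-population decoding with cross-validation and shuffle nulls.

Pseudo-populations are assembled by randomly matching trials within
condition across units that need not have been recorded simultaneously.
Decoding accuracy per time bin is estimated by stratified 10-fold
cross-validation repeated 5 times, with every feature z-scored using
training-fold statistics only (the no-leakage property calibrated by
the shuffle tests), and the whole procedure repeated over fresh random
pseudo-populations (resamples), giving repeats x resamples accuracy
samples per comparison. The classifier is a maximum-correlation-
coefficient rule: a test pattern is assigned the class whose training
centroid it correlates with best. Chance is 1/8 for location decoding
(the 8 peripheral locations; the center never appears as a nonmatch and
is excluded) and 1/2 for match/nonmatch decoding.

Significance: a bin is flagged when the mean actual accuracy falls
outside the 2.5-97.5 percentile interval of the shuffled-label
accuracies; a two-sample z-test p-value is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .dataset import PERIPHERAL_LOCATIONS, TrialRecord, UnitSpikeTrain
from .selection import bin_spike_counts

__all__ = [
    "DecodeConfig",
    "PseudoPopulation",
    "DecodingResult",
    "EligibilityError",
    "UnitTrialData",
    "unit_trial_data",
    "build_pseudopopulation",
    "correlation_classifier_accuracy",
    "decode_timecourse",
    "shuffle_null",
    "significance",
]


class EligibilityError(ValueError):
    pass


@dataclass(frozen=True)
class DecodeConfig:
    """Decoding hyperparameters (defaults follow the study's procedure)."""

    n_units: int = 200
    bin_s: float = 0.5
    step_s: float = 0.05
    folds: int = 10
    repeats: int = 5
    resamples: int = 100
    n_shuffles: int = 100
    alpha: float = 0.05
    label: str = "location8"  # "location8" | "match2"
    trials_per_condition: int = 10  # k: pseudo-trials per condition
    t_start: float = -1.0  # relative to cue onset
    t_stop: float = 2.25

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.label not in ("location8", "match2"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")

    @property
    def chance(self) -> float:
        return 1.0 / 8 if self.label == "location8" else 0.5

    def bin_edges(self) -> np.ndarray:
        starts = np.arange(self.t_start,
                           self.t_stop - self.bin_s + 1e-9, self.step_s)
        return starts

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_edges() + self.bin_s / 2


@dataclass
class UnitTrialData:
    """Binned rates of one unit grouped by condition label."""

    unit_id: str
    rates: Dict[int, np.ndarray]  # condition -> (n_trials, n_bins)


def _trial_label(trial: TrialRecord, label: str) -> Optional[int]:
    if label == "location8":
        if trial.cue_location not in PERIPHERAL_LOCATIONS:
            return None  # center excluded from location decoding
        return trial.cue_location
    return int(trial.is_match)


def unit_trial_data(unit: UnitSpikeTrain, trials: Sequence[TrialRecord],
                    cfg: DecodeConfig) -> UnitTrialData:
    """Bin one unit's spikes on the sliding-window grid, cue-aligned."""
    starts = cfg.bin_edges()
    by_cond: Dict[int, List[np.ndarray]] = {}
    for t in trials:
        lab = _trial_label(t, cfg.label)
        if lab is None:
            continue
        st = np.sort(unit.spikes.get(t.trial_id, np.empty(0))) - t.cue_on
        counts = np.array([
            bin_spike_counts(st, np.array([s, s + cfg.bin_s]))[0]
            for s in starts
        ], dtype=float)
        by_cond.setdefault(lab, []).append(counts / cfg.bin_s)
    return UnitTrialData(unit_id=unit.unit_id,
                         rates={c: np.array(v) for c, v in by_cond.items()})


@dataclass
class PseudoPopulation:
    tensor: np.ndarray  # (n_units, n_pseudo_trials, n_bins)
    labels: np.ndarray  # (n_pseudo_trials,)
    bin_centers: np.ndarray

    def __post_init__(self) -> None:
        if self.tensor.shape[1] != len(self.labels):
            raise ValueError("label vector length mismatch")


def build_pseudopopulation(units: Sequence[UnitTrialData], cfg: DecodeConfig,
                           rng: np.random.Generator) -> PseudoPopulation:
    """Assemble a pseudo-population tensor from per-unit condition data.

    Per unit and condition, k trials are drawn without replacement and
    independently permuted, which randomly matches trials across units
    into pseudo-trials. Units are sampled without replacement when
    enough are eligible, otherwise with replacement.
    """
    k = cfg.trials_per_condition
    conditions = sorted(set().union(*[set(u.rates) for u in units])) \
        if units else []
    expected = (list(PERIPHERAL_LOCATIONS) if cfg.label == "location8"
                else [0, 1])
    if conditions != expected:
        missing = sorted(set(expected) - set(conditions))
        if missing:
            raise EligibilityError(f"conditions {missing} absent from data")
    eligible = []
    for u in units:
        short = [c for c in expected
                 if c not in u.rates or len(u.rates[c]) < k]
        if not short:
            eligible.append(u)
    if not eligible:
        raise EligibilityError(
            f"no unit has >= {k} trials in every condition"
        )
    replace = len(eligible) < cfg.n_units
    idx = rng.choice(len(eligible), size=cfg.n_units, replace=replace)
    n_bins = eligible[0].rates[expected[0]].shape[1]
    tensor = np.empty((cfg.n_units, len(expected) * k, n_bins))
    labels = np.repeat(expected, k)
    for row, ui in enumerate(idx):
        u = eligible[ui]
        col = 0
        for c in expected:
            pick = rng.choice(len(u.rates[c]), size=k, replace=False)
            tensor[row, col:col + k] = u.rates[c][pick]
            col += k
    centers = cfg.bin_centers[:n_bins]
    return PseudoPopulation(tensor=tensor, labels=labels, bin_centers=centers)


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------


def _max_corr_predict(train_x: np.ndarray, train_y: np.ndarray,
                      test_x: np.ndarray) -> np.ndarray:
    """Maximum-correlation-coefficient prediction.

    Class centroids are computed on the training patterns; each test
    pattern is assigned the class whose centroid has the highest
    Pearson correlation with it.
    """
    classes = np.unique(train_y)
    centroids = np.array([train_x[train_y == c].mean(axis=0) for c in classes])
    c = centroids - centroids.mean(axis=1, keepdims=True)
    x = test_x - test_x.mean(axis=1, keepdims=True)
    cn = np.linalg.norm(c, axis=1)
    xn = np.linalg.norm(x, axis=1)
    cn[cn == 0] = 1.0
    xn[xn == 0] = 1.0
    corr = (x @ c.T) / np.outer(xn, cn)
    return classes[np.argmax(corr, axis=1)]


def correlation_classifier_accuracy(
    features: np.ndarray, labels: np.ndarray, folds: int,
    rng: np.random.Generator, leak_normalization: bool = False,
) -> float:
    """Accuracy of the max-correlation classifier under stratified CV.

    Features are z-scored with statistics from the training folds only;
    features with zero training variance are dropped for that fold.
    ``leak_normalization=True`` deliberately z-scores with full-data
    statistics and exists solely as a negative control for leakage
    tests; it must never be used for reported results.
    """
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(rng.integers(2 ** 31)))
    correct = 0
    if leak_normalization:
        mu_all = features.mean(axis=0)
        sd_all = features.std(axis=0, ddof=0)
    for train_idx, test_idx in skf.split(features, labels):
        if leak_normalization:
            sd = np.where(sd_all == 0, 1.0, sd_all)
            ztr = (features[train_idx] - mu_all) / sd
            zte = (features[test_idx] - mu_all) / sd
            keep = sd_all > 0
        else:
            mu = features[train_idx].mean(axis=0)
            sd = features[train_idx].std(axis=0, ddof=0)
            keep = sd > 0
            sd_safe = np.where(keep, sd, 1.0)
            ztr = (features[train_idx] - mu) / sd_safe
            zte = (features[test_idx] - mu) / sd_safe
        ztr = ztr[:, keep]
        zte = zte[:, keep]
        if ztr.shape[1] < 2:
            # all features degenerate in this fold: predict the majority
            vals, counts = np.unique(labels[train_idx], return_counts=True)
            pred = np.full(len(test_idx), vals[np.argmax(counts)])
        else:
            pred = _max_corr_predict(ztr, labels[train_idx], zte)
        correct += int(np.sum(pred == labels[test_idx]))
    return correct / len(labels)


# ---------------------------------------------------------------------------
# decoding time course
# ---------------------------------------------------------------------------


@dataclass
class DecodingResult:
    bin_centers: np.ndarray
    accuracy: np.ndarray  # (n_bins, repeats * resamples)
    null_accuracy: Optional[np.ndarray] = None  # (n_bins, n_null_samples)
    chance: float = 0.5
    significant: Optional[np.ndarray] = None
    z_p: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if np.any(self.accuracy < 0) or np.any(self.accuracy > 1):
            raise ValueError("accuracies must lie in [0, 1]")


def _run_cv(builder: Callable[[np.random.Generator], PseudoPopulation],
            cfg: DecodeConfig, rng: np.random.Generator,
            shuffle_labels: bool) -> Tuple[np.ndarray, np.ndarray]:
    samples = None
    for r in range(cfg.resamples):
        pp = builder(rng)
        labels = pp.labels
        if shuffle_labels:
            labels = rng.permutation(labels)
        n_bins = pp.tensor.shape[2]
        if samples is None:
            samples = np.empty((n_bins, cfg.resamples * cfg.repeats))
            centers = pp.bin_centers
        for rep in range(cfg.repeats):
            for b in range(n_bins):
                feats = pp.tensor[:, :, b].T  # pseudo-trials x units
                samples[b, r * cfg.repeats + rep] = \
                    correlation_classifier_accuracy(feats, labels,
                                                    cfg.folds, rng)
    return centers, samples


def decode_timecourse(
    builder: Callable[[np.random.Generator], PseudoPopulation],
    cfg: DecodeConfig, rng: np.random.Generator,
) -> DecodingResult:
    """Per-bin decoding accuracy over fresh pseudo-population resamples.

    ``builder`` draws a new pseudo-population from an rng (typically a
    closure over :func:`build_pseudopopulation`); the result carries
    ``repeats * resamples`` accuracy samples per bin.
    """
    centers, samples = _run_cv(builder, cfg, rng, shuffle_labels=False)
    return DecodingResult(bin_centers=centers, accuracy=samples,
                          chance=cfg.chance)


def shuffle_null(
    builder: Callable[[np.random.Generator], PseudoPopulation],
    cfg: DecodeConfig, rng: np.random.Generator,
    n_shuffles: Optional[int] = None,
) -> Dict[str, np.ndarray]:
    """Shuffled-label accuracy distribution and its 95% interval.

    Labels are permuted once per resample before the identical CV
    procedure. Returns the per-bin sample matrix and the 2.5-97.5
    percentile band.
    """
    n = cfg.n_shuffles if n_shuffles is None else n_shuffles
    if n < 20:
        import warnings
        warnings.warn("n_shuffles < 20: the 95% interval is poorly resolved",
                      stacklevel=2)
    null_cfg = cfg if cfg.resamples == n else _with_resamples(cfg, n)
    centers, samples = _run_cv(builder, null_cfg, rng, shuffle_labels=True)
    lo = np.percentile(samples, 2.5, axis=1)
    hi = np.percentile(samples, 97.5, axis=1)
    return {"bin_centers": centers, "samples": samples,
            "low": lo, "high": hi}


def _with_resamples(cfg: DecodeConfig, n: int) -> DecodeConfig:
    from dataclasses import replace
    return replace(cfg, resamples=n)


def significance(result: DecodingResult,
                 null: Dict[str, np.ndarray]) -> DecodingResult:
    """Flag bins whose mean accuracy leaves the null 95% interval."""
    mean_acc = result.accuracy.mean(axis=1)
    flags = (mean_acc < null["low"]) | (mean_acc > null["high"])
    # two-sample z-test of actual vs shuffled accuracy samples
    a = result.accuracy
    b = null["samples"]
    se = np.sqrt(a.var(axis=1, ddof=1) / a.shape[1]
                 + b.var(axis=1, ddof=1) / b.shape[1])
    se[se == 0] = np.finfo(float).tiny
    z = (a.mean(axis=1) - b.mean(axis=1)) / se
    p = 2 * stats.norm.sf(np.abs(z))
    result.null_accuracy = b
    result.significant = flags
    result.z_p = p
    return result
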