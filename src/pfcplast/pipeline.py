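"""End-to-end orchestration: generate/load a dataset, run every analysis
stage per phase and task, and write a report of CSV/JSON tables.

Each report section is the numerical counterpart of one analysis
surface of the study: responsive-unit fractions per phase, population
PSTHs, daily best-location heat maps, decoding time courses with
shuffle-null bands, noise-correlation distance profiles with the phase
ANCOVA, LFP band-power phase ANOVAs, and dPCA variance tables. Results
are a pure function of (dataset bytes, config): re-running with the
same seed reproduces identical numbers.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import dataset as dsmod
from . import decode as decmod
from . import noisecorr as ncmod
from . import selection as selmod
from . import signals as sigmod
from .dataset import ExperimentDataset, PHASES, read_dataset
from .synthgen import SynthConfig, generate_experiment

logger = logging.getLogger("pfcplast.pipeline")

__all__ = ["PipelineConfig", "ConfigValidationError", "validate_config",
           "run_pipeline"]

STAGES = ("screening", "psth", "heatmaps", "decode", "noisecorr",
          "lfp", "dpca")


class ConfigValidationError(ValueError):
    def __init__(self, errors: List[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class PipelineConfig:
    """Normalized pipeline configuration."""

    seed: int
    out_dir: str
    dataset_path: Optional[str] = None  # load instead of generating
    synth: Dict = field(default_factory=dict)  # SynthConfig overrides
    stages: Dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES})
    decode_n_units: int = 40
    decode_folds: int = 10
    decode_resamples: int = 10
    decode_repeats: int = 2
    decode_trials_per_condition: int = 8
    decode_bin_s: float = 0.5
    decode_step_s: float = 0.25
    min_pair_trials: int = 20
    psth_bin_s: float = 0.05
    log_level: str = "INFO"


_KNOWN_KEYS = {
    "seed", "out_dir", "dataset_path", "synth", "stages",
    "decode_n_units", "decode_folds", "decode_resamples", "decode_repeats",
    "decode_trials_per_condition", "decode_bin_s", "decode_step_s",
    "min_pair_trials", "psth_bin_s", "log_level",
}


def validate_config(source) -> PipelineConfig:
    """Normalize a config mapping or YAML path; raise with field paths."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    errors: List[str] = []
    unknown = set(raw) - _KNOWN_KEYS
    for key in sorted(unknown):
        errors.append(f"{key}: unknown configuration key")
    if "seed" not in raw and not raw.get("dataset_path"):
        errors.append("seed: mandatory when the dataset source is synthetic")
    stages = {s: True for s in STAGES}
    for key, val in (raw.get("stages") or {}).items():
        if key not in STAGES:
            errors.append(f"stages.{key}: unknown stage")
        elif not isinstance(val, bool):
            errors.append(f"stages.{key}: must be boolean")
        else:
            stages[key] = val
    for key in ("decode_n_units", "decode_resamples", "decode_repeats",
                "decode_trials_per_condition", "min_pair_trials"):
        if key in raw and (not isinstance(raw[key], int) or raw[key] < 1):
            errors.append(f"{key}: must be a positive integer")
    if "decode_folds" in raw and (not isinstance(raw["decode_folds"], int)
                                  or raw["decode_folds"] < 2):
        errors.append("decode_folds: cross-validation needs >= 2 folds")
    if raw.get("synth") is not None and not isinstance(raw["synth"], dict):
        errors.append("synth: must be a mapping of generator overrides")
    if errors:
        raise ConfigValidationError(errors)
    kwargs = {k: raw[k] for k in raw if k in _KNOWN_KEYS and k != "stages"}
    kwargs.setdefault("seed", 0)
    kwargs.setdefault("out_dir", "pfc_report")
    return PipelineConfig(stages=stages, **kwargs)


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------


def _screen_session(session, task: str, alpha: float = 0.05) -> pd.DataFrame:
    trials = session.trials_for_task(task, correct_only=True)
    if not trials:
        return pd.DataFrame()
    n_locations = len({t.cue_location for t in trials})
    rows = []
    for unit in session.units:
        try:
            if n_locations >= 2:
                res = selmod.screen_responsive_multi_location(unit, trials,
                                                              alpha=alpha)
            else:
                res = selmod.screen_responsive_single_location(unit, trials,
                                                               alpha=alpha)
        except selmod.ScreeningError:
            continue
        rows.append({
            "session_index": session.session_index, "phase": session.phase,
            "task": task, "unit_id": unit.unit_id, "kind": unit.kind,
            "is_responsive": res.is_responsive, "test": res.test,
            "p_cue": res.p_cue, "p_delay1": res.p_delay1,
            "percent_rate_increase": res.percent_rate_increase,
            "best_cue_location": res.best_cue_location,
            "best_delay1_location": res.best_delay1_location,
        })
    return pd.DataFrame(rows)


def _stage_screening(ds: ExperimentDataset, out: Path) -> pd.DataFrame:
    frames = []
    for session in ds.sessions:
        for task in ("passive", "active"):
            df = _screen_session(session, task)
            if not df.empty:
                frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(out / "responsiveness.csv", index=False)
    summary = (
        table.groupby(["phase", "task"])
        .agg(n_units=("unit_id", "size"),
             responsive_fraction=("is_responsive", "mean"))
        .reset_index()
    )
    summary.to_csv(out / "responsive_fractions.csv", index=False)
    return table


def _common_window(trials) -> Tuple[float, float]:
    pre = min(t.cue_on for t in trials)
    post = min(t.end - t.cue_on for t in trials)
    return (-pre, post)


def _stage_psth(ds: ExperimentDataset, screening: pd.DataFrame, out: Path,
                bin_s: float) -> None:
    rows = []
    for phase in ds.phases_present:
        for task in ("passive", "active"):
            units, trial_lists = [], []
            for session in ds.sessions_in_phase(phase):
                trials = session.trials_for_task(task, correct_only=True)
                if not trials:
                    continue
                resp = screening[
                    (screening.session_index == session.session_index)
                    & (screening.task == task) & screening.is_responsive
                ].unit_id
                resp = set(resp)
                for unit in session.units:
                    if unit.unit_id in resp:
                        units.append(unit)
                        trial_lists.append(trials)
            if not units:
                continue
            t0, t1 = _common_window([t for ts in trial_lists for t in ts])
            res = selmod.population_psth(
                units, trial_lists, t0, t1, bin_s=bin_s,
                baseline_subtract=True,
            )
            for t, m, s in zip(res["time"], res["mean"], res["sem"]):
                rows.append({"phase": phase, "task": task, "time_s": t,
                             "mean_rate": m, "sem": s,
                             "n_units": len(units)})
    pd.DataFrame(rows).to_csv(out / "population_psth.csv", index=False)


def _stage_heatmaps(ds: ExperimentDataset, screening: pd.DataFrame,
                    out: Path) -> None:
    rows = []
    for session in ds.sessions:
        for task in ("passive", "active"):
            trials = session.trials_for_task(task, correct_only=True)
            if not trials:
                continue
            resp = set(screening[
                (screening.session_index == session.session_index)
                & (screening.task == task) & screening.is_responsive
            ].unit_id)
            units = [u for u in session.units if u.unit_id in resp]
            if not units:
                continue
            for loc in sorted({t.cue_location for t in trials}):
                at_loc = [t for t in trials if t.cue_location == loc]
                rates = [np.mean(selmod.epoch_rates(u, at_loc, "cue"))
                         for u in units]
                rows.append({
                    "session_index": session.session_index,
                    "phase": session.phase, "task": task, "location": loc,
                    "mean_cue_rate": float(np.mean(rates)),
                    "n_units": len(units),
                })
    pd.DataFrame(rows).to_csv(out / "daily_location_rates.csv", index=False)


def _stage_decode(ds: ExperimentDataset, cfg: PipelineConfig, out: Path,
                  rng: np.random.Generator) -> None:
    rows = []
    for phase in ds.phases_present:
        for task in ("passive", "active"):
            units, trial_lists = [], []
            for session in ds.sessions_in_phase(phase):
                trials = session.trials_for_task(task, correct_only=True)
                if not trials:
                    continue
                for unit in session.units:
                    if unit.kind == "MUA":
                        units.append(unit)
                        trial_lists.append(trials)
            if not units:
                continue
            all_trials = [t for ts in trial_lists for t in ts]
            t0, t1 = _common_window(all_trials)
            for label in ("location8", "match2"):
                dcfg = decmod.DecodeConfig(
                    folds=min(cfg.decode_folds, cfg.decode_trials_per_condition),
                    n_units=cfg.decode_n_units, bin_s=cfg.decode_bin_s,
                    step_s=cfg.decode_step_s,
                    repeats=cfg.decode_repeats,
                    resamples=cfg.decode_resamples,
                    n_shuffles=cfg.decode_resamples,
                    label=label,
                    trials_per_condition=cfg.decode_trials_per_condition,
                    t_start=t0, t_stop=t1,
                )
                data = [decmod.unit_trial_data(u, ts, dcfg)
                        for u, ts in zip(units, trial_lists)]
                try:
                    builder = lambda r, d=data, c=dcfg: \
                        decmod.build_pseudopopulation(d, c, r)
                    builder(np.random.default_rng(0))
                except decmod.EligibilityError as exc:
                    logger.warning("decode %s %s %s skipped: %s",
                                   phase, task, label, exc)
                    continue
                result = decmod.decode_timecourse(builder, dcfg, rng)
                null = decmod.shuffle_null(builder, dcfg, rng)
                result = decmod.significance(result, null)
                for i, t in enumerate(result.bin_centers):
                    rows.append({
                        "phase": phase, "task": task, "label": label,
                        "bin_center_s": t,
                        "mean_accuracy": float(result.accuracy[i].mean()),
                        "null_low": float(null["low"][i]),
                        "null_high": float(null["high"][i]),
                        "significant": bool(result.significant[i]),
                        "z_p": float(result.z_p[i]),
                        "chance": dcfg.chance,
                    })
    pd.DataFrame(rows).to_csv(out / "decoding_timecourses.csv", index=False)


def _stage_noisecorr(ds: ExperimentDataset, cfg: PipelineConfig,
                     out: Path) -> None:
    records = []
    for session in ds.sessions:
        sua = [u for u in session.units if u.kind == "SUA"]
        for task in ("passive", "active"):
            if not session.trials_for_task(task):
                continue
            records.extend(
                ncmod.correlation_table(session, task, units=sua,
                                        min_trials=cfg.min_pair_trials)
            )
    df = ncmod.records_to_frame(records)
    df.to_csv(out / "noise_correlation_pairs.csv", index=False)
    summaries = {}
    for task in ("passive", "active"):
        sub = df[df.task == task]
        if sub.empty or sub.phase.nunique() < 2:
            continue
        try:
            summaries[task] = ncmod.phase_comparison_ancova(sub)
        except ValueError as exc:
            logger.warning("ANCOVA (%s) skipped: %s", task, exc)
        ncmod.distance_bin_means(sub).assign(task=task).to_csv(
            out / f"noise_correlation_distance_{task}.csv", index=False)
    try:
        summaries["same_electrode_two_way"] = ncmod.same_electrode_two_way(df)
    except ValueError as exc:
        logger.warning("same-electrode 2-way skipped: %s", exc)
    with open(out / "noise_correlation_ancova.json", "w") as fh:
        json.dump(summaries, fh, indent=1)


def _stage_lfp(ds: ExperimentDataset, out: Path) -> None:
    rows = []
    anovas = {}
    for task in ("passive", "active"):
        per_session: Dict[int, Dict[int, List[np.ndarray]]] = {}
        phases: Dict[int, str] = {}
        t0 = None
        fs = None
        for session in ds.sessions:
            trials = session.trials_for_task(task)
            if not trials or not session.lfp:
                continue
            cue_on = trials[0].cue_on
            t0 = -cue_on
            per_session[session.session_index] = {
                tr.electrode: [tr.samples[t.trial_id] for t in trials
                               if t.trial_id in tr.samples]
                for tr in session.lfp
            }
            phases[session.session_index] = session.phase
            fs = session.lfp[0].fs
        if not per_session:
            continue
        for band in sigmod.STANDARD_BANDS:
            values = sigmod.band_power_by_session(
                per_session, fs, band, baseline=(t0, 0.0),
                epoch=(0.0, 0.5), t0=t0,
            )
            for sidx, v in values.items():
                rows.append({"session_index": sidx, "phase": phases[sidx],
                             "task": task, "band": band.name,
                             "epoch": "cue", "value": v})
            if len(set(phases.values())) >= 2:
                anovas[f"{task}_{band.name}"] = sigmod.phase_band_anova(
                    values, phases)
    pd.DataFrame(rows).to_csv(out / "band_power_sessions.csv", index=False)
    with open(out / "band_power_anova.json", "w") as fh:
        json.dump(anovas, fh, indent=1)


def _stage_dpca(ds: ExperimentDataset, screening: pd.DataFrame,
                out: Path) -> None:
    from . import dpca as dpcamod
    rows = []
    for phase in ds.phases_present:
        for task in ("passive", "active"):
            tensors = []
            eligible = []
            for session in ds.sessions_in_phase(phase):
                trials = session.trials_for_task(task, correct_only=True)
                locs = sorted({t.cue_location for t in trials}
                              & set(dsmod.PERIPHERAL_LOCATIONS))
                if len(locs) < 8:
                    continue
                resp = set(screening[
                    (screening.session_index == session.session_index)
                    & (screening.task == task) & screening.is_responsive
                ].unit_id)
                units = [u for u in session.units if u.unit_id in resp]
                if units:
                    eligible.append((trials, locs, units))
            if not eligible:
                continue
            # one time grid shared by every session of this phase x task
            t0, t1 = _common_window([t for trials, _, _ in eligible
                                     for t in trials])
            edges = np.arange(t0, t1 + 1e-9, 0.1)
            nb = len(edges) - 1
            for trials, locs, units in eligible:
                for unit in units:
                    cell = np.full((len(locs), 2, nb), np.nan)
                    for si, loc in enumerate(locs):
                        for di, match in enumerate((False, True)):
                            sel = [t for t in trials
                                   if t.cue_location == loc
                                   and t.is_match == match]
                            if not sel:
                                continue
                            acc = np.zeros(nb)
                            for t in sel:
                                st = np.sort(unit.spikes.get(
                                    t.trial_id, np.empty(0))) - t.cue_on
                                acc += selmod.bin_spike_counts(st, edges)
                            cell[si, di] = acc / (len(sel) * 0.1)
                    if np.all(np.isfinite(cell)):
                        tensors.append(cell)
            if len(tensors) < 3:
                continue
            x = np.array(tensors)
            fit = dpcamod.fit_dpca(x, n_components=5)
            table = fit.variance_table()
            table["phase"] = phase
            table["task"] = task
            rows.append(table)
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(
            out / "dpca_variance.csv", index=False)
    else:
        pd.DataFrame(columns=["marginalization", "component",
                              "explained_variance_share", "phase", "task"]
                     ).to_csv(out / "dpca_variance.csv", index=False)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_pipeline(cfg: PipelineConfig) -> Dict[str, object]:
    """Run all enabled stages and write the report bundle to ``out_dir``."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict[str, object] = {"stages": {}, "seed": cfg.seed}
    try:
        if cfg.dataset_path:
            ds = read_dataset(cfg.dataset_path)
        else:
            synth = SynthConfig(seed=cfg.seed, **cfg.synth)
            ds = generate_experiment(synth)
        manifest["n_sessions"] = len(ds.sessions)
        manifest["phases"] = ds.phases_present

        screening = None
        timings = {}
        need_screen = any(cfg.stages.get(s) for s in
                          ("screening", "psth", "heatmaps", "dpca"))
        if need_screen:
            tic = time.perf_counter()
            screening = _stage_screening(ds, out)
            timings["screening"] = time.perf_counter() - tic
            manifest["stages"]["screening"] = cfg.stages.get("screening", True)
        for name, fn in (
            ("psth", lambda: _stage_psth(ds, screening, out, cfg.psth_bin_s)),
            ("heatmaps", lambda: _stage_heatmaps(ds, screening, out)),
            ("decode", lambda: _stage_decode(
                ds, cfg, out, np.random.default_rng(
                    np.random.SeedSequence([cfg.seed, 101])))),
            ("noisecorr", lambda: _stage_noisecorr(ds, cfg, out)),
            ("lfp", lambda: _stage_lfp(ds, out)),
            ("dpca", lambda: _stage_dpca(ds, screening, out)),
        ):
            if not cfg.stages.get(name, True):
                manifest["stages"][name] = False
                continue
            tic = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                manifest["stages"][name] = f"failed: {exc}"
                with open(out / "manifest.json", "w") as fh:
                    json.dump(manifest, fh, indent=1, default=str)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            timings[name] = time.perf_counter() - tic
            manifest["stages"][name] = True
            logger.info("stage %s done in %.1fs", name, timings[name])
        manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    return manifest
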