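"""Cohort orchestration: behavior -> imaging -> history modulation ->
discrimination -> movement, plus the cohort-level statistics.

``run_pipeline`` executes the full analysis for each subject of a cohort
(synthetic recipes or fixture directories) and aggregates the per-subject
results: learning thresholds, history-modulation onsets in trial time and
learning time, the onset-threshold Spearman correlation, history/current
AUC comparisons, a two-way repeated-measures ANOVA of stim-window activity
(history x phase), and the movement null controls.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import stats

from . import __version__, behavior, discrimination, historymod, movement, synthdata
from .imaging import PRE_WINDOW, STIM_WINDOW, SessionTensor, WindowDef, window_average
from .movement import MovementBundle

__all__ = [
    "SubjectResult",
    "CohortResult",
    "run_pipeline",
    "paired_cohort_test",
    "rm_anova_history_learning",
]

log = logging.getLogger("trialhist.pipeline")

PHASES = ("naive", "learning", "expert")

DEFAULTS = {
    "n_iter": 1000,
    "k_sd": 2.0,
    "bin_size": 100,
    "min_pairs": 20,
    "areas": ["BC", "RL"],
    "area_windows": {"BC": "stim", "RL": "pre"},
    "seed": 0,
}
_WINDOWS = {"stim": STIM_WINDOW, "pre": PRE_WINDOW}


@dataclass
class SubjectResult:
    subject_id: str
    threshold: float
    sigmoid: behavior.SigmoidFit
    phases: behavior.PhaseAssignment
    pair_counts: dict
    trialtime: dict = field(default_factory=dict)  # (phase, area) -> ModulationTrace | reason
    learning_mod: dict = field(default_factory=dict)  # area -> LearningModulation
    auc_stim: dict = field(default_factory=dict)  # mode -> stim-window mean AUC (expert)
    stim_activity: dict = field(default_factory=dict)  # (phase, pair) -> mean BC stim dF/F
    movement_tests: dict = field(default_factory=dict)  # phase -> comparison dict


@dataclass
class CohortResult:
    subjects: list
    onset_threshold: dict
    auc_comparison: dict | None
    anova: dict | None
    movement_cohort: dict
    grand_stim_delta: dict  # phase -> cohort mean of (CR-Hit - Hit-Hit) BC stim activity
    config: dict

    def subject_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            lm = s.learning_mod.get("BC")
            rows.append(
                {
                    "subject": s.subject_id,
                    "threshold": s.threshold,
                    "learning_onset": None if lm is None else lm.onset_trial,
                    "learning_onset_rel": None if lm is None else lm.onset_trial_rel,
                    "history_auc_stim": s.auc_stim.get("history"),
                    "current_auc_stim": s.auc_stim.get("current"),
                }
            )
        return pd.DataFrame(rows)


def _load_subject(spec: dict, fallback_seed: int, k: int):
    """One subject: either a synthetic recipe or a fixture directory."""
    if "fixture_dir" in spec:
        d = Path(spec["fixture_dir"])
        table = pd.read_csv(d / "trials.csv")
        with h5py.File(d / "dff.h5", "r") as f:
            tensor = SessionTensor(
                f["dff"][()],
                f["time_s"][()],
                float(f.attrs["frame_rate_hz"]),
                channel_names=tuple(str(n) for n in f.attrs["channel_names"]),
            )
        control = None
        cpath = d / "control.h5"
        if cpath.exists():
            with h5py.File(cpath, "r") as f:
                control = SessionTensor(
                    f["control"][()],
                    f["time_s"][()],
                    float(f.attrs["frame_rate_hz"]),
                    channel_names=tensor.channel_names,
                )
        bundle = None
        mpath = d / "movement.h5"
        if mpath.exists():
            with h5py.File(mpath, "r") as f:
                bundle = MovementBundle(
                    body=f["body"][()],
                    body_time_s=f["body_time_s"][()],
                    whisker_angle=f["whisker_angle"][()],
                    whisker_time_s=f["whisker_time_s"][()],
                )
        return table, tensor, control, bundle
    cfg_kwargs = dict(spec.get("synthetic", {}))
    cfg_kwargs.setdefault("seed", fallback_seed + k)
    cfg = synthdata.SynthConfig(**cfg_kwargs)
    table = synthdata.simulate_behavior(cfg)
    tensor, control, _ = synthdata.simulate_session_tensor(table, cfg)
    bundle = synthdata.simulate_movement(table, cfg)
    return table, tensor, control, bundle


def _analyze_subject(subject_id: str, table, tensor, control, bundle, cfg: dict) -> SubjectResult:
    from .imaging import correct_control_channel

    if control is not None and np.any(control.values):
        tensor = correct_control_channel(tensor, control)

    curve = behavior.bin_learning_curve(table, bin_size=cfg["bin_size"])
    fit = behavior.fit_sigmoid(curve)
    threshold = behavior.learning_threshold(fit)
    phases = behavior.assign_phases(table, threshold, min_pairs=cfg["min_pairs"])
    res = SubjectResult(
        subject_id=subject_id,
        threshold=threshold,
        sigmoid=fit,
        phases=phases,
        pair_counts=behavior.pair_counts(table).to_dict(),
    )
    seed = cfg["seed"]
    for p, (phase, sess) in enumerate(phases.as_dict().items()):
        if sess is None:
            for area in cfg["areas"]:
                res.trialtime[(phase, area)] = "phase session undefined"
            continue
        for a, area in enumerate(cfg["areas"]):
            try:
                res.trialtime[(phase, area)] = historymod.trialtime_modulation(
                    tensor,
                    table,
                    area=area,
                    session_id=sess,
                    n_iter=cfg["n_iter"],
                    seed=seed * 1000 + 10 * p + a,
                    k_sd=cfg["k_sd"],
                    min_trials=cfg["min_pairs"],
                )
            except ValueError as e:
                log.warning("subject %s %s/%s trial-time modulation skipped: %s",
                            subject_id, phase, area, e)
                res.trialtime[(phase, area)] = str(e)
    for a, area in enumerate(cfg["areas"]):
        res.learning_mod[area] = historymod.learning_modulation(
            tensor,
            table,
            threshold,
            area=area,
            window=_WINDOWS[cfg["area_windows"].get(area, "stim")],
            bin_size=cfg["bin_size"],
            n_iter=cfg["n_iter"],
            seed=seed * 1000 + 100 + a,
            k_sd=cfg["k_sd"],
        )
    # expert-phase discrimination, stim-window averaged over frame-wise AUC
    stim_mask = STIM_WINDOW.frame_mask(tensor.time_s)
    for mode in ("history", "current"):
        try:
            trace = discrimination.auc_trace(
                tensor, table, mode=mode, area="BC", session_id=phases.expert
            )
            res.auc_stim[mode] = float(trace.values[stim_mask].mean())
        except ValueError as e:
            log.warning("subject %s %s AUC skipped: %s", subject_id, mode, e)
            res.auc_stim[mode] = None
    # BC stim-window activity per phase and history pair (for the cohort ANOVA)
    wavg = window_average(tensor, STIM_WINDOW)[:, tensor.channel_names.index("BC")]
    pos_of = pd.Series(np.arange(len(table)), index=table["trial_index"].to_numpy())
    pairs_df = behavior.pair_history(table)
    sess_of = table.set_index("trial_index")["session_id"]
    for phase, sess in phases.as_dict().items():
        if sess is None:
            continue
        in_phase = pairs_df[sess_of.loc[pairs_df["curr_trial_index"]].to_numpy() == sess]
        for pair in historymod.MAIN_PAIRS:
            rows = pos_of.loc[
                in_phase.loc[in_phase["pair"] == pair, "curr_trial_index"]
            ].to_numpy()
            if len(rows):
                res.stim_activity[(phase, pair)] = float(wavg[rows].mean())
    if bundle is not None:
        for phase, sess in phases.as_dict().items():
            if sess is None:
                continue
            try:
                res.movement_tests[phase] = movement.movement_history_comparison(
                    bundle, table, session_id=sess
                )
            except ValueError as e:
                res.movement_tests[phase] = {"missing": True, "reason": str(e)}
    return res


def run_pipeline(config: dict, out_dir=None) -> CohortResult:
    """Run the full history analysis on a cohort.

    ``config["subjects"]`` is a list of subject specs, each either
    ``{"synthetic": {SynthConfig overrides}}`` or ``{"fixture_dir": path}``.
    Remaining keys override the defaults (n_iter, k_sd, bin_size, min_pairs,
    areas, seed).  When ``out_dir`` is given, per-subject and cohort CSV/JSON
    outputs plus a run log are written there.
    """
    cfg = {**DEFAULTS, **{k: v for k, v in config.items() if k != "subjects"}}
    subjects_spec = config.get("subjects")
    if not subjects_spec:
        raise ValueError("config must list at least one subject")
    results = []
    for k, spec in enumerate(subjects_spec):
        sid = spec.get("id", f"subject{k + 1:02d}")
        log.info("analyzing %s", sid)
        try:
            table, tensor, control, bundle = _load_subject(spec, cfg["seed"], k)
            results.append(_analyze_subject(sid, table, tensor, control, bundle, cfg))
        except Exception as e:
            raise RuntimeError(f"pipeline failed for subject {sid!r}: {e}") from e

    onsets = [r.learning_mod["BC"].onset_trial for r in results]
    thresholds = [r.threshold for r in results]
    try:
        rho, p, n_excl = historymod.onset_threshold_correlation(onsets, thresholds)
        onset_thr = {"rho": rho, "p": p, "n_excluded": n_excl, "insufficient": False}
    except ValueError as e:
        onset_thr = {"rho": None, "p": None, "insufficient": True, "reason": str(e)}

    auc_cmp = None
    h = [r.auc_stim.get("history") for r in results]
    c = [r.auc_stim.get("current") for r in results]
    if all(v is not None for v in h + c) and len(h) >= 3:
        auc_cmp = discrimination.compare_auc(h, c)

    anova = None
    mat = _anova_matrix(results)
    if mat is not None:
        try:
            anova = rm_anova_history_learning(mat)
        except ValueError as e:
            log.warning("RM-ANOVA skipped: %s", e)

    move_cohort = {}
    for modality in ("body", "whisker"):
        for phase in PHASES:
            a = [
                r.movement_tests.get(phase, {}).get(modality, {}).get("mean_a")
                for r in results
            ]
            b = [
                r.movement_tests.get(phase, {}).get(modality, {}).get("mean_b")
                for r in results
            ]
            if all(v is not None for v in a + b) and len(a) >= 3:
                move_cohort[(modality, phase)] = paired_cohort_test(a, b)

    grand = {}
    for phase in PHASES:
        deltas = [
            r.stim_activity[(phase, "CR-Hit")] - r.stim_activity[(phase, "Hit-Hit")]
            for r in results
            if (phase, "CR-Hit") in r.stim_activity and (phase, "Hit-Hit") in r.stim_activity
        ]
        if deltas:
            grand[phase] = float(np.mean(deltas))

    cohort = CohortResult(
        subjects=results,
        onset_threshold=onset_thr,
        auc_comparison=auc_cmp,
        anova=anova,
        movement_cohort=move_cohort,
        grand_stim_delta=grand,
        config=cfg,
    )
    if out_dir is not None:
        _write_outputs(cohort, Path(out_dir))
    return cohort


def _anova_matrix(results) -> np.ndarray | None:
    """subjects x history(2) x phase(3) matrix of BC stim activity, or None."""
    mat = np.full((len(results), 2, len(PHASES)), np.nan)
    for i, r in enumerate(results):
        for j, pair in enumerate(historymod.MAIN_PAIRS):
            for k, phase in enumerate(PHASES):
                if (phase, pair) in r.stim_activity:
                    mat[i, j, k] = r.stim_activity[(phase, pair)]
    if np.isnan(mat).any() or len(results) < 3:
        return None
    return mat


def median_summary(values) -> dict | None:
    """Median with both SEM and MAD, labelled — the dispersion convention for
    medians is ambiguous, so both are reported."""
    v = np.asarray([x for x in values if x is not None], dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return None
    return {
        "median": float(np.median(v)),
        "sem": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0,
        "mad": float(np.median(np.abs(v - np.median(v)))),
        "n": int(v.size),
    }


def paired_cohort_test(values_a, values_b) -> dict:
    """Wilcoxon signed-rank between paired per-subject vectors (Pratt zeros)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 3:
        raise ValueError(f"need >= 3 paired values, got {a.size}")
    d = a - b
    if np.all(d == 0):
        return {"statistic": 0.0, "p": 1.0, "all_zero": True, "n": int(a.size)}
    res = stats.wilcoxon(a, b, zero_method="pratt")
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "all_zero": False,
        "n": int(a.size),
    }


def rm_anova_history_learning(values: np.ndarray) -> dict:
    """Two-way repeated-measures ANOVA: history (2) x phase (3), subject as
    the repeated factor, with Tukey-adjusted history contrasts per phase.

    ``values`` is subjects x 2 (CR-Hit, Hit-Hit) x 3 (naive, learning,
    expert).  Sphericity is not corrected; conventional within-subject
    degrees of freedom are reported.
    """
    from statsmodels.stats.anova import AnovaRM
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    if values.ndim != 3 or values.shape[1] != 2 or values.shape[2] != 3:
        raise ValueError("expect subjects x 2 histories x 3 phases")
    if np.isnan(values).any():
        raise ValueError("missing cells: the repeated-measures design must be complete")
    if np.allclose(values, values.flat[0]):
        raise ValueError("zero variance: all cells equal")
    n_subj = values.shape[0]
    rows = []
    for i in range(n_subj):
        for j, hist in enumerate(historymod.MAIN_PAIRS):
            for k, phase in enumerate(PHASES):
                rows.append(
                    {"subject": i, "history": hist, "phase": phase, "value": values[i, j, k]}
                )
    long = pd.DataFrame(rows)
    table = AnovaRM(long, "value", "subject", within=["history", "phase"]).fit().anova_table
    tukey = {}
    for phase in PHASES:
        sub = long[long["phase"] == phase]
        res = pairwise_tukeyhsd(sub["value"], sub["history"])
        tukey[phase] = {
            "p": float(res.pvalues[0]),
            "reject": bool(res.reject[0]),
            "meandiff": float(res.meandiffs[0]),
        }
    return {
        "anova": table,
        "tukey": tukey,
        "sphericity_corrected": False,
        "p_history": float(table.loc["history", "Pr > F"]),
        "p_phase": float(table.loc["phase", "Pr > F"]),
        "p_interaction": float(table.loc["history:phase", "Pr > F"]),
    }


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict()
    return x


def _write_outputs(cohort: CohortResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cohort.subject_frame().to_csv(out / "subjects.csv", index=False)
    for r in cohort.subjects:
        sdir = out / r.subject_id
        sdir.mkdir(exist_ok=True)
        for (phase, area), tr in r.trialtime.items():
            if isinstance(tr, historymod.ModulationTrace):
                tr.to_frame().to_csv(sdir / f"modulation_{phase}_{area}.csv", index=False)
        for area, lm in r.learning_mod.items():
            lm.to_frame().to_csv(sdir / f"learning_modulation_{area}.csv", index=False)
        summary = {
            "threshold": r.threshold,
            "sigmoid": {"a": r.sigmoid.a, "b": r.sigmoid.b, "c": r.sigmoid.c},
            "phases": {k: str(v) for k, v in r.phases.as_dict().items()},
            "pair_counts": r.pair_counts,
            "onsets_trialtime_s": {
                f"{ph}/{ar}": (tr.onset_time_s if isinstance(tr, historymod.ModulationTrace) else None)
                for (ph, ar), tr in r.trialtime.items()
            },
            "learning_onsets": {ar: lm.onset_trial for ar, lm in r.learning_mod.items()},
            "auc_stim": r.auc_stim,
            "movement": r.movement_tests,
        }
        with open(sdir / "summary.json", "w") as f:
            json.dump(_jsonable(summary), f, indent=1)
    onset_summaries = {}
    for area in cohort.config["areas"]:
        onset_summaries[f"learning_onset_{area}"] = median_summary(
            [r.learning_mod[area].onset_trial for r in cohort.subjects if area in r.learning_mod]
        )
        for phase in PHASES:
            vals = [
                tr.onset_time_s
                for r in cohort.subjects
                for key, tr in r.trialtime.items()
                if key == (phase, area) and isinstance(tr, historymod.ModulationTrace)
            ]
            onset_summaries[f"trialtime_onset_{phase}_{area}_s"] = median_summary(vals)
    cohort_summary = {
        "version": __version__,
        "config": {k: v for k, v in cohort.config.items()},
        "onset_threshold": cohort.onset_threshold,
        "onset_summaries": onset_summaries,
        "auc_comparison": cohort.auc_comparison,
        "grand_stim_delta": cohort.grand_stim_delta,
        "movement_cohort": cohort.movement_cohort,
        "anova": None
        if cohort.anova is None
        else {k: v for k, v in cohort.anova.items() if k != "anova"},
    }
    with open(out / "cohort.json", "w") as f:
        json.dump(_jsonable(cohort_summary), f, indent=1)
    with open(out / "run.log", "w") as f:
        f.write(f"trialhist {__version__}\nseed={cohort.config['seed']}\n")
        for r in cohort.subjects:
            f.write(
                f"{r.subject_id}: threshold={r.threshold:.1f} "
                f"pairs={ {k: v for k, v in sorted(r.pair_counts.items())} }\n"
            )
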