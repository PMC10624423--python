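"""History modulation and its onset in trial time and learning time.

The history modulation index is the difference between the mean responses of
CR-Hit trials (a Hit preceded by a correct rejection) and Hit-Hit trials.
Its significance band is the mean +/- 2 SD of a trial-shuffle null obtained
by randomly repartitioning the pooled trials into groups of the original
sizes (default 1000 iterations).  The onset is the first frame (or 100-trial
learning bin) whose modulation exceeds the upper band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior
from .imaging import STIM_WINDOW, SessionTensor, WindowDef, window_average

__all__ = [
    "ModulationTrace",
    "LearningModulation",
    "modulation_trace",
    "shuffle_null",
    "detect_onset",
    "trialtime_modulation",
    "learning_modulation",
    "onset_threshold_correlation",
]

#: history-pair labels of the main contrast, in (positive, reference) order
MAIN_PAIRS = ("CR-Hit", "Hit-Hit")

#: minimum trials per pair type for a phase to enter the modulation analysis
MIN_TRIALS_PER_PAIR = 20

#: persistence rule applied by the composed trial-time / learning-time scans
DEFAULT_MIN_CONSECUTIVE = 2


def modulation_trace(group_a: np.ndarray, group_b: np.ndarray) -> np.ndarray:
    """Per-frame mean(group A) - mean(group B); groups are trials x frames."""
    group_a = np.atleast_2d(np.asarray(group_a, dtype=float))
    group_b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if group_a.shape[0] == 0 or group_b.shape[0] == 0:
        raise ValueError("both trial groups must be nonempty")
    if group_a.shape[1] != group_b.shape[1]:
        raise ValueError("groups differ in frame axis length")
    return group_a.mean(axis=0) - group_b.mean(axis=0)


def shuffle_null(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
    batch: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-shuffle null for the modulation index.

    Pools the two groups, repartitions them ``n_iter`` times into random
    groups of the original sizes, and recomputes the per-frame mean
    difference each time.  Returns (null_mean, null_sd) per frame.
    Deterministic given ``seed``; permutations are drawn vectorised in
    batches to keep memory bounded.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    group_a = np.atleast_2d(np.asarray(group_a, dtype=float))
    group_b = np.atleast_2d(np.asarray(group_b, dtype=float))
    n_a, n_b = group_a.shape[0], group_b.shape[0]
    if n_a < 1 or n_b < 1:
        raise ValueError("both groups need at least one trial")
    pooled = np.concatenate([group_a, group_b], axis=0)
    n_tot = n_a + n_b
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = pooled.sum(axis=0)
    # running moments of the shuffle distribution of delta
    s1 = np.zeros(pooled.shape[1])
    s2 = np.zeros(pooled.shape[1])
    done = 0
    while done < n_iter:
        m = min(batch, n_iter - done)
        # random repartition: argsort of uniforms = uniform random permutation
        perm = np.argsort(rng.random((m, n_tot)), axis=1)
        sum_a = pooled[perm[:, :n_a]].sum(axis=1)  # m x frames
        # mean difference via pooled total: mean_b = (total - sum_a)/n_b
        delta = sum_a / n_a - (total - sum_a) / n_b
        s1 += delta.sum(axis=0)
        s2 += (delta**2).sum(axis=0)
        done += m
    null_mean = s1 / n_iter
    null_sd = np.sqrt(np.maximum(s2 / n_iter - null_mean**2, 0.0))
    return null_mean, null_sd


def detect_onset(
    delta: np.ndarray,
    null_mean: np.ndarray,
    null_sd: np.ndarray,
    k_sd: float = 2.0,
    min_consecutive: int = 1,
    two_sided: bool = False,
) -> int | None:
    """First index where the modulation exceeds the shuffle band.

    The band is null_mean + k_sd * null_sd (upper side only by default: the
    hypothesis is an activity *increase* on CR-preceded trials).  With
    ``min_consecutive`` > 1, the crossing must persist that many consecutive
    samples.  Returns None when the band is never exceeded.
    """
    delta = np.asarray(delta, dtype=float)
    null_mean = np.asarray(null_mean, dtype=float)
    null_sd = np.asarray(null_sd, dtype=float)
    if not (delta.shape == null_mean.shape == null_sd.shape):
        raise ValueError("delta and null arrays must have the same shape")
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    if min_consecutive < 1:
        raise ValueError("min_consecutive must be >= 1")
    degenerate = (null_sd == 0) & (delta != 0)
    if degenerate.any():
        raise ValueError(
            f"null SD is zero at {int(degenerate.sum())} positions with nonzero modulation"
        )
    above = delta > null_mean + k_sd * null_sd
    if two_sided:
        above |= delta < null_mean - k_sd * null_sd
    return _first_run(above, min_consecutive)


def _first_run(above: np.ndarray, m: int) -> int | None:
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= m:
            return i - m + 1
    return None


@dataclass
class ModulationTrace:
    """History modulation along trial time with its shuffle band and onset."""

    time_s: np.ndarray
    delta: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    n_iter: int
    n_a: int
    n_b: int
    k_sd: float = 2.0
    onset_time_s: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "delta": self.delta,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
            }
        )


@dataclass
class LearningModulation:
    """Stim-window history modulation per 100-trial bin across learning."""

    bin_centers: np.ndarray  # absolute trial numbers
    bin_centers_rel: np.ndarray  # relative to the threshold bin's center
    delta: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    missing: np.ndarray
    n_iter: int
    bin_size: int
    threshold: float
    k_sd: float = 2.0
    onset_trial: float | None = None  # absolute trial number of onset bin center
    onset_trial_rel: float | None = None  # same, relative to threshold bin

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "bin_center_rel": self.bin_centers_rel,
                "delta": self.delta,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "missing": self.missing,
            }
        )


def _pair_groups(
    table: pd.DataFrame,
    pairs_wanted: tuple[str, str],
    trial_subset: pd.Index | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Row positions (into the tensor trial axis) of the two pair groups."""
    pairs = behavior.pair_history(table)
    if trial_subset is not None:
        pairs = pairs[pairs["curr_trial_index"].isin(trial_subset)]
    pos_of = pd.Series(np.arange(len(table)), index=table["trial_index"].to_numpy())
    out = []
    for label in pairs_wanted:
        idx = pairs.loc[pairs["pair"] == label, "curr_trial_index"]
        out.append(pos_of.loc[idx].to_numpy())
    return out[0], out[1]


def trialtime_modulation(
    tensor: SessionTensor,
    table: pd.DataFrame,
    area: str,
    session_id=None,
    pairs: tuple[str, str] = MAIN_PAIRS,
    n_iter: int = 1000,
    seed: int = 0,
    k_sd: float = 2.0,
    min_consecutive: int = DEFAULT_MIN_CONSECUTIVE,
    min_trials: int = MIN_TRIALS_PER_PAIR,
) -> ModulationTrace:
    """History modulation of one area along trial time within one phase.

    Restricts to one session (phase) when ``session_id`` is given, forms the
    CR-Hit and Hit-Hit groups, and composes modulation_trace, shuffle_null
    and detect_onset.  The onset is reported in seconds relative to texture
    stop, or None when the band is never crossed.
    """
    if len(table) != tensor.n_trials:
        raise ValueError(
            f"table has {len(table)} trials but tensor has {tensor.n_trials}"
        )
    subset = None
    if session_id is not None:
        subset = pd.Index(table.loc[table["session_id"] == session_id, "trial_index"])
    ia, ib = _pair_groups(table, pairs, subset)
    if len(ia) < min_trials or len(ib) < min_trials:
        raise ValueError(
            f"too few trials for {pairs} (got {len(ia)}/{len(ib)}, need {min_trials} each)"
        )
    traces = tensor.channel(area)
    ga, gb = traces[ia], traces[ib]
    delta = modulation_trace(ga, gb)
    null_mean, null_sd = shuffle_null(ga, gb, n_iter=n_iter, seed=seed)
    onset_idx = detect_onset(delta, null_mean, null_sd, k_sd=k_sd, min_consecutive=min_consecutive)
    return ModulationTrace(
        time_s=tensor.time_s,
        delta=delta,
        null_mean=null_mean,
        null_sd=null_sd,
        n_iter=n_iter,
        n_a=len(ia),
        n_b=len(ib),
        k_sd=k_sd,
        onset_time_s=None if onset_idx is None else float(tensor.time_s[onset_idx]),
    )


def learning_modulation(
    tensor: SessionTensor,
    table: pd.DataFrame,
    threshold: float,
    area: str,
    window: WindowDef = STIM_WINDOW,
    bin_size: int = 100,
    pairs: tuple[str, str] = MAIN_PAIRS,
    n_iter: int = 1000,
    seed: int = 0,
    k_sd: float = 2.0,
    min_consecutive: int = DEFAULT_MIN_CONSECUTIVE,
    min_per_group: int = 5,
) -> LearningModulation:
    """History modulation across the learning dimension (100-trial bins).

    Per bin of ``bin_size`` consecutive trials, the modulation is the
    difference of window-averaged (default stim window) activity between the
    two pair types falling in that bin, with a per-bin trial-shuffle null.
    Bins are anchored at trial 1; the bin containing the learning threshold
    defines relative trial 0.  The onset is the first bin exceeding the
    upper band, persisting ``min_consecutive`` consecutive valid bins.
    """
    if len(table) != tensor.n_trials:
        raise ValueError("table/tensor trial count mismatch")
    table_sorted = table.sort_values("trial_index").reset_index(drop=True)
    vals = window_average(tensor, window)
    area_j = tensor.channel_names.index(area)
    scalars = vals[:, area_j]
    pairs_df = behavior.pair_history(table_sorted)
    pos_of = pd.Series(np.arange(len(table_sorted)), index=table_sorted["trial_index"].to_numpy())
    idx = table_sorted["trial_index"].to_numpy()
    n_bins = len(table_sorted) // bin_size
    if n_bins < 1:
        raise ValueError("fewer trials than one bin")
    rng = np.random.default_rng(seed)
    centers = np.empty(n_bins)
    delta = np.full(n_bins, np.nan)
    null_mean = np.full(n_bins, np.nan)
    null_sd = np.full(n_bins, np.nan)
    missing = np.ones(n_bins, dtype=bool)
    for b in range(n_bins):
        lo, hi = idx[b * bin_size], idx[(b + 1) * bin_size - 1]
        centers[b] = (lo + hi) / 2.0
        in_bin = pairs_df[(pairs_df["curr_trial_index"] >= lo) & (pairs_df["curr_trial_index"] <= hi)]
        ga = scalars[pos_of.loc[in_bin.loc[in_bin["pair"] == pairs[0], "curr_trial_index"]].to_numpy()]
        gb = scalars[pos_of.loc[in_bin.loc[in_bin["pair"] == pairs[1], "curr_trial_index"]].to_numpy()]
        if len(ga) < min_per_group or len(gb) < min_per_group:
            continue
        delta[b] = ga.mean() - gb.mean()
        nm, ns = shuffle_null(ga[:, None], gb[:, None], n_iter=n_iter, seed=rng)
        null_mean[b], null_sd[b] = nm[0], ns[0]
        missing[b] = False
    # the bin whose trial range contains the threshold defines relative 0
    starts = idx[np.arange(n_bins) * bin_size]
    thr_bin = int(np.clip(np.searchsorted(starts, threshold, side="right") - 1, 0, n_bins - 1))
    centers_rel = centers - centers[thr_bin]
    valid = ~missing
    onset_idx = None
    if valid.any():
        oi = detect_onset(
            delta[valid], null_mean[valid], null_sd[valid], k_sd=k_sd, min_consecutive=min_consecutive
        )
        if oi is not None:
            onset_idx = int(np.flatnonzero(valid)[oi])
    return LearningModulation(
        bin_centers=centers,
        bin_centers_rel=centers_rel,
        delta=delta,
        null_mean=null_mean,
        null_sd=null_sd,
        missing=missing,
        n_iter=n_iter,
        bin_size=bin_size,
        threshold=float(threshold),
        k_sd=k_sd,
        onset_trial=None if onset_idx is None else float(centers[onset_idx]),
        onset_trial_rel=None if onset_idx is None else float(centers_rel[onset_idx]),
    )


def onset_threshold_correlation(onsets, thresholds) -> tuple[float, float, int]:
    """Spearman correlation between per-subject onset trials and thresholds.

    Subjects with an undetected onset (None/NaN) are excluded; their count is
    returned as the third element.  Requires >= 3 subjects with onsets.
    """
    onsets = np.array([np.nan if o is None else float(o) for o in onsets])
    thresholds = np.asarray(thresholds, dtype=float)
    if onsets.shape != thresholds.shape:
        raise ValueError("onsets and thresholds must have equal length")
    ok = ~np.isnan(onsets) & ~np.isnan(thresholds)
    n_excluded = int((~ok).sum())
    if ok.sum() < 3:
        raise ValueError(
            f"need >= 3 subjects with detected onsets, have {int(ok.sum())}"
        )
    rho, p = stats.spearmanr(onsets[ok], thresholds[ok])
    return float(rho), float(p), n_excluded
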