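"""Movement controls: body-movement metric, whisker envelope, and
history-conditioned comparisons that should come out null.

The history contrast in cortex is only interpretable if CR-Hit and Hit-Hit
trials do not differ in movement; these routines quantify body movement as
1 - frame-to-frame image correlation within body ROIs (range [0, 2]) and
whisking as a sliding max-minus-min envelope of the whisker angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from . import behavior
from .imaging import STIM_WINDOW, WindowDef

__all__ = [
    "MovementBundle",
    "body_movement_metric",
    "whisker_envelope",
    "movement_history_comparison",
]

BODY_RATE_HZ = 30.0
WHISKER_RATE_HZ = 50.0


@dataclass
class MovementBundle:
    """Per-trial movement traces aligned to texture stop.

    ``body`` is the 1-correlation metric (trials x frames at 30 Hz),
    ``whisker_angle`` the whisker angle in degrees (trials x frames, 50 Hz).
    Either may be None when the corresponding camera is missing.
    """

    body: np.ndarray | None
    body_time_s: np.ndarray | None
    whisker_angle: np.ndarray | None
    whisker_time_s: np.ndarray | None
    roi_labels: tuple = ("forelimbs", "neck")
    body_rate: float = BODY_RATE_HZ
    whisker_rate: float = WHISKER_RATE_HZ


def body_movement_metric(frames: np.ndarray, rois: dict) -> np.ndarray:
    """Body movement per camera frame step: 1 - Pearson r of consecutive frames.

    ``frames`` is a T x H x W stack; ``rois`` maps label -> boolean mask.
    Per ROI the metric is computed over the flattened masked pixels of
    consecutive frames, then ROIs are averaged into one "body" vector of
    length T - 1.  Steps where a frame has zero variance within an ROI are
    NaN (undefined correlation) and are ignored by the ROI average.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a T x H x W stack with at least 2 frames")
    if not rois:
        raise ValueError("no ROIs given")
    per_roi = []
    for label, mask in rois.items():
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"ROI {label!r} is empty")
        pix = frames[:, mask]  # T x n_pix
        x = pix[:-1] - pix[:-1].mean(axis=1, keepdims=True)
        y = pix[1:] - pix[1:].mean(axis=1, keepdims=True)
        sx = np.sqrt((x**2).sum(axis=1))
        sy = np.sqrt((y**2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (x * y).sum(axis=1) / (sx * sy)
        r[(sx == 0) | (sy == 0)] = np.nan
        per_roi.append(1.0 - r)
    stacked = np.vstack(per_roi)
    out = np.full(stacked.shape[1], np.nan)
    ok = ~np.isnan(stacked)
    has_any = ok.any(axis=0)
    with np.errstate(invalid="ignore"):
        out[has_any] = np.nanmean(stacked[:, has_any], axis=0)
    return out


def whisker_envelope(
    angle: np.ndarray,
    rate_hz: float = WHISKER_RATE_HZ,
    window_s: float = 0.05,
    baseline_samples: int | None = None,
) -> np.ndarray:
    """Whisking envelope: sliding (max - min) of the whisker angle.

    The window length equals the imaging frame duration (50 ms by default).
    The window is centered; edges use the available samples.  When
    ``baseline_samples`` is given, the mean of that many leading samples is
    subtracted afterwards (frame-zero normalization by subtraction — angles
    can be near zero, so division is not meaningful).
    """
    angle = np.asarray(angle, dtype=float)
    w = int(round(window_s * rate_hz))
    if w < 1:
        raise ValueError(f"window {window_s}s shorter than one sample at {rate_hz} Hz")
    if angle.shape[-1] < w:
        raise ValueError("trace shorter than the window")
    env = maximum_filter1d(angle, size=w, axis=-1, mode="nearest") - minimum_filter1d(
        angle, size=w, axis=-1, mode="nearest"
    )
    if baseline_samples:
        env = env - env[..., :baseline_samples].mean(axis=-1, keepdims=True)
    return env


def _resample(traces: np.ndarray, src_time: np.ndarray, dst_time: np.ndarray) -> np.ndarray:
    out = np.empty((traces.shape[0], dst_time.size))
    for i in range(traces.shape[0]):
        out[i] = np.interp(dst_time, src_time, traces[i])
    return out


def movement_history_comparison(
    bundle: MovementBundle,
    table: pd.DataFrame,
    session_id=None,
    window: WindowDef = STIM_WINDOW,
    imaging_rate_hz: float = 20.0,
    pairs: tuple[str, str] = ("CR-Hit", "Hit-Hit"),
) -> dict:
    """Compare window-averaged movement between CR-Hit and Hit-Hit trials.

    Video-rate traces are linearly resampled to the imaging grid, window
    averaged per trial, and compared within subject with a rank-sum
    (Mann-Whitney) test.  Missing modalities are reported as such, never
    silently passed.
    """
    pairs_df = behavior.pair_history(table.sort_values("trial_index").reset_index(drop=True))
    if session_id is not None:
        keep_trials = table.loc[table["session_id"] == session_id, "trial_index"]
        pairs_df = pairs_df[pairs_df["curr_trial_index"].isin(keep_trials)]
    pos_of = pd.Series(
        np.arange(len(table)), index=table.sort_values("trial_index")["trial_index"].to_numpy()
    )
    ia = pos_of.loc[pairs_df.loc[pairs_df["pair"] == pairs[0], "curr_trial_index"]].to_numpy()
    ib = pos_of.loc[pairs_df.loc[pairs_df["pair"] == pairs[1], "curr_trial_index"]].to_numpy()
    out: dict = {"n_a": int(len(ia)), "n_b": int(len(ib))}
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError(f"both pair types needed; got {len(ia)}/{len(ib)}")

    for name, traces, src_time, derive in (
        ("body", bundle.body, bundle.body_time_s, None),
        ("whisker", bundle.whisker_angle, bundle.whisker_time_s, "envelope"),
    ):
        if traces is None or src_time is None:
            out[name] = {"missing": True}
            continue
        if derive == "envelope":
            traces = whisker_envelope(traces, rate_hz=bundle.whisker_rate)
        grid = np.arange(src_time[0], src_time[-1], 1.0 / imaging_rate_hz)
        res = _resample(np.asarray(traces, dtype=float), np.asarray(src_time), grid)
        m = (grid >= window.start_s) & (grid < window.stop_s)
        if not m.any():
            raise ValueError(f"window {window.name} outside the {name} trace")
        per_trial = np.nanmean(res[:, m], axis=1)
        va, vb = per_trial[ia], per_trial[ib]
        u, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
        out[name] = {
            "missing": False,
            "mean_a": float(np.nanmean(va)),
            "mean_b": float(np.nanmean(vb)),
            "statistic": float(u),
            "p": float(p),
        }
    return out
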