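"""Single-trial ROC-AUC discrimination between trial groups.

The AUC is the probability that a randomly drawn trial from the positive
group has a larger response than one from the reference group, with ties
given half credit (midrank convention) — equivalently the Mann-Whitney U
statistic normalised by n_a * n_b.  0.5 means no discrimination power.

Two contrasts are analysed:

* **history** — CR-Hit vs Hit-Hit, i.e. the same current trial type (Hit)
  split by the preceding trial; CR-Hit is the positive class.
* **current** — Hit vs CR regardless of history; Hit is the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import behavior
from .imaging import SessionTensor, WindowDef, window_average

__all__ = ["AUCResult", "roc_auc", "auc_trace", "auc_map", "compare_auc"]

#: below this many trials per class an AUC trace is refused
MIN_GROUP_SIZE = 10


def roc_auc(values_a, values_b) -> float:
    """Rank-based AUC of group A ("positive") against group B.

    AUC = P(a > b) + 0.5 * P(a = b) over all cross pairs.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ranks = stats.rankdata(np.concatenate([a, b]))  # midranks handle ties
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


@dataclass
class AUCResult:
    mode: str  # "history" | "current"
    values: np.ndarray  # per frame, or H x W per pixel
    n_a: int
    n_b: int
    time_s: np.ndarray | None = None
    window: str | None = None

    def to_frame(self) -> pd.DataFrame:
        if self.time_s is None:
            raise ValueError("no time axis (window-averaged map result)")
        return pd.DataFrame({"time_s": self.time_s, "auc": self.values})


def _contrast_groups(
    table: pd.DataFrame, mode: str, session_id=None
) -> tuple[np.ndarray, np.ndarray]:
    """Tensor row positions of the (positive, reference) groups for a contrast."""
    table_sorted = table.sort_values("trial_index").reset_index(drop=True)
    pos_of = pd.Series(np.arange(len(table_sorted)), index=table_sorted["trial_index"].to_numpy())
    if session_id is not None:
        in_phase = table_sorted["session_id"] == session_id
    else:
        in_phase = pd.Series(True, index=table_sorted.index)
    if mode == "history":
        pairs = behavior.pair_history(table_sorted)
        keep = pairs["curr_trial_index"].isin(table_sorted.loc[in_phase, "trial_index"])
        pairs = pairs[keep]
        ia = pos_of.loc[pairs.loc[pairs["pair"] == "CR-Hit", "curr_trial_index"]].to_numpy()
        ib = pos_of.loc[pairs.loc[pairs["pair"] == "Hit-Hit", "curr_trial_index"]].to_numpy()
    elif mode == "current":
        sub = table_sorted[in_phase]
        ia = pos_of.loc[sub.loc[sub["outcome"] == "Hit", "trial_index"]].to_numpy()
        ib = pos_of.loc[sub.loc[sub["outcome"] == "CR", "trial_index"]].to_numpy()
    else:
        raise ValueError(f"mode must be 'history' or 'current', got {mode!r}")
    return ia, ib


def auc_trace(
    tensor: SessionTensor,
    table: pd.DataFrame,
    mode: str,
    area: str,
    session_id=None,
    min_group: int = MIN_GROUP_SIZE,
) -> AUCResult:
    """Frame-wise AUC of one area for the history or current contrast."""
    if len(table) != tensor.n_trials:
        raise ValueError("table/tensor trial count mismatch")
    ia, ib = _contrast_groups(table, mode, session_id)
    if len(ia) < min_group or len(ib) < min_group:
        raise ValueError(
            f"{mode} AUC needs >= {min_group} trials per class, got {len(ia)}/{len(ib)}"
        )
    traces = tensor.channel(area)
    vals = np.array([roc_auc(traces[ia, f], traces[ib, f]) for f in range(traces.shape[1])])
    return AUCResult(
        mode=mode, values=vals, n_a=len(ia), n_b=len(ib), time_s=tensor.time_s
    )


def auc_map(
    pixel_tensor: SessionTensor,
    table: pd.DataFrame,
    mode: str,
    window: WindowDef,
    session_id=None,
    min_group: int = MIN_GROUP_SIZE,
) -> AUCResult:
    """Per-pixel AUC of window-averaged activity (H x W map)."""
    if pixel_tensor.channel_kind != "pixel":
        raise ValueError("auc_map requires a pixel tensor")
    ia, ib = _contrast_groups(table, mode, session_id)
    if len(ia) < min_group or len(ib) < min_group:
        raise ValueError(
            f"{mode} AUC needs >= {min_group} trials per class, got {len(ia)}/{len(ib)}"
        )
    wavg = window_average(pixel_tensor, window)  # trials x H x W
    h, w = wavg.shape[1:]
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = roc_auc(wavg[ia, i, j], wavg[ib, i, j])
    return AUCResult(mode=mode, values=out, n_a=len(ia), n_b=len(ib), window=window.name)


def compare_auc(history_auc, current_auc) -> dict:
    """Cohort comparison of per-subject window-averaged AUCs.

    Wilcoxon signed-rank between the paired history and current AUC vectors
    (Pratt zero handling) plus one-sample signed-rank tests of each mode
    against chance (0.5).  Identical vectors return p = 1 with a flag.
    """
    h = np.asarray(history_auc, dtype=float)
    c = np.asarray(current_auc, dtype=float)
    if h.shape != c.shape:
        raise ValueError("paired AUC vectors must have the same length")
    if h.size < 3:
        raise ValueError("need >= 3 subjects")
    out: dict = {"n_subjects": int(h.size)}
    out["history_vs_current"] = _signed_rank(h, c)
    out["history_vs_chance"] = _signed_rank(h, np.full_like(h, 0.5))
    out["current_vs_chance"] = _signed_rank(c, np.full_like(c, 0.5))
    return out


def _signed_rank(a: np.ndarray, b: np.ndarray) -> dict:
    d = a - b
    if np.all(d == 0):
        return {"statistic": 0.0, "p": 1.0, "all_zero": True}
    res = stats.wilcoxon(a, b, zero_method="pratt")
    return {"statistic": float(res.statistic), "p": float(res.pvalue), "all_zero": False}
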