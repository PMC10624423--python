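"""Behavioral analysis for the go/no-go texture discrimination task.

Trial outcome typing, trial-history pairing, d' learning curves, sigmoid
learning thresholds, and assignment of naive/learning/expert phases.

Conventions
-----------
Trial indices are 1-based (the "trial number" axis of a learning curve).
Outcomes follow signal-detection nomenclature: a *Hit* is a lick to the go
texture, a *Miss* a withheld lick to go, *FA* (false alarm) a lick to no-go,
and *CR* (correct rejection) a withheld lick to no-go.  A history pair such
as "CR-Hit" denotes a Hit trial immediately preceded (within the same
session) by a CR trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtri

__all__ = [
    "OUTCOMES",
    "classify_outcome",
    "pair_history",
    "pair_counts",
    "compute_dprime",
    "LearningCurve",
    "bin_learning_curve",
    "SigmoidFit",
    "sigmoid",
    "fit_sigmoid",
    "learning_threshold",
    "PhaseAssignment",
    "assign_phases",
    "history_conditioned_behavior",
]

OUTCOMES = ("Hit", "Miss", "FA", "CR")

_OUTCOME_MAP = {
    ("go", True): "Hit",
    ("go", False): "Miss",
    ("nogo", True): "FA",
    ("nogo", False): "CR",
}


def classify_outcome(texture: str, licked: bool) -> str:
    """Map (texture, lick) to the trial outcome label.

    go+lick -> Hit, go+no-lick -> Miss, nogo+lick -> FA, nogo+no-lick -> CR.
    """
    key = (texture, bool(licked))
    if texture not in ("go", "nogo"):
        raise ValueError(f"unknown texture label: {texture!r} (expected 'go' or 'nogo')")
    return _OUTCOME_MAP[key]


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"trial_index", "session_id", "texture", "licked", "outcome"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if table["trial_index"].duplicated().any():
        raise ValueError("duplicate trial_index in trial table")
    return table.sort_values("trial_index")


def pair_history(table: pd.DataFrame) -> pd.DataFrame:
    """Pair every trial with its immediate predecessor within the session.

    Returns a DataFrame with one row per trial except the first trial of each
    session, columns ``prev_outcome``, ``curr_outcome``, ``curr_trial_index``
    and ``pair`` (e.g. ``"CR-Hit"``).  Pairs never cross session boundaries:
    the overnight gap breaks the trial-to-trial continuity the history
    analysis relies on.
    """
    table = _validate_table(table)
    prev_outcome = table["outcome"].shift(1)
    same_session = table["session_id"].eq(table["session_id"].shift(1))
    keep = same_session.fillna(False)
    pairs = pd.DataFrame(
        {
            "prev_outcome": prev_outcome[keep],
            "curr_outcome": table["outcome"][keep],
            "curr_trial_index": table["trial_index"][keep],
        }
    ).reset_index(drop=True)
    pairs["pair"] = pairs["prev_outcome"] + "-" + pairs["curr_outcome"]
    return pairs


def pair_counts(table: pd.DataFrame) -> pd.Series:
    """Count history pairs (e.g. CR-Hit) in a trial table."""
    return pair_history(table)["pair"].value_counts()


def compute_dprime(n_hit: int, n_miss: int, n_fa: int, n_cr: int) -> float:
    """Signal-detection sensitivity d' = Z(hit rate) - Z(false-alarm rate).

    Z is the probit (inverse normal CDF).  Rates of exactly 0 or 1 are
    clipped to 1/(2N) and 1 - 1/(2N), with N the number of go (or no-go)
    trials, so the probit stays finite.
    """
    for n in (n_hit, n_miss, n_fa, n_cr):
        if n < 0:
            raise ValueError("trial counts must be nonnegative")
    n_go = n_hit + n_miss
    n_nogo = n_fa + n_cr
    if n_go == 0:
        raise ValueError("d' undefined: no go trials (hit rate has no denominator)")
    if n_nogo == 0:
        raise ValueError("d' undefined: no no-go trials (FA rate has no denominator)")
    hit_rate = _clip_rate(n_hit / n_go, n_go)
    fa_rate = _clip_rate(n_fa / n_nogo, n_nogo)
    return float(ndtri(hit_rate) - ndtri(fa_rate))


def _clip_rate(rate: float, n: int) -> float:
    lo = 1.0 / (2 * n)
    return min(max(rate, lo), 1.0 - lo)


@dataclass
class LearningCurve:
    """Binned d' versus trial number.

    ``dprime`` is NaN where a bin is missing (no go or no no-go trials);
    ``missing`` marks those bins.
    """

    bin_size: int
    bin_centers: np.ndarray  # trial units, 1-based axis
    dprime: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.dprime = np.asarray(self.dprime, dtype=float)
        if self.missing is None:
            self.missing = np.isnan(self.dprime)
        self.missing = np.asarray(self.missing, dtype=bool)

    @property
    def valid(self) -> np.ndarray:
        return ~self.missing

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_center": self.bin_centers, "dprime": self.dprime, "missing": self.missing}
        )


def bin_learning_curve(table: pd.DataFrame, bin_size: int = 100) -> LearningCurve:
    """d' per non-overlapping bin of ``bin_size`` consecutive trials.

    A trailing partial bin is dropped.  Bins without both trial classes are
    flagged missing rather than extrapolated.
    """
    table = _validate_table(table)
    if len(table) == 0:
        raise ValueError("empty trial table")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n_bins = len(table) // bin_size
    if n_bins == 0:
        raise ValueError(f"fewer than bin_size={bin_size} trials ({len(table)})")
    outcome = table["outcome"].to_numpy()
    idx = table["trial_index"].to_numpy()
    centers = np.empty(n_bins)
    dprime = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sl = slice(b * bin_size, (b + 1) * bin_size)
        centers[b] = idx[sl].mean()
        counts = {o: int(np.sum(outcome[sl] == o)) for o in OUTCOMES}
        if counts["Hit"] + counts["Miss"] == 0 or counts["FA"] + counts["CR"] == 0:
            continue  # bin stays missing
        dprime[b] = compute_dprime(counts["Hit"], counts["Miss"], counts["FA"], counts["CR"])
    return LearningCurve(bin_size=bin_size, bin_centers=centers, dprime=dprime)


def sigmoid(t, a, b, c):
    """Logistic learning curve s(t) = a / (1 + exp(-(t - b)/c)).

    ``a`` is the d' amplitude, ``b`` the trial number of the inflection
    (half-amplitude) point, ``c`` the steepness in trials.
    """
    return a / (1.0 + np.exp(-(np.asarray(t, dtype=float) - b) / c))


@dataclass
class SigmoidFit:
    a: float
    b: float
    c: float
    rss: float
    converged: bool
    degenerate: bool
    n_points: int

    def predict(self, t):
        return sigmoid(t, self.a, self.b, self.c)


# amplitude below which a fit is declared unidentifiable (flat curve)
_DEGENERATE_A = 0.05


def fit_sigmoid(
    curve: LearningCurve,
    a_max: float = 6.0,
    n_starts_b: int = 4,
    n_starts_c: int = 2,
) -> SigmoidFit:
    """Bounded least-squares sigmoid fit with multi-start initialisation.

    Starts on a grid of (b, c) within the observed trial range; a in
    [0, a_max], b within the bin-center range, c > 0.  The best start by
    residual sum of squares wins.  A fit with amplitude ~0 is flagged
    degenerate (b is then unidentifiable).
    """
    t = curve.bin_centers[curve.valid]
    y = curve.dprime[curve.valid]
    if t.size < 4:
        raise ValueError(f"need >= 4 non-missing bins to fit a sigmoid, got {t.size}")
    t_lo, t_hi = float(t.min()), float(t.max())
    span = max(t_hi - t_lo, 1.0)
    bounds = ([0.0, t_lo, 1e-6], [a_max, t_hi, 10.0 * span])
    a0 = float(np.clip(y.max(), 0.1, a_max))
    best = None
    for b0 in np.linspace(t_lo + 0.1 * span, t_hi - 0.1 * span, n_starts_b):
        for c0 in (span / 20.0, span / 5.0):
            try:
                popt, _ = optimize.curve_fit(
                    sigmoid, t, y, p0=[a0, b0, c0], bounds=bounds, maxfev=5000
                )
            except RuntimeError:
                continue
            rss = float(np.sum((sigmoid(t, *popt) - y) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
    if best is None:
        raise RuntimeError("sigmoid fit failed to converge from all starts")
    (a, b, c), rss = best
    return SigmoidFit(
        a=float(a),
        b=float(b),
        c=float(c),
        rss=rss,
        converged=True,
        degenerate=bool(a < _DEGENERATE_A),
        n_points=int(t.size),
    )


def learning_threshold(fit: SigmoidFit) -> float:
    """Trial number at the inflection (half-amplitude) point of the fit."""
    if not fit.converged:
        raise ValueError("cannot take a threshold from a non-convergent fit")
    if fit.degenerate:
        raise ValueError(
            f"degenerate fit (a={fit.a:.3g}): inflection point unidentifiable"
        )
    return fit.b


@dataclass
class PhaseAssignment:
    """One session per phase: naive before, learning at, expert after threshold."""

    naive: object
    learning: object
    expert: object
    overlapping: bool = False  # learning == expert (threshold crossed on last day)

    def as_dict(self) -> dict:
        return {"naive": self.naive, "learning": self.learning, "expert": self.expert}


def assign_phases(
    table: pd.DataFrame, threshold: float, min_pairs: int = 20
) -> PhaseAssignment:
    """Assign naive / learning / expert sessions given a learning threshold.

    naive: first session lying entirely before the threshold with at least
    ``min_pairs`` trials of each of CR-Hit and Hit-Hit (a naive day without
    correct rejections cannot support the history contrast).  learning: the
    session containing the threshold trial.  expert: the last session.
    """
    table = _validate_table(table)
    sessions = (
        table.groupby("session_id", sort=False)["trial_index"].agg(["min", "max"]).reset_index()
    )
    first_trial, last_trial = sessions["min"].iloc[0], sessions["max"].iloc[-1]
    if not (first_trial <= threshold <= last_trial):
        raise ValueError(
            f"threshold {threshold:.1f} outside recorded trials [{first_trial}, {last_trial}]"
        )
    pairs = pair_history(table)
    sess_of_trial = table.set_index("trial_index")["session_id"]
    pairs = pairs.assign(session_id=sess_of_trial.loc[pairs["curr_trial_index"]].to_numpy())

    naive = None
    for _, row in sessions.iterrows():
        if row["max"] >= threshold:
            break
        counts = pairs.loc[pairs["session_id"] == row["session_id"], "pair"].value_counts()
        if counts.get("CR-Hit", 0) >= min_pairs and counts.get("Hit-Hit", 0) >= min_pairs:
            naive = row["session_id"]
            break
    if naive is None:
        warnings.warn("no session qualifies as naive (enough CR-Hit/Hit-Hit before threshold)")
    in_sess = sessions[(sessions["min"] <= threshold) & (sessions["max"] >= threshold)]
    learning = in_sess["session_id"].iloc[0]
    expert = sessions["session_id"].iloc[-1]
    return PhaseAssignment(
        naive=naive, learning=learning, expert=expert, overlapping=bool(learning == expert)
    )


def history_conditioned_behavior(
    table: pd.DataFrame,
    predecessors: tuple[str, ...] = ("Hit", "CR"),
    bin_size: int = 100,
) -> dict:
    """Behavioral report stratified by the preceding trial's outcome.

    Returns per-predecessor learning curves (binned over the restricted
    trials), false-alarm probability by predecessor, and a two-proportion
    chi-square comparison of FA probability between the first two
    predecessor strata.  Empty strata are flagged missing, not fabricated.
    """
    table = _validate_table(table)
    pairs = pair_history(table)
    report: dict = {"curves": {}, "fa_by_predecessor": {}, "missing": []}
    by_trial = table.set_index("trial_index")
    n_bins = len(table) // bin_size
    first = int(table["trial_index"].iloc[0])
    for prev in predecessors:
        idx = pairs.loc[pairs["prev_outcome"] == prev, "curr_trial_index"]
        sub = by_trial.loc[idx].reset_index()
        if len(sub) == 0:
            report["missing"].append(prev)
            report["curves"][prev] = None
        else:
            # bins on the *global* trial axis so strata stay comparable
            centers = np.empty(n_bins)
            dp = np.full(n_bins, np.nan)
            for b in range(n_bins):
                lo, hi = first + b * bin_size, first + (b + 1) * bin_size
                centers[b] = lo + (bin_size - 1) / 2.0
                blk = sub[(sub["trial_index"] >= lo) & (sub["trial_index"] < hi)]
                counts = blk["outcome"].value_counts()
                n_go = counts.get("Hit", 0) + counts.get("Miss", 0)
                n_nogo = counts.get("FA", 0) + counts.get("CR", 0)
                if n_go and n_nogo:
                    dp[b] = compute_dprime(
                        counts.get("Hit", 0), counts.get("Miss", 0),
                        counts.get("FA", 0), counts.get("CR", 0),
                    )
            if np.isnan(dp).all():
                report["missing"].append(prev)
                report["curves"][prev] = None
            else:
                report["curves"][prev] = LearningCurve(
                    bin_size=bin_size, bin_centers=centers, dprime=dp
                )
        nogo = sub[sub["texture"] == "nogo"]
        if len(nogo) == 0:
            report["fa_by_predecessor"][prev] = {"n": 0, "p_fa": np.nan}
        else:
            report["fa_by_predecessor"][prev] = {
                "n": int(len(nogo)),
                "n_fa": int(nogo["licked"].sum()),
                "p_fa": float(nogo["licked"].mean()),
            }
    c0, c1 = (report["curves"].get(p) for p in predecessors[:2])
    if c0 is not None and c1 is not None:
        n = min(c0.dprime.size, c1.dprime.size)
        d0, d1 = c0.dprime[:n], c1.dprime[:n]
        ok = ~np.isnan(d0) & ~np.isnan(d1)
        if ok.sum() >= 3 and not np.allclose(d0[ok], d1[ok]):
            w = stats.wilcoxon(d0[ok], d1[ok], zero_method="pratt")
            report["curve_comparison"] = {"p": float(w.pvalue), "statistic": float(w.statistic)}
        else:
            report["curve_comparison"] = {"p": 1.0, "statistic": 0.0}
    else:
        report["curve_comparison"] = None

    a, b = (report["fa_by_predecessor"].get(p, {"n": 0}) for p in predecessors[:2])
    if a["n"] > 0 and b["n"] > 0:
        tbl = np.array(
            [[a["n_fa"], a["n"] - a["n_fa"]], [b["n_fa"], b["n"] - b["n_fa"]]]
        )
        if tbl[:, 0].sum() in (0, tbl.sum()):  # degenerate: all or no FAs
            report["fa_comparison"] = {"p": 1.0, "statistic": 0.0}
        else:
            chi2, p, _, _ = stats.chi2_contingency(tbl, correction=False)
            report["fa_comparison"] = {"p": float(p), "statistic": float(chi2)}
    else:
        report["fa_comparison"] = None
    return report
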