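"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the analysis assumes: a pseudo-random
go/no-go texture sequence (no more than ``max_repeats`` repetitions), lick
behavior whose d' follows a sigmoid across trials, event-aligned dF/F in a
barrel-cortex-like ("BC") and a rostrolateral-like ("RL") area with an
additive history effect (CR-preceded Hit trials > Hit-preceded) that
switches on at a configurable learning-time onset and acts in a
configurable trial-time window per area, an optional slow contamination
channel shared between the signal and a calcium-insensitive control
wavelength, and movement traces drawn identically for all history
conditions.

Every injected parameter is recorded in :class:`GroundTruth` so recovery
tests can compare estimates against the truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import behavior
from .imaging import PRE_WINDOW, STIM_WINDOW, AreaMaskSet, SessionTensor, WindowDef

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "simulate_behavior",
    "simulate_session_tensor",
    "simulate_pixel_tensor",
    "simulate_movement",
    "default_pixel_masks",
    "make_fixture",
]

_NAMED_WINDOWS = {"pre": PRE_WINDOW, "stim": STIM_WINDOW}

# RNG sub-stream tags: same seed => identical draws per component, so e.g.
# regenerating with contamination_amp=0 leaves the noise untouched
_STREAM_BEHAVIOR, _STREAM_NOISE, _STREAM_CONTAM, _STREAM_PIXEL, _STREAM_MOVE = range(5)


@dataclass
class SynthConfig:
    """Ground-truth parameters of one simulated subject.

    Defaults emulate the study conditions: ~500 trials per daily session
    over 5 days, 20 Hz imaging in a 4 s window around texture stop, learning
    to d' ~ 2.5 with an inflection near trial 1000, and a history effect
    (~2% dF/F) that switches on 500 trials after the inflection — in the
    stim window for BC and the pre window for RL.
    """

    n_trials: int = 2500
    n_sessions: int = 5
    frame_rate: float = 20.0
    trial_window: tuple[float, float] = (-2.0, 2.0)
    p_go: float = 0.5
    max_repeats: int = 3
    learn_a: float = 2.5  # d' amplitude of the sigmoid
    learn_b: float = 1000.0  # inflection trial
    learn_c: float = 150.0  # steepness, trials
    base_response: float = 0.05  # dF/F stim response amplitude in BC
    nogo_response_frac: float = 0.4  # no-go stim response as fraction of go
    history_effect: float = 0.02  # additive dF/F on CR-preceded trials
    history_onset_learning: float = 1500.0  # trial index where the effect switches on
    history_ramp_trials: int = 0  # 0 = hard step; >0 = linear ramp length
    history_window: dict = field(default_factory=lambda: {"BC": "stim", "RL": "pre"})
    noise_sd: float = 0.05  # per-frame Gaussian dF/F noise
    contamination_amp: float = 0.02  # slow shared-channel contamination
    n_areas: int = 2
    pixel_grid: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1 (empty dataset refused)")
        if self.n_sessions < 1 or self.n_sessions > self.n_trials:
            raise ValueError("n_sessions must be in [1, n_trials]")
        if not 0.0 <= self.p_go <= 1.0:
            raise ValueError("p_go must be a probability")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not self.trial_window[0] < 0.0 < self.trial_window[1]:
            raise ValueError("trial_window must span t=0 (texture stop)")
        if self.max_repeats < 1:
            raise ValueError(
                "max_repeats must be >= 1: with two textures a run limit of 0 is infeasible"
            )
        if not 1 <= self.learn_b <= self.n_trials:
            raise ValueError("learn_b must lie within [1, n_trials]")
        if not 1 <= self.history_onset_learning <= self.n_trials:
            raise ValueError("history_onset_learning must lie within [1, n_trials]")
        if self.learn_c <= 0:
            raise ValueError("learn_c must be positive")
        if self.noise_sd < 0 or self.contamination_amp < 0:
            raise ValueError("noise/contamination amplitudes must be nonnegative")
        if self.n_areas < 2:
            raise ValueError("need at least the BC-like and RL-like areas")
        for area, win in self.history_window.items():
            if win not in _NAMED_WINDOWS:
                raise ValueError(f"unknown history window {win!r} for area {area!r}")

    @property
    def area_names(self) -> tuple:
        extra = tuple(f"A{i}" for i in range(2, self.n_areas))
        return ("BC", "RL") + extra

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])

    def time_axis(self) -> np.ndarray:
        t0, t1 = self.trial_window
        n = int(round((t1 - t0) * self.frame_rate))
        return t0 + np.arange(n) / self.frame_rate

    def target_dprime(self, trial_index) -> np.ndarray:
        """The generative d' sigmoid evaluated at 1-based trial indices."""
        t = np.asarray(trial_index, dtype=float)
        return self.learn_a / (1.0 + np.exp(-(t - self.learn_b) / self.learn_c))


@dataclass
class GroundTruth:
    """SynthConfig plus the realized per-trial quantities."""

    config: SynthConfig
    p_lick: np.ndarray  # realized per-trial lick probability
    injected_amplitude: np.ndarray  # per-trial additive history effect (dF/F)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self.config)
        d["p_lick"] = [float(x) for x in self.p_lick]
        d["injected_amplitude"] = [float(x) for x in self.injected_amplitude]
        return d


def simulate_behavior(config: SynthConfig) -> pd.DataFrame:
    """Simulate the go/no-go trial table.

    The texture sequence is drawn per trial with rejection: a draw that
    would extend a same-texture run past ``max_repeats`` is redrawn, exactly
    enforcing the task's "no more than three repetitions" constraint.  Lick
    probabilities place the population d' on the target sigmoid with an
    unbiased criterion: hit rate = Phi(d'/2), FA rate = Phi(-d'/2).

    Returns a table with the trial schema columns plus the realized
    ``p_lick`` (kept in memory, not written to fixture CSVs).
    """
    rng = config.rng(_STREAM_BEHAVIOR)
    n = config.n_trials
    if config.p_go in (0.0, 1.0) and n > config.max_repeats:
        raise ValueError(
            "infeasible sequence constraint: a single-texture sequence cannot "
            f"respect max_repeats={config.max_repeats}"
        )
    textures = np.empty(n, dtype=object)
    run = 0
    for i in range(n):
        tex = "go" if rng.random() < config.p_go else "nogo"
        if i > 0 and tex == textures[i - 1] and run >= config.max_repeats:
            while tex == textures[i - 1]:
                tex = "go" if rng.random() < config.p_go else "nogo"
        run = run + 1 if i > 0 and tex == textures[i - 1] else 1
        textures[i] = tex
    idx = np.arange(1, n + 1)
    d = config.target_dprime(idx)
    p_lick = np.where(textures == "go", ndtr(d / 2.0), ndtr(-d / 2.0))
    licked = rng.random(n) < p_lick
    outcome = np.array(
        [behavior.classify_outcome(t, bool(l)) for t, l in zip(textures, licked)], dtype=object
    )
    session_bounds = np.array_split(idx, config.n_sessions)
    session_id = np.concatenate(
        [np.full(len(chunk), f"day{k + 1:02d}", dtype=object) for k, chunk in enumerate(session_bounds)]
    )
    # 12 s trial cadence within each day, restarting each session
    within = np.concatenate([np.arange(len(chunk)) for chunk in session_bounds])
    return pd.DataFrame(
        {
            "trial_index": idx,
            "session_id": session_id,
            "texture": textures,
            "licked": licked.astype(int),
            "outcome": outcome,
            "t_texture_stop_s": 8.0 + 12.0 * within,
            "p_lick": p_lick,
        }
    )


def _response_kernel(time_s: np.ndarray, window: WindowDef, ramp_s: float = 0.2) -> np.ndarray:
    """Half-cosine ramp to a plateau spanning the window, decaying after it."""
    k = np.zeros_like(time_s)
    up = (time_s >= window.start_s) & (time_s < window.start_s + ramp_s)
    k[up] = 0.5 * (1 - np.cos(np.pi * (time_s[up] - window.start_s) / ramp_s))
    k[(time_s >= window.start_s + ramp_s) & (time_s < window.stop_s)] = 1.0
    down = (time_s >= window.stop_s) & (time_s < window.stop_s + ramp_s)
    k[down] = 0.5 * (1 + np.cos(np.pi * (time_s[down] - window.stop_s) / ramp_s))
    return k


def _history_gain(config: SynthConfig, trial_index: np.ndarray) -> np.ndarray:
    """Learning-time gate of the history effect: hard step or optional ramp."""
    t = np.asarray(trial_index, dtype=float)
    if config.history_ramp_trials > 0:
        g = (t - config.history_onset_learning) / config.history_ramp_trials
        return np.clip(g, 0.0, 1.0) * (t >= config.history_onset_learning)
    return (t >= config.history_onset_learning).astype(float)


def _clean_area_signal(table: pd.DataFrame, config: SynthConfig) -> np.ndarray:
    """Noise-free trials x frames x areas signal (responses + history effect)."""
    time_s = config.time_axis()
    n, f, a = len(table), time_s.size, config.n_areas
    clean = np.zeros((n, f, a))
    stim_k = _response_kernel(time_s, STIM_WINDOW)
    pre_k = _response_kernel(time_s, PRE_WINDOW)
    go = (table["texture"] == "go").to_numpy()
    # BC: stimulus-evoked touch response, stronger for go (licked/rewarded) trials
    amp = np.where(go, config.base_response, config.nogo_response_frac * config.base_response)
    clean[:, :, 0] += amp[:, None] * stim_k[None, :]
    # RL: anticipatory pre-period activity on all trials
    clean[:, :, 1] += 0.4 * config.base_response * pre_k[None, :]
    # history effect: CR-preceded trials at/after the learning-time onset
    pairs = behavior.pair_history(table)
    cr_pre = pairs.loc[pairs["prev_outcome"] == "CR", "curr_trial_index"].to_numpy()
    gate = np.zeros(n)
    pos = np.searchsorted(table["trial_index"].to_numpy(), cr_pre)
    gate[pos] = _history_gain(config, cr_pre)
    for j, area in enumerate(config.area_names[:2]):
        win_k = stim_k if config.history_window.get(area, "stim") == "stim" else pre_k
        clean[:, :, j] += config.history_effect * gate[:, None] * win_k[None, :]
    return clean


def _contamination(table: pd.DataFrame, config: SynthConfig) -> np.ndarray:
    """Slow per-trial contamination trace (sinusoid + AR(1) drift), trials x frames."""
    time_s = config.time_axis()
    rng = config.rng(_STREAM_CONTAM)
    n, f = len(table), time_s.size
    phase = rng.uniform(0, 2 * np.pi, size=n)
    sine = np.sin(2 * np.pi * 0.2 * time_s[None, :] + phase[:, None])
    ar = np.empty((n, f))
    eps = rng.standard_normal((n, f))
    ar[:, 0] = eps[:, 0]
    for k in range(1, f):
        ar[:, k] = 0.98 * ar[:, k - 1] + 0.2 * eps[:, k]
    ar /= max(np.abs(ar).max(), 1e-12)
    return config.contamination_amp * (0.7 * sine + 0.3 * ar)


def simulate_session_tensor(
    table: pd.DataFrame, config: SynthConfig
) -> tuple[SessionTensor, SessionTensor | None, GroundTruth]:
    """Simulate the event-aligned area tensor (plus control channel).

    Returns ``(signal, control, ground_truth)``.  The control tensor carries
    exactly the contamination trace shared with the signal channel (it is
    calcium-insensitive), so signal - control recovers the contamination-free
    signal; it is None when ``contamination_amp`` is 0.
    """
    if len(table) != config.n_trials:
        raise ValueError(
            f"table has {len(table)} trials but config.n_trials={config.n_trials}"
        )
    time_s = config.time_axis()
    clean = _clean_area_signal(table, config)
    noise = config.rng(_STREAM_NOISE).standard_normal(clean.shape) * config.noise_sd
    values = clean + noise
    control = None
    if config.contamination_amp > 0:
        contam = _contamination(table, config)[:, :, None]
        values = values + contam
        control = SessionTensor(
            values=np.broadcast_to(contam, clean.shape).copy(),
            time_s=time_s,
            frame_rate=config.frame_rate,
            channel_names=config.area_names,
        )
    signal = SessionTensor(
        values=values,
        time_s=time_s,
        frame_rate=config.frame_rate,
        channel_names=config.area_names,
    )
    idx = table["trial_index"].to_numpy()
    pairs = behavior.pair_history(table)
    cr_pre = set(pairs.loc[pairs["prev_outcome"] == "CR", "curr_trial_index"])
    injected = np.array(
        [config.history_effect * g if i in cr_pre else 0.0 for i, g in zip(idx, _history_gain(config, idx))]
    )
    p_lick = table["p_lick"].to_numpy() if "p_lick" in table else np.full(len(table), np.nan)
    return signal, control, GroundTruth(config=config, p_lick=p_lick, injected_amplitude=injected)


def default_pixel_masks(pixel_grid: tuple[int, int]) -> AreaMaskSet:
    """Quadrant block masks for the BC-like and RL-like pixel regions."""
    h, w = pixel_grid
    bc = np.zeros((h, w), dtype=bool)
    rl = np.zeros((h, w), dtype=bool)
    bc[h // 2 :, : w // 2] = True
    rl[: h // 2, w // 2 :] = True
    return AreaMaskSet({"BC": bc, "RL": rl})


def simulate_pixel_tensor(table: pd.DataFrame, config: SynthConfig) -> SessionTensor:
    """Pixel-resolved tensor: area signals painted into block masks plus noise."""
    if config.pixel_grid is None:
        raise ValueError("config.pixel_grid is not set")
    h, w = config.pixel_grid
    clean = _clean_area_signal(table, config)
    masks = default_pixel_masks(config.pixel_grid)
    vals = np.zeros((clean.shape[0], clean.shape[1], h, w))
    vals[:, :, masks.masks["BC"]] = clean[:, :, 0][:, :, None]
    vals[:, :, masks.masks["RL"]] = clean[:, :, 1][:, :, None]
    vals += config.rng(_STREAM_PIXEL).standard_normal(vals.shape) * config.noise_sd
    return SessionTensor(
        values=vals, time_s=config.time_axis(), frame_rate=config.frame_rate, channel_kind="pixel"
    )


def simulate_movement(table: pd.DataFrame, config: SynthConfig):
    """Simulate body-metric (30 Hz) and whisker-angle (50 Hz) traces.

    All trials are drawn from one distribution regardless of history: a
    baseline body-movement level with a stim-locked bump identical across
    trials, and whisking as a sinusoid with random amplitude, frequency and
    phase per trial.  Any history difference the analysis finds here is a
    false positive by construction.
    """
    from .movement import BODY_RATE_HZ, WHISKER_RATE_HZ, MovementBundle

    rng = config.rng(_STREAM_MOVE)
    t0, t1 = config.trial_window
    n = len(table)
    bt = t0 + np.arange(int(round((t1 - t0) * BODY_RATE_HZ))) / BODY_RATE_HZ
    wt = t0 + np.arange(int(round((t1 - t0) * WHISKER_RATE_HZ))) / WHISKER_RATE_HZ
    bump = 0.25 * np.exp(-(bt**2) / (2 * 0.15**2))
    body = 0.8 + bump[None, :] + 0.1 * rng.standard_normal((n, bt.size))
    body = np.clip(body, 0.0, 2.0)
    amp = rng.uniform(5.0, 15.0, size=n)
    freq = rng.uniform(8.0, 12.0, size=n)
    phase = rng.uniform(0, 2 * np.pi, size=n)
    whisker = amp[:, None] * np.sin(
        2 * np.pi * freq[:, None] * wt[None, :] + phase[:, None]
    ) + 0.5 * rng.standard_normal((n, wt.size))
    return MovementBundle(
        body=body, body_time_s=bt, whisker_angle=whisker, whisker_time_s=wt
    )


_CSV_COLUMNS = ["trial_index", "session_id", "texture", "licked", "outcome", "t_texture_stop_s"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def make_fixture(config: SynthConfig, out_dir) -> dict:
    """Write a complete synthetic session to disk; returns the manifest.

    Files: ``trials.csv``, ``dff.h5`` (signal, optional pixels), ``control.h5``
    (contamination-only control channel; written even when zero so the
    correction path is always exercised), ``movement.h5``,
    ``ground_truth.json``, plus ``manifest.json`` listing each file with its
    SHA-256 checksum.  Re-running with the same config is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = simulate_behavior(config)
    signal, control, truth = simulate_session_tensor(table, config)
    bundle = simulate_movement(table, config)

    files = {}
    p = out / "trials.csv"
    table[_CSV_COLUMNS].to_csv(p, index=False)
    files["trials"] = p

    p = out / "dff.h5"
    with h5py.File(p, "w") as f:
        f.create_dataset("dff", data=signal.values)
        f.create_dataset("time_s", data=signal.time_s)
        f.attrs["frame_rate_hz"] = signal.frame_rate
        f.attrs["t_zero"] = "texture_stop"
        f.attrs["channel_names"] = list(signal.channel_names)
        if config.pixel_grid is not None:
            f.create_dataset("dff_pixels", data=simulate_pixel_tensor(table, config).values)
    files["dff"] = p

    p = out / "control.h5"
    with h5py.File(p, "w") as f:
        vals = control.values if control is not None else np.zeros_like(signal.values)
        f.create_dataset("control", data=vals)
        f.create_dataset("time_s", data=signal.time_s)
        f.attrs["frame_rate_hz"] = signal.frame_rate
    files["control"] = p

    p = out / "movement.h5"
    with h5py.File(p, "w") as f:
        f.create_dataset("body", data=bundle.body)
        f.create_dataset("body_time_s", data=bundle.body_time_s)
        f.create_dataset("whisker_angle", data=bundle.whisker_angle)
        f.create_dataset("whisker_time_s", data=bundle.whisker_time_s)
    files["movement"] = p

    p = out / "ground_truth.json"
    with open(p, "w") as f:
        json.dump(truth.as_dict(), f, indent=1, default=str)
    files["ground_truth"] = p

    manifest = {
        "files": {k: {"path": v.name, "sha256": _sha256(v)} for k, v in files.items()},
        "n_trials": config.n_trials,
        "seed": config.seed,
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest
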