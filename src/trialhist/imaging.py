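"""Event-aligned fluorescence tensors: normalization, control-channel
correction, area extraction, and trial-time window averaging.

A :class:`SessionTensor` holds trials x frames x channels values at a fixed
frame rate, with the time axis in seconds relative to texture stop (t = 0).
Channels are either named cortical areas or pixels (then the value array is
trials x frames x H x W).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "SessionTensor",
    "WindowDef",
    "PRE_WINDOW",
    "STIM_WINDOW",
    "AreaMaskSet",
    "frame_zero_normalize",
    "correct_control_channel",
    "roi_timecourse",
    "window_average",
    "save_tensor",
    "load_tensor",
]


@dataclass
class WindowDef:
    """Half-open trial-time window [start_s, stop_s) relative to texture stop."""

    name: str
    start_s: float
    stop_s: float

    def __post_init__(self):
        if not self.start_s < self.stop_s:
            raise ValueError(f"window {self.name}: start {self.start_s} >= stop {self.stop_s}")

    def frame_mask(self, time_s: np.ndarray) -> np.ndarray:
        return (time_s >= self.start_s) & (time_s < self.stop_s)


#: Texture approaching, mostly before first whisker touch.
PRE_WINDOW = WindowDef("pre", -1.0, -0.6)
#: Texture in touch with the whiskers, around texture stop.
STIM_WINDOW = WindowDef("stim", -0.2, 0.2)


@dataclass
class SessionTensor:
    """Event-aligned normalized fluorescence (dF/F), trials x frames x channels."""

    values: np.ndarray
    time_s: np.ndarray
    frame_rate: float
    channel_kind: str = "area"  # "area" | "pixel"
    channel_names: tuple = ()
    invalid_trials: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.channel_kind not in ("area", "pixel"):
            raise ValueError(f"channel_kind must be 'area' or 'pixel', got {self.channel_kind!r}")
        expected_ndim = 3 if self.channel_kind == "area" else 4
        if self.values.ndim != expected_ndim:
            raise ValueError(
                f"{self.channel_kind} tensor must be {expected_ndim}-D, got {self.values.ndim}-D"
            )
        if self.values.shape[1] != self.time_s.size:
            raise ValueError("frame axis does not match time_s length")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if not (self.time_s[0] <= 0.0 <= self.time_s[-1]):
            raise ValueError("time axis must span t=0 (texture stop)")
        if self.invalid_trials is None:
            self.invalid_trials = np.zeros(self.values.shape[0], dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Trials x frames values of one named area channel."""
        if self.channel_kind != "area":
            raise ValueError("channel() requires an area tensor")
        try:
            j = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channel_names}") from None
        return self.values[:, :, j]


@dataclass
class AreaMaskSet:
    """Named binary masks over an H x W pixel grid."""

    masks: dict

    def __post_init__(self):
        if not self.masks:
            raise ValueError("mask set is empty")
        shapes = {np.asarray(m).shape for m in self.masks.values()}
        if len(shapes) != 1:
            raise ValueError(f"masks have inconsistent shapes: {shapes}")
        self.masks = {k: np.asarray(m, dtype=bool) for k, m in self.masks.items()}
        for name, m in self.masks.items():
            if not m.any():
                raise ValueError(f"mask {name!r} is empty")

    def names(self) -> tuple:
        return tuple(self.masks)


def frame_zero_normalize(
    raw: np.ndarray,
    time_s: np.ndarray,
    frame_rate: float,
    baseline_frames: int = 20,
    channel_kind: str = "area",
) -> SessionTensor:
    """Per-trial, per-channel baseline normalization ("frame-zero division").

    Each trial and channel is divided by the mean of its first
    ``baseline_frames`` frames (the frames just before the stimulus cue) and
    1 is subtracted, giving dF/F with a ~0 baseline.  Trials with a
    non-positive baseline mean are flagged invalid (NaN), not dropped.
    """
    raw = np.asarray(raw, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    if baseline_frames < 1 or baseline_frames > raw.shape[1]:
        raise ValueError(f"baseline_frames={baseline_frames} outside trial window")
    base = raw[:, :baseline_frames].mean(axis=1, keepdims=True)
    invalid = np.any(base.reshape(base.shape[0], -1) <= 0, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = raw / base - 1.0
    out[invalid] = np.nan
    return SessionTensor(
        values=out,
        time_s=time_s,
        frame_rate=frame_rate,
        channel_kind=channel_kind,
        invalid_trials=invalid,
    )


def correct_control_channel(
    signal: SessionTensor, control: SessionTensor, atol: float = 1e-9
) -> SessionTensor:
    """Subtract the calcium-insensitive control channel from the signal.

    Both tensors must already be frame-zero normalized.  If the control was
    acquired interleaved on a shifted time grid it is linearly interpolated
    onto the signal grid first.  The subtraction cancels any additive
    contamination (hemodynamic, photometric) common to both wavelengths.
    """
    if signal.values.shape[0] != control.values.shape[0]:
        raise ValueError("signal and control differ in trial count")
    ctrl_vals = control.values
    if control.time_s.shape != signal.time_s.shape or not np.allclose(
        control.time_s, signal.time_s, atol=atol
    ):
        if signal.time_s[0] < control.time_s[0] - atol or signal.time_s[-1] > control.time_s[-1] + atol:
            raise ValueError("control grid does not cover the signal grid; cannot resample")
        flat = ctrl_vals.reshape(ctrl_vals.shape[0], ctrl_vals.shape[1], -1)
        res = np.empty((flat.shape[0], signal.time_s.size, flat.shape[2]))
        for k in range(flat.shape[2]):
            for i in range(flat.shape[0]):
                res[i, :, k] = np.interp(signal.time_s, control.time_s, flat[i, :, k])
        ctrl_vals = res.reshape(signal.values.shape)
    if ctrl_vals.shape != signal.values.shape:
        raise ValueError(
            f"shape mismatch after resampling: {ctrl_vals.shape} vs {signal.values.shape}"
        )
    return replace(
        signal,
        values=signal.values - ctrl_vals,
        invalid_trials=signal.invalid_trials | control.invalid_trials,
    )


def roi_timecourse(pixel_tensor: SessionTensor, masks: AreaMaskSet) -> SessionTensor:
    """Collapse a pixel tensor to named-area traces by unweighted mask means."""
    if pixel_tensor.channel_kind != "pixel":
        raise ValueError("roi_timecourse requires a pixel tensor")
    h, w = pixel_tensor.values.shape[2:]
    names = masks.names()
    out = np.empty((pixel_tensor.n_trials, pixel_tensor.time_s.size, len(names)))
    for j, name in enumerate(names):
        m = masks.masks[name]
        if m.shape != (h, w):
            raise ValueError(f"mask {name!r} shape {m.shape} != grid {(h, w)}")
        out[:, :, j] = pixel_tensor.values[:, :, m].mean(axis=2)
    return replace(
        pixel_tensor, values=out, channel_kind="area", channel_names=names
    )


def window_average(tensor: SessionTensor, window: WindowDef) -> np.ndarray:
    """Mean over the frames falling in ``window``, per trial and channel.

    Returns trials x channels (or trials x H x W for a pixel tensor).
    """
    mask = window.frame_mask(tensor.time_s)
    if not mask.any():
        raise ValueError(
            f"window {window.name} [{window.start_s}, {window.stop_s}) contains no frames"
        )
    return tensor.values[:, mask].mean(axis=1)


def save_tensor(path, signal: SessionTensor, control: SessionTensor | None = None,
                pixel: SessionTensor | None = None) -> None:
    """Write tensors to the HDF5 session layout (/dff, /control, /dff_pixels, /time_s)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("dff", data=signal.values)
        f.create_dataset("time_s", data=signal.time_s)
        f.attrs["frame_rate_hz"] = signal.frame_rate
        f.attrs["t_zero"] = "texture_stop"
        f.attrs["channel_names"] = [str(n) for n in signal.channel_names]
        if control is not None:
            f.create_dataset("control", data=control.values)
        if pixel is not None:
            f.create_dataset("dff_pixels", data=pixel.values)


def load_tensor(path) -> dict:
    """Read the HDF5 session layout back into SessionTensor objects."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        time_s = f["time_s"][()]
        rate = float(f.attrs["frame_rate_hz"])
        names = tuple(str(n) for n in f.attrs.get("channel_names", ()))
        out["signal"] = SessionTensor(f["dff"][()], time_s, rate, "area", names)
        if "control" in f:
            out["control"] = SessionTensor(f["control"][()], time_s, rate, "area", names)
        if "dff_pixels" in f:
            out["pixel"] = SessionTensor(f["dff_pixels"][()], time_s, rate, "pixel")
    return out
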