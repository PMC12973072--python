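"""Trail rendering: gain/offset enhancement, time-coloring, fades, and
pixel-wise maximum projection.

Given a stack of average-subtracted frames, a trail image is built by

1. enhancing each frame: ``max(0, gain * v - offset)`` clipped at 1,
   which boosts contrast and zeroes low-amplitude noise;
2. weighting each frame by a fade ramp so the oldest portion of the
   window gradually disappears while the newest enters at full strength;
3. selecting, per pixel, the frame with the largest weighted enhanced
   intensity (ties broken toward the later frame, emphasizing recent
   behavior) and coloring that value by the winning frame's normalized
   acquisition time through a colormap.

A still uses the full recording as one window with u spanning the whole
recording; a video applies the same projection inside a trailing
temporal window slid across the recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from wormviz.colormaps import ColorMap, builtin, evaluate_many
from wormviz.video_io import FrameStack, RGBFrame


@dataclass
class TrailParams:
    """Rendering knobs for trail stills and videos.

    window_s
        Trailing window length in seconds, or ``"full"`` for a still
        over the entire recording.
    fade_fraction
        Fraction (0–0.5) of the window over which the oldest frames ramp
        linearly from invisible to full weight.
    gain, offset
        Contrast gain and noise-floor offset of the enhancement step.
    colormap
        Time-to-color encoding.
    stride
        Emit one output frame per ``stride`` input frames (video mode).
    time_norm
        ``"window"``: color by position within each window (recency);
        ``"global"``: color by absolute position in the recording.
    """

    window_s: float | str = 20.0
    fade_fraction: float = 0.2
    gain: float = 10.0
    offset: float = 0.05
    colormap: ColorMap = field(default_factory=lambda: builtin("blue_red"))
    stride: int = 1
    time_norm: str = "window"

    def __post_init__(self) -> None:
        if self.window_s != "full" and not float(self.window_s) > 0:
            raise ValueError(f"window_s must be positive or 'full', got {self.window_s}")
        if not 0.0 <= self.fade_fraction <= 0.5:
            raise ValueError(f"fade_fraction must lie in [0, 0.5], got {self.fade_fraction}")
        if not self.gain > 0:
            raise ValueError(f"gain must be positive, got {self.gain}")
        if not 0.0 <= self.offset < 1.0:
            raise ValueError(f"offset must lie in [0, 1), got {self.offset}")
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")
        if self.time_norm not in ("window", "global"):
            raise ValueError(f"time_norm must be 'window' or 'global', got {self.time_norm}")


@dataclass
class TrailFrame:
    """One rendered trail image and the temporal window it covers."""

    image: RGBFrame
    t_end: float
    window: tuple[float, float]


def enhance(sub_frame: np.ndarray, gain: float, offset: float) -> np.ndarray:
    """Contrast gain + noise-floor offset: ``clip(gain*v - offset, 0, 1)``.

    Pixels with ``gain*v <= offset`` become exactly 0.
    """
    if not gain > 0:
        raise ValueError(f"gain must be positive, got {gain}")
    if not 0.0 <= offset < 1.0:
        raise ValueError(f"offset must lie in [0, 1), got {offset}")
    return np.clip(gain * np.asarray(sub_frame) - offset, 0.0, 1.0)


def _fade_ramp_len(n: int, fade_fraction: float) -> int:
    m = int(np.floor(fade_fraction * n + 0.5))  # round half up
    return min(m, n - 1)  # the newest frame is never faded


def fade_weight(i: int, n: int, fade_fraction: float) -> float:
    """Weight of frame ``i`` (0 = oldest) in a window of ``n`` frames.

    Ramps linearly 0→1 over the oldest ``round(fade_fraction * n)``
    frames and is 1 elsewhere, so old track segments vanish gradually
    across successive output frames while the newest frame always enters
    at full strength.
    """
    if not 0 <= i < n:
        raise ValueError(f"frame index {i} outside window of {n} frames")
    if not 0.0 <= fade_fraction <= 0.5:
        raise ValueError(f"fade_fraction must lie in [0, 0.5], got {fade_fraction}")
    m = _fade_ramp_len(n, fade_fraction)
    if m >= 1 and i < m:
        return i / m
    return 1.0


def _fade_weights(n: int, fade_fraction: float) -> np.ndarray:
    m = _fade_ramp_len(n, fade_fraction)
    w = np.ones(n)
    if m >= 1:
        w[:m] = np.arange(m) / m
    return w


def colorize(
    enh_frame: np.ndarray, u: float, cmap: ColorMap, weight: float = 1.0
) -> RGBFrame:
    """Multiply an enhanced frame by the color of time u and a fade weight."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"weight must lie in [0, 1], got {weight}")
    rgb = evaluate_many(cmap, np.array([u]))[0]
    return RGBFrame(np.asarray(enh_frame)[:, :, None] * rgb[None, None, :] * weight)


def project_window(
    sub_stack: FrameStack,
    frame_indices: range,
    params: TrailParams,
    u_values: np.ndarray | None = None,
) -> TrailFrame:
    """Collapse a contiguous frame range into one time-colored trail image.

    Per pixel, the frame with maximal weighted enhanced intensity wins
    (ties to the later frame) and contributes its enhanced value times
    its fade weight times the color of its normalized time.  ``u_values``
    overrides the default window-relative normalization (used for global
    time coloring).
    """
    idx = np.asarray(frame_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty frame range")
    n = idx.size
    enh = enhance(sub_stack.frames[idx], params.gain, params.offset)
    w = _fade_weights(n, params.fade_fraction)
    s = enh * w[:, None, None]

    # argmax on the reversed stack returns the FIRST maximal frame there,
    # i.e. the LATEST in original order — the tie-break toward recency.
    winner = n - 1 - np.argmax(s[::-1], axis=0)

    if u_values is None:
        u = idx.astype(float) - idx[0]
        u = u / u[-1] if n > 1 else np.ones(1)
    else:
        u = np.asarray(u_values, dtype=np.float64)
        if u.shape != (n,):
            raise ValueError(f"u_values must have shape ({n},), got {u.shape}")
    colors = evaluate_many(params.colormap, u)  # (n, 3)

    val = np.take_along_axis(s, winner[None], axis=0)[0]  # enh * weight of winner
    img = val[:, :, None] * colors[winner]
    img[val == 0.0] = 0.0  # all-zero pixels stay black regardless of colormap

    t = sub_stack.times[idx]
    return TrailFrame(
        image=RGBFrame(np.clip(img, 0.0, 1.0)),
        t_end=float(t[-1]),
        window=(float(t[0]), float(t[-1])),
    )


def render_still(stack: FrameStack, params: TrailParams | None = None) -> TrailFrame:
    """Trail still over the full recording; u spans start → end of recording."""
    if params is None:
        params = TrailParams(window_s="full", fade_fraction=0.0)
    n = stack.n_frames
    if n < 1:
        raise ValueError("empty stack")
    span = stack.times[-1] - stack.times[0]
    u = (stack.times - stack.times[0]) / span if span > 0 else np.ones(n)
    return project_window(stack, range(n), params, u_values=u)


def window_frame_count(window_s: float, fps: float) -> int:
    """Number of frames per window: ``round(window_s * fps)``, at least 1."""
    return max(1, int(np.floor(window_s * fps + 0.5)))


def render_video(stack: FrameStack, params: TrailParams) -> list[TrailFrame]:
    """Sliding-window trail video: one TrailFrame per stride-th input frame.

    Each output at input frame t projects the trailing window of
    ``round(window_s * fps)`` frames ending at t; windows are truncated
    (not padded) at the start of the recording.  A window longer than
    the recording falls back to a single full-recording projection with
    a warning.
    """
    if params.window_s == "full":
        raise ValueError("window_s='full' renders a still; use render_still")
    n_win = window_frame_count(float(params.window_s), stack.fps)
    total = stack.n_frames
    if n_win > total:
        warnings.warn(
            f"window of {n_win} frames exceeds recording length {total}; "
            "emitting a single full-recording trail frame",
            stacklevel=2,
        )
        full = replace(params, window_s="full")
        return [render_still(stack, full)]

    out: list[TrailFrame] = []
    for t in range(0, total, params.stride):
        lo = max(0, t - n_win + 1)
        rng = range(lo, t + 1)
        if params.time_norm == "global":
            span = stack.times[-1] - stack.times[0]
            u = (stack.times[np.asarray(rng)] - stack.times[0]) / span if span > 0 \
                else np.ones(len(rng))
            out.append(project_window(stack, rng, params, u_values=u))
        else:
            out.append(project_window(stack, rng, params))
    return out
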