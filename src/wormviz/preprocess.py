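"""Preprocessing: brightness/vignetting correction and average subtraction.

Two stages precede trail rendering:

1. Per-frame brightness normalization followed by division by a smooth
   multiplicative illumination estimate (the "vignette field"), obtained
   by heavily Gaussian-blurring the temporal average frame.  This evens
   out low-frequency shading from uneven illumination.
2. Average-frame subtraction: each frame is replaced by the pixel-wise
   absolute difference from the temporal mean image.  The absolute value
   makes the operation symmetric between brightfield recordings (dark
   worms on a bright lawn) and darkfield recordings (bright worms on a
   dark background): static pixels go to zero, moving worms light up.

All stages clip their output back into [0, 1] so the frame-stack
representation stays closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from wormviz.video_io import FrameStack

DEFAULT_EPSILON = 1e-3


@dataclass
class AverageFrame:
    """Temporal mean image of a stack."""

    pixels: np.ndarray = field(repr=False)
    n_frames: int = 0


@dataclass
class VignetteField:
    """Smooth multiplicative illumination estimate, spatial mean 1.

    ``field`` is the Gaussian-blurred average frame, floored at
    ``epsilon`` (to guard division in dark borders) and rescaled to unit
    spatial mean so correction preserves global brightness.
    """

    field: np.ndarray = field(repr=False)
    sigma_px: float = 0.0
    epsilon: float = DEFAULT_EPSILON


def default_sigma(shape: tuple[int, int]) -> float:
    """Default blur scale: 1/8 of the smaller frame dimension.

    The correction must only touch low spatial frequencies, far beyond
    the worm scale.
    """
    return min(shape) / 8.0


def normalize_brightness(stack: FrameStack, target: float | str = "auto") -> FrameStack:
    """Rescale each frame so its mean intensity equals a common target.

    With ``target="auto"`` the target is the grand mean of all per-frame
    means.  Output is clipped to [0, 1].
    """
    means = stack.frames.mean(axis=(1, 2))
    zero = np.flatnonzero(means <= 0)
    if zero.size:
        raise ValueError(
            f"frame {zero[0]} has zero mean intensity; cannot normalize an "
            "all-black frame"
        )
    t = float(means.mean()) if target == "auto" else float(target)
    scaled = stack.frames * (t / means)[:, None, None]
    return FrameStack(
        frames=np.clip(scaled, 0.0, 1.0),
        times=stack.times,
        fps=stack.fps,
        source_bit_depth=stack.source_bit_depth,
    )


def _temporal_mean(frames: np.ndarray) -> np.ndarray:
    # anchored at frame 0 so the mean of a static stack is bit-exact:
    # mean = f0 + mean(frames - f0), and frames - f0 is exactly zero there
    return frames[0] + (frames - frames[0]).mean(axis=0)


def compute_average_frame(stack: FrameStack) -> AverageFrame:
    """Pixel-wise arithmetic mean over time."""
    if stack.n_frames < 2:
        raise ValueError(f"need at least 2 frames to average, got {stack.n_frames}")
    return AverageFrame(pixels=_temporal_mean(stack.frames), n_frames=stack.n_frames)


def _blur_extrapolating(img: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian blur with antisymmetric (odd) reflection padding.

    Plain (even) reflection flattens the field's gradient at the frame
    edge, which biases the shading estimate as far as ~2 sigma into the
    frame.  Odd reflection extrapolates the local slope instead, so the
    blur of a linearly varying field is exact up to the boundary.
    """
    # pad is capped at half the frame so a very large sigma still averages
    # toward a uniform field instead of chasing the extrapolated slope
    pad = min(int(np.ceil(4 * sigma_px)), min(img.shape) // 2)
    if pad == 0:
        return gaussian_filter(img, sigma=sigma_px, mode="nearest")
    padded = np.pad(img, pad, mode="reflect", reflect_type="odd")
    return gaussian_filter(padded, sigma=sigma_px, mode="nearest")[pad:-pad, pad:-pad]


def estimate_vignette(
    avg: AverageFrame, sigma_px: float, epsilon: float = DEFAULT_EPSILON
) -> VignetteField:
    """Estimate the multiplicative shading field from the average frame.

    Gaussian blur with slope-extrapolating boundaries, floor at
    ``epsilon``, then rescale to unit spatial mean so the correction
    preserves global brightness.
    """
    if sigma_px <= 0:
        raise ValueError(f"sigma_px must be positive, got {sigma_px}")
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    blurred = _blur_extrapolating(avg.pixels, sigma_px)
    floored = np.maximum(blurred, epsilon)
    # avg in [0,1] implies mean(floored) <= 1 in practice, so dividing by
    # the mean keeps the floor intact; the second floor is a no-op then.
    normalized = np.maximum(floored / floored.mean(), epsilon)
    return VignetteField(field=normalized, sigma_px=sigma_px, epsilon=epsilon)


def correct_vignette(stack: FrameStack, vignette: VignetteField) -> FrameStack:
    """Divide every frame by the vignette field; clip to [0, 1]."""
    if vignette.field.shape != stack.shape:
        raise ValueError(
            f"vignette shape {vignette.field.shape} does not match frame "
            f"shape {stack.shape}"
        )
    corrected = np.clip(stack.frames / vignette.field[None], 0.0, 1.0)
    return FrameStack(
        frames=corrected,
        times=stack.times,
        fps=stack.fps,
        source_bit_depth=stack.source_bit_depth,
    )


def average_subtract(stack: FrameStack) -> FrameStack:
    """Absolute difference of every frame from the stack's own mean.

    Isolates pixels that change intensity over the recording; a
    perfectly static scene maps to all-zero frames.  Invariant under
    global intensity inversion (``1 - I``), which is why both
    brightfield and darkfield recordings work.
    """
    if stack.n_frames < 2:
        raise ValueError(f"need at least 2 frames to subtract, got {stack.n_frames}")
    mean = _temporal_mean(stack.frames)
    sub = np.abs(stack.frames - mean[None])
    return FrameStack(
        frames=np.clip(sub, 0.0, 1.0),
        times=stack.times,
        fps=stack.fps,
        source_bit_depth=stack.source_bit_depth,
    )
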