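"""Video and image-sequence I/O.

The pipeline works on :class:`FrameStack` objects: grayscale frame
sequences with intensities normalized to the real interval [0, 1]
regardless of the source bit depth, so that downstream gain/offset
parameters are bit-depth independent.

Lossless output goes to multi-page ImageJ-style TIFF (which carries the
frame rate as metadata) or to numbered PNG sequences; both round-trip
8-bit pixel data exactly.  Containers that need an ffmpeg backend are
attempted through imageio and fail with a clear message when no backend
is available.
"""

from __future__ import annotations

import glob
import os
import re
from dataclasses import dataclass, field
from typing import Sequence

import imageio.v2 as iio
import numpy as np
import tifffile

# ITU-R BT.601 luminance weights, the de-facto video standard.
_LUMA = np.array([0.299, 0.587, 0.114])

_TIFF_EXTS = {".tif", ".tiff"}
_IMAGE_EXTS = {".png", ".bmp"} | _TIFF_EXTS


class VideoIOError(RuntimeError):
    """Raised when a video or image file cannot be read or written."""


@dataclass
class FrameStack:
    """Ordered grayscale frame sequence with acquisition timestamps.

    Parameters
    ----------
    frames
        3-D float array indexed ``(time, row, col)``, values in [0, 1].
    times
        Per-frame acquisition time in seconds, strictly increasing.
    fps
        Nominal frame rate (frames per second), > 0.
    source_bit_depth
        Bit depth of the source data (8 or 16).
    """

    frames: np.ndarray
    times: np.ndarray
    fps: float
    source_bit_depth: int = 8

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be 3-D (time, row, col); got shape {self.frames.shape}"
            )
        if len(self.times) != self.frames.shape[0]:
            raise ValueError(
                f"{self.frames.shape[0]} frames but {len(self.times)} timestamps"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if self.frames.size and (self.frames.min() < 0 or self.frames.max() > 1):
            raise ValueError("frame intensities must lie in [0, 1]")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.source_bit_depth not in (8, 16):
            raise ValueError(f"source_bit_depth must be 8 or 16, got {self.source_bit_depth}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (rows, cols)."""
        return self.frames.shape[1:]

    @classmethod
    def from_frames(cls, frames: np.ndarray, fps: float, source_bit_depth: int = 8) -> "FrameStack":
        """Build a stack with synthesized times ``times[i] = i / fps``."""
        frames = np.asarray(frames, dtype=np.float64)
        times = np.arange(frames.shape[0]) / fps
        return cls(frames=frames, times=times, fps=fps, source_bit_depth=source_bit_depth)


@dataclass
class RGBFrame:
    """A single rendered RGB image, channels last, values in [0, 1]."""

    pixels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"RGBFrame needs shape (row, col, 3); got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("RGBFrame values must be finite")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("RGBFrame values must lie in [0, 1]")

    def to_uint8(self) -> np.ndarray:
        return np.round(self.pixels * 255.0).astype(np.uint8)


def _normalize(arr: np.ndarray) -> tuple[np.ndarray, int]:
    """Map an integer/float image array onto [0, 1]; return (array, bit depth)."""
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0, 8
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0, 16
    if np.issubdtype(arr.dtype, np.floating):
        out = arr.astype(np.float64)
        if out.size and out.max() > 1.0:  # float TIFFs sometimes store 0..255
            out = out / out.max()
        return np.clip(out, 0.0, 1.0), 8
    raise VideoIOError(f"unsupported pixel dtype {arr.dtype}")


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        return frame[:, :, :3] @ _LUMA
    raise VideoIOError(f"cannot interpret frame of shape {frame.shape} as image")


def _tiff_fps(path: str) -> float | None:
    with tifffile.TiffFile(path) as tf:
        meta = tf.imagej_metadata or {}
        if "fps" in meta:
            return float(meta["fps"])
        if "finterval" in meta and meta["finterval"] > 0:
            return 1.0 / float(meta["finterval"])
    return None


def load_video(path: str, as_gray: bool = True, fps: float | None = None) -> FrameStack:
    """Load a video file (or multi-page TIFF) into a :class:`FrameStack`.

    Intensities are rescaled to [0, 1] from the source bit depth; color
    frames are reduced to BT.601 luminance when ``as_gray`` is set.  The
    frame rate is taken from the ``fps`` argument if given, else from
    container metadata; if neither is available an error is raised.
    """
    if not os.path.exists(path):
        raise VideoIOError(f"video file not found: {path}")
    ext = os.path.splitext(path)[1].lower()
    meta_fps: float | None = None
    try:
        if ext in _TIFF_EXTS:
            raw = tifffile.imread(path)
            meta_fps = _tiff_fps(path)
            if raw.ndim == 2:
                raw = raw[None]
            frames_raw = list(raw)
        else:
            reader = iio.get_reader(path)
            try:
                meta = reader.get_meta_data()
                if meta.get("fps"):
                    meta_fps = float(meta["fps"])
                frames_raw = [np.asarray(f) for f in reader]
            finally:
                reader.close()
    except VideoIOError:
        raise
    except Exception as exc:  # decode failure
        raise VideoIOError(f"could not decode {path}: {exc}") from exc

    if len(frames_raw) < 2:
        raise VideoIOError(
            f"{path} holds {len(frames_raw)} frame(s); the pipeline needs at "
            "least 2 frames to form an average"
        )
    eff_fps = fps if fps is not None else meta_fps
    if eff_fps is None:
        raise VideoIOError(
            f"{path} carries no frame-rate metadata; pass fps= explicitly"
        )

    frames = []
    depth = 8
    for f in frames_raw:
        norm, depth = _normalize(f)
        if not as_gray and norm.ndim == 3:
            raise VideoIOError(
                f"{path} holds color frames; FrameStack is grayscale — pass "
                "as_gray=True or use read_rgb_video for raw RGB access"
            )
        frames.append(_to_gray(norm))
    stack = np.stack(frames)
    return FrameStack.from_frames(stack, fps=float(eff_fps), source_bit_depth=depth)


def read_rgb_video(path: str) -> tuple[list[RGBFrame], float | None]:
    """Read a video's frames as RGB without luminance reduction.

    Returns the frames and the container frame rate (None if absent).
    Grayscale content is replicated across the three channels.
    """
    if not os.path.exists(path):
        raise VideoIOError(f"video file not found: {path}")
    ext = os.path.splitext(path)[1].lower()
    fps: float | None = None
    if ext in _TIFF_EXTS:
        raw = tifffile.imread(path)
        fps = _tiff_fps(path)
        if raw.ndim == 2:
            raw = raw[None]
        elif raw.ndim == 3 and raw.shape[-1] == 3:
            raw = raw[None]
        frames_raw = list(raw)
    else:
        reader = iio.get_reader(path)
        try:
            meta = reader.get_meta_data()
            if meta.get("fps"):
                fps = float(meta["fps"])
            frames_raw = [np.asarray(f) for f in reader]
        finally:
            reader.close()
    out = []
    for f in frames_raw:
        norm, _ = _normalize(f)
        if norm.ndim == 2:
            norm = np.repeat(norm[:, :, None], 3, axis=2)
        out.append(RGBFrame(norm[:, :, :3]))
    return out, fps


_NUM_RE = re.compile(r"(\d+)")


def _natural_key(name: str) -> list:
    return [int(tok) if tok.isdigit() else tok for tok in _NUM_RE.split(name)]


def load_image_sequence(pattern: str, fps: float, as_gray: bool = True) -> FrameStack:
    """Load a numbered image sequence (glob pattern) as a :class:`FrameStack`.

    Files are ordered by natural sort of their names (``f2`` before
    ``f10``); times are synthesized as ``index / fps``.
    """
    paths = sorted(glob.glob(pattern), key=lambda p: _natural_key(os.path.basename(p)))
    if len(paths) < 2:
        raise VideoIOError(
            f"pattern {pattern!r} matched {len(paths)} file(s); need at least 2"
        )
    frames = []
    depth = 8
    for p in paths:
        raw = iio.imread(p)
        norm, depth = _normalize(raw)
        g = _to_gray(norm) if as_gray else norm
        if frames and g.shape != frames[0].shape:
            raise VideoIOError(
                f"frame shape mismatch: {p} is {g.shape}, expected {frames[0].shape}"
            )
        frames.append(g)
    return FrameStack.from_frames(np.stack(frames), fps=fps, source_bit_depth=depth)


def _as_uint8_frames(frames: Sequence[RGBFrame | np.ndarray]) -> list[np.ndarray]:
    out = []
    for f in frames:
        if isinstance(f, RGBFrame):
            out.append(f.to_uint8())
        else:
            arr = np.asarray(f, dtype=np.float64)
            out.append(RGBFrame(arr).to_uint8())
    shapes = {a.shape for a in out}
    if len(shapes) > 1:
        raise VideoIOError(f"frames have mixed shapes: {sorted(shapes)}")
    return out


def write_video(
    frames: Sequence[RGBFrame | np.ndarray],
    path: str,
    fps: float,
    lossless: bool = True,
) -> None:
    """Write RGB frames to a video container.

    ``.tif/.tiff`` → multi-page ImageJ TIFF with fps metadata (lossless).
    A path containing ``%`` or pointing at a directory → PNG sequence
    (lossless).  Anything else goes through imageio, which requires an
    ffmpeg backend and is refused for ``lossless=True``.
    """
    if len(frames) == 0:
        raise VideoIOError("cannot write a video with zero frames")
    data = _as_uint8_frames(frames)
    ext = os.path.splitext(path)[1].lower()

    if ext in _TIFF_EXTS:
        tifffile.imwrite(
            path,
            np.stack(data),
            imagej=True,
            metadata={"fps": float(fps), "axes": "TYXS"},
        )
        return
    if "%" in path or ext == "":
        os.makedirs(path if ext == "" else os.path.dirname(path) or ".", exist_ok=True)
        template = os.path.join(path, "frame_%06d.png") if ext == "" else path
        for i, frame in enumerate(data):
            iio.imwrite(template % i, frame)
        return
    if lossless:
        raise VideoIOError(
            f"no lossless codec available for {ext!r}; write a .tif stack or a "
            "PNG sequence (directory / %-template path) instead"
        )
    try:
        iio.mimwrite(path, data, fps=fps)
    except Exception as exc:
        raise VideoIOError(
            f"could not encode {path} (is an ffmpeg backend installed?): {exc}"
        ) from exc


def write_image(frame: RGBFrame | np.ndarray, path: str) -> None:
    """Write a single RGB frame as an 8-bit PNG/TIFF still (lossless)."""
    if not isinstance(frame, RGBFrame):
        frame = RGBFrame(np.asarray(frame, dtype=np.float64))
    try:
        iio.imwrite(path, frame.to_uint8())
    except Exception as exc:
        raise VideoIOError(f"could not write image {path}: {exc}") from exc


def check_acquisition(
    stack: FrameStack, worm_length_px: float, max_speed_px_per_s: float
) -> list[str]:
    """Advisory check that frames are frequent enough for continuous trails.

    Warns when a worm moving at ``max_speed_px_per_s`` would travel more
    than one body length between successive frames.  Never blocks.
    """
    if worm_length_px <= 0 or max_speed_px_per_s <= 0:
        raise ValueError("worm_length_px and max_speed_px_per_s must be positive")
    warnings: list[str] = []
    if stack.n_frames > 1:
        interval = float(np.median(np.diff(stack.times)))
    else:
        interval = 1.0 / stack.fps
    displacement = max_speed_px_per_s * interval
    if displacement > worm_length_px:
        warnings.append(
            f"worms may travel {displacement:.1f} px between frames "
            f"(> body length {worm_length_px:.1f} px); trails may be "
            "discontinuous — acquire faster"
        )
    return warnings
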