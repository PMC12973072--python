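"""Seedable simulation of worm-like locomotion recordings with ground truth.

The generator emulates the features of a plate-scale behavioral
recording that the pipeline cares about: several worm-sized blobs
(bright on dark for darkfield, dark on bright for brightfield) moving in
a two-state roam/dwell random walk, a static low-frequency radial
vignette, a constant background level, and additive sensor noise.
Per-frame ground-truth centroids and behavioral states are returned
alongside the rendered frames, so every pipeline stage can be tested
without external data.

Motion model: each worm carries a heading that diffuses as a wrapped
Gaussian random walk (wider in dwell, where movement is slow and
disordered) and a two-state Markov chain toggling between roaming (fast,
relatively straight movement) and dwelling (slow, localized movement),
with a symmetric per-second switch probability.  Positions reflect at
the frame boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from wormviz.video_io import FrameStack

ROAM, DWELL = "roam", "dwell"


@dataclass
class SimScene:
    """Synthetic-world description.

    Defaults describe a desk-scale plate assay: 1 frame/s acquisition (the
    recommended rate for behavioral assays), a 256 px plate image at
    roughly 4 px per adult-worm width, five animals, darkfield polarity,
    roaming at 5 px/s vs dwelling at 1 px/s with a 5%/s state switch, a
    30% radial vignette and mild sensor noise.
    """

    shape: tuple[int, int] = (256, 256)
    fps: float = 1.0
    duration_s: float = 300.0
    n_worms: int = 5
    worm_sigma_px: float = 2.0
    worm_peak: float = 0.5
    polarity: str = "darkfield"  # darkfield: bright worms | brightfield: dark worms
    roam_speed_px_s: float = 5.0
    dwell_speed_px_s: float = 1.0
    switch_prob_per_s: float = 0.05
    turn_sigma_rad: float = 0.3
    vignette_strength: float = 0.3
    noise_sigma: float = 0.01
    background_level: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.polarity not in ("darkfield", "brightfield"):
            raise ValueError(f"polarity must be darkfield|brightfield, got {self.polarity!r}")
        if self.dwell_speed_px_s > self.roam_speed_px_s:
            raise ValueError("dwell_speed_px_s must not exceed roam_speed_px_s")
        if not 0.0 <= self.switch_prob_per_s <= 1.0:
            raise ValueError("switch_prob_per_s must lie in [0, 1]")
        if not 0.0 <= self.vignette_strength < 1.0:
            raise ValueError("vignette_strength must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.background_level <= 1.0:
            raise ValueError("background_level must lie in [0, 1]")
        if not 0.0 < self.worm_peak <= 1.0:
            raise ValueError("worm_peak must lie in (0, 1]")
        if self.n_worms < 0:
            raise ValueError("n_worms must be >= 0")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration_s must be positive")

    @property
    def n_frames(self) -> int:
        return max(2, int(round(self.duration_s * self.fps)))


@dataclass
class GroundTruth:
    """Per-worm, per-frame centroids (row, col) and behavioral states."""

    centroids: np.ndarray = field(repr=False)  # (n_frames, n_worms, 2) float px
    states: np.ndarray = field(repr=False)  # (n_frames, n_worms) of "roam"/"dwell"

    @property
    def n_frames(self) -> int:
        return self.centroids.shape[0]

    @property
    def n_worms(self) -> int:
        return self.centroids.shape[1]

    def to_rows(self) -> list[tuple[int, int, float, float, str]]:
        """Flatten to (frame, worm_id, row, col, state) rows for CSV export."""
        rows = []
        for f in range(self.n_frames):
            for w in range(self.n_worms):
                r, c = self.centroids[f, w]
                rows.append((f, w, float(r), float(c), str(self.states[f, w])))
        return rows

    def write_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("frame,worm_id,row,col,state\n")
            for f, w, r, c, s in self.to_rows():
                fh.write(f"{f},{w},{r:.6f},{c:.6f},{s}\n")


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect a coordinate into [lo, hi] (handles multiple bounces)."""
    span = hi - lo
    if span <= 0:
        return lo
    y = (x - lo) % (2 * span)
    return lo + (y if y <= span else 2 * span - y)


def vignette_profile(shape: tuple[int, int], strength: float) -> np.ndarray:
    """Radial-quadratic shading field: ``1 - strength * (r / r_max)^2``.

    r is distance from the frame center, r_max the half-diagonal, so the
    field spans [1 - strength, 1].
    """
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(np.float64)
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    r2 = (rr - r0) ** 2 + (cc - c0) ** 2
    r_max2 = r0**2 + c0**2
    return 1.0 - strength * r2 / r_max2


def _render_blob(frame: np.ndarray, row: float, col: float, sigma: float, peak: float) -> None:
    """Add an isotropic Gaussian blob in place, cropped to a ±4σ patch."""
    rows, cols = frame.shape
    ext = int(np.ceil(4 * sigma))
    r_lo, r_hi = max(0, int(np.floor(row)) - ext), min(rows, int(np.ceil(row)) + ext + 1)
    c_lo, c_hi = max(0, int(np.floor(col)) - ext), min(cols, int(np.ceil(col)) + ext + 1)
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi].astype(np.float64)
    d2 = (rr - row) ** 2 + (cc - col) ** 2
    frame[r_lo:r_hi, c_lo:c_hi] += peak * np.exp(-d2 / (2 * sigma**2))


def simulate(scene: SimScene) -> tuple[FrameStack, GroundTruth]:
    """Render a synthetic locomotion recording with ground truth.

    Deterministic under a fixed ``scene.seed`` (bit-identical output).
    """
    rng = np.random.default_rng(scene.seed)
    rows, cols = scene.shape
    n_frames, n_worms = scene.n_frames, scene.n_worms

    # per-frame switch probability from the per-second rate
    p_frame = 1.0 - (1.0 - scene.switch_prob_per_s) ** (1.0 / scene.fps)
    speeds = {ROAM: scene.roam_speed_px_s / scene.fps, DWELL: scene.dwell_speed_px_s / scene.fps}
    turn_sigma = {ROAM: scene.turn_sigma_rad, DWELL: 4.0 * scene.turn_sigma_rad}

    margin = 2.0 * scene.worm_sigma_px
    pos = np.empty((n_worms, 2))
    pos[:, 0] = rng.uniform(margin, rows - 1 - margin, n_worms) if n_worms else 0
    pos[:, 1] = rng.uniform(margin, cols - 1 - margin, n_worms) if n_worms else 0
    heading = rng.uniform(0, 2 * np.pi, n_worms)
    state = np.where(rng.random(n_worms) < 0.5, ROAM, DWELL).astype(object)

    centroids = np.zeros((n_frames, n_worms, 2))
    states = np.empty((n_frames, n_worms), dtype=object)

    vignette = vignette_profile(scene.shape, scene.vignette_strength)
    sign = 1.0 if scene.polarity == "darkfield" else -1.0
    frames = np.empty((n_frames, rows, cols))

    for f in range(n_frames):
        if f > 0:
            for w in range(n_worms):
                if rng.random() < p_frame:
                    state[w] = DWELL if state[w] == ROAM else ROAM
                heading[w] += rng.normal(0.0, turn_sigma[state[w]])
                step = speeds[state[w]]
                pos[w, 0] = _reflect(pos[w, 0] + step * np.sin(heading[w]), 0.0, rows - 1.0)
                pos[w, 1] = _reflect(pos[w, 1] + step * np.cos(heading[w]), 0.0, cols - 1.0)
        centroids[f] = pos
        states[f] = state

        img = np.zeros((rows, cols))
        for w in range(n_worms):
            _render_blob(img, pos[w, 0], pos[w, 1], scene.worm_sigma_px, scene.worm_peak)
        frame = (scene.background_level + sign * img) * vignette
        if scene.noise_sigma > 0:
            frame = frame + rng.normal(0.0, scene.noise_sigma, frame.shape)
        frames[f] = np.clip(frame, 0.0, 1.0)

    stack = FrameStack.from_frames(frames, fps=scene.fps)
    return stack, GroundTruth(centroids=centroids, states=states)


def ideal_trail_mask(
    truth: GroundTruth, frame_range: range, radius_px: float
) -> np.ndarray:
    """Oracle mask: union of disks of ``radius_px`` around every centroid
    visited in ``frame_range``.  Shape must be supplied by the caller via
    the centroid coordinates' bounding frame; here the mask is sized to
    cover the largest centroid coordinate (callers normally pass the
    scene shape through :func:`ideal_trail_mask_shaped`).
    """
    shape = (
        int(np.ceil(truth.centroids[..., 0].max())) + 1 if truth.centroids.size else 1,
        int(np.ceil(truth.centroids[..., 1].max())) + 1 if truth.centroids.size else 1,
    )
    return ideal_trail_mask_shaped(truth, frame_range, radius_px, shape)


def ideal_trail_mask_shaped(
    truth: GroundTruth, frame_range: range, radius_px: float, shape: tuple[int, int]
) -> np.ndarray:
    """Union-of-disks trail oracle with an explicit output shape."""
    mask = np.zeros(shape, dtype=bool)
    idx = [f for f in frame_range if 0 <= f < truth.n_frames]
    if frame_range and len(idx) != len(frame_range):
        raise ValueError("frame_range extends outside the ground truth")
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    for f in idx:
        for w in range(truth.n_worms):
            r, c = truth.centroids[f, w]
            if radius_px < 1.0:
                mask[int(round(r)), int(round(c))] = True
            else:
                ext = int(np.ceil(radius_px)) + 1
                r_lo, r_hi = max(0, int(r) - ext), min(shape[0], int(r) + ext + 1)
                c_lo, c_hi = max(0, int(c) - ext), min(shape[1], int(c) + ext + 1)
                d2 = (rr[r_lo:r_hi, c_lo:c_hi] - r) ** 2 + (cc[r_lo:r_hi, c_lo:c_hi] - c) ** 2
                mask[r_lo:r_hi, c_lo:c_hi] |= d2 <= radius_px**2
    return mask
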