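"""Time-to-color encodings for trail rendering.

A :class:`ColorMap` maps normalized time u in [0, 1] to an RGB triple by
piecewise-linear interpolation between control points.  Interpolation is
done in linear RGB: the trail pixel is formed by multiplying an
intensity by the color, and linear RGB keeps that product interpretable.

Built-ins cover the common cases: sequential blue→red and cyan→magenta
gradients for progression through time, a diverging map with a neutral
white midpoint for pre/post-intervention recordings, and a constant
white map when no temporal encoding is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

RGB = tuple[float, float, float]


@dataclass(frozen=True)
class ColorMap:
    name: str
    control_points: tuple[tuple[float, RGB], ...]
    kind: str = "custom"  # sequential | diverging | custom


def _validate_points(points: Sequence[tuple[float, Sequence[float]]]) -> tuple:
    if len(points) < 2:
        raise ValueError("a colormap needs at least 2 control points")
    us = [float(u) for u, _ in points]
    if us[0] != 0.0:
        raise ValueError(f"first control point must be at u=0, got u={us[0]}")
    if us[-1] != 1.0:
        raise ValueError(f"last control point must be at u=1, got u={us[-1]}")
    for a, b in zip(us, us[1:]):
        if b <= a:
            raise ValueError(f"control point u values must strictly increase; {b} after {a}")
    cleaned = []
    for u, rgb in points:
        rgb = tuple(float(c) for c in rgb)
        if len(rgb) != 3:
            raise ValueError(f"control point at u={u} has {len(rgb)} channels, need 3")
        if any(not 0.0 <= c <= 1.0 for c in rgb):
            raise ValueError(f"control point at u={u} has rgb {rgb} outside [0, 1]")
        cleaned.append((float(u), rgb))
    return tuple(cleaned)


def from_control_points(
    points: Sequence[tuple[float, Sequence[float]]],
    name: str = "custom",
    kind: str = "custom",
) -> ColorMap:
    """Build a user-defined colormap from (u, rgb) control points."""
    return ColorMap(name=name, control_points=_validate_points(points), kind=kind)


_BUILTINS: dict[str, ColorMap] = {}


def _register(name: str, kind: str, points) -> None:
    _BUILTINS[name] = ColorMap(name, _validate_points(points), kind)


_register("blue_red", "sequential", [(0.0, (0, 0, 1)), (1.0, (1, 0, 0))])
_register("cyan_magenta", "sequential", [(0.0, (0, 1, 1)), (1.0, (1, 0, 1))])
_register(
    "blue_white_red",
    "diverging",
    [(0.0, (0, 0, 1)), (0.5, (1, 1, 1)), (1.0, (1, 0, 0))],
)
_register("constant_white", "sequential", [(0.0, (1, 1, 1)), (1.0, (1, 1, 1))])
_register("green_yellow_red", "sequential",
          [(0.0, (0, 0.8, 0)), (0.5, (1, 1, 0)), (1.0, (1, 0, 0))])


def available() -> list[str]:
    return sorted(_BUILTINS)


def builtin(name: str) -> ColorMap:
    """Look up a built-in colormap by name."""
    try:
        return _BUILTINS[name]
    except KeyError:
        raise KeyError(
            f"unknown colormap {name!r}; available: {', '.join(available())}"
        ) from None


def evaluate(cmap: ColorMap, u: float) -> np.ndarray:
    """Evaluate a colormap at normalized time u in [0, 1] → rgb array."""
    u = float(u)
    if not 0.0 <= u <= 1.0:
        raise ValueError(f"u must lie in [0, 1], got {u}")
    us = np.array([p[0] for p in cmap.control_points])
    rgbs = np.array([p[1] for p in cmap.control_points])
    return np.array([np.interp(u, us, rgbs[:, c]) for c in range(3)])


def evaluate_many(cmap: ColorMap, u: np.ndarray) -> np.ndarray:
    """Vectorized :func:`evaluate`: (n,) u values → (n, 3) rgb array."""
    u = np.asarray(u, dtype=np.float64)
    if u.size and (u.min() < 0 or u.max() > 1):
        raise ValueError("all u values must lie in [0, 1]")
    us = np.array([p[0] for p in cmap.control_points])
    rgbs = np.array([p[1] for p in cmap.control_points])
    return np.stack([np.interp(u, us, rgbs[:, c]) for c in range(3)], axis=-1)


def load_control_points_file(path: str, name: str = "custom") -> ColorMap:
    """Read a plain-text colormap: one "u r g b" row per control point."""
    points = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            vals = [float(tok) for tok in line.split()]
            if len(vals) != 4:
                raise ValueError(f"{path}: expected 'u r g b' rows, got {line!r}")
            points.append((vals[0], tuple(vals[1:])))
    return from_control_points(points, name=name)
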