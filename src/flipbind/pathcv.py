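"""Path collective variables over an ordered set of reference frames.

Given reference frames R_1..R_N and a configuration x, the progress and
distance variables are the standard exponentially weighted sums

    s(x) = sum_i i * exp(-lambda d_i^2) / sum_i exp(-lambda d_i^2)
    z(x) = -(1/lambda) * ln sum_i exp(-lambda d_i^2)

with d_i the metric distance from x to frame i.  Frames are 1-based, so
s runs from 1 to N and maps directly onto the landmark values of the
binding coordinate (main barrier near s=12, external pose near s=15-16 for
the default 30-frame presets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: spacing tolerance: adjacent-frame distances must lie within this factor
#: of their mean
SPACING_FACTOR = 2.0


@dataclass(frozen=True)
class PathCoordinates:
    s: float
    z: float


@dataclass(frozen=True)
class ReferencePath:
    """Ordered reference frames with the metric parameter lambda.

    frames : (nframes, ndim) array in CV (or fixed-frame Cartesian) units.
    lam : inverse squared-distance units; resolves adjacent frames.
    metric : only "euclidean" is supported (fixed-frame distances).
    """

    frames: np.ndarray
    lam: float
    metric: str = "euclidean"

    def __post_init__(self):
        frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        object.__setattr__(self, "frames", frames)
        if frames.shape[0] < 2:
            raise ValueError("a reference path needs at least 2 frames")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.metric != "euclidean":
            raise ValueError(f"unsupported metric {self.metric!r}")

    @property
    def nframes(self) -> int:
        return self.frames.shape[0]

    def adjacent_distances(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.frames, axis=0), axis=1)

    def check_spacing(self) -> None:
        d = self.adjacent_distances()
        if np.any(d == 0):
            raise ValueError("degenerate path: coincident adjacent frames")
        mean = d.mean()
        if d.max() > SPACING_FACTOR * mean or d.min() < mean / SPACING_FACTOR:
            raise ValueError(
                "path spacing too uneven: adjacent distances "
                f"range {d.min():.3g}-{d.max():.3g} vs mean {mean:.3g}"
            )


def compute_path_cv(config, path: ReferencePath) -> PathCoordinates:
    """Evaluate (s, z) for one configuration.

    Uses a log-sum-exp shift for numerical stability; a configuration so
    far from every frame that the raw exponentials underflow (lambda*d^2
    beyond the double-precision exponent range) is rejected as off-path
    rather than silently returning garbage.
    """
    x = np.atleast_1d(np.asarray(config, dtype=float))
    if x.shape[0] != path.frames.shape[1]:
        raise ValueError(
            f"configuration dimension {x.shape[0]} does not match "
            f"path frames of dimension {path.frames.shape[1]}"
        )
    d2 = np.sum((path.frames - x[None, :]) ** 2, axis=1)
    expo = -path.lam * d2
    shift = expo.max()
    if shift < -745.0:
        raise ValueError("configuration is off-path: all frame distances overflow")
    w = np.exp(expo - shift)
    sw = w.sum()
    idx = np.arange(1, path.nframes + 1, dtype=float)
    s = float(np.dot(idx, w) / sw)
    z = float(-(shift + np.log(sw)) / path.lam)
    return PathCoordinates(s=s, z=z)


def build_reference_path(points, nframes: int, lam: float | None = None) -> ReferencePath:
    """Resample an ordered point sequence to nframes at equal arc length.

    ``points`` may be two endpoints or a whole (unevenly sampled)
    trajectory; frames are placed at equal fractions of the cumulative
    chord length, which makes the spacing invariant hold by construction.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2:
        raise ValueError("points must be a (npoints, ndim) array")
    # drop consecutive duplicates
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0
    pts = pts[keep]
    if len(pts) < 2:
        raise ValueError("need at least 2 distinct source points")
    if nframes < 2:
        raise ValueError("nframes must be >= 2")
    if len(pts) < nframes and len(pts) != 2:
        raise ValueError(f"only {len(pts)} distinct source points for {nframes} frames")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], nframes)
    frames = np.empty((nframes, pts.shape[1]))
    for j in range(pts.shape[1]):
        frames[:, j] = np.interp(targets, arc, pts[:, j])
    path = ReferencePath(frames=frames, lam=lam if lam is not None else 1.0)
    if lam is None:
        path = ReferencePath(frames=frames, lam=choose_lambda(path))
    path.check_spacing()
    return path


def choose_lambda(path: ReferencePath) -> float:
    """Standard heuristic lambda = 2.3 / <d^2> over adjacent frames."""
    d = path.adjacent_distances()
    if np.any(d == 0):
        raise ValueError("degenerate path: zero adjacent distance")
    return float(2.3 / np.mean(d**2))
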