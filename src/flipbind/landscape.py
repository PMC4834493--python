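"""Analytic toy free-energy landscapes along a binding progress coordinate.

A :class:`ToyLandscape` is a sum of Gaussian wells and barriers (plus an
optional harmonic term and confining walls) over a 1D progress coordinate
``s``, optionally extended by a double-well "flip" axis ``q_flip``.  The
topography of the default preset mimics a kinase–inhibitor binding profile:
a deep bound basin containing two near-degenerate poses A and B, a main
unbinding barrier, a metastable external pose C a few kcal/mol above the
bound state, and a flat unbound plateau.

Landscapes are *calibrated*: :func:`make_landscape` adjusts Gaussian centers
and heights iteratively so that each declared minimum/saddle is a true
stationary point of the analytic form at the requested position and free
energy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .constants import T_DEFAULT


@dataclass(frozen=True)
class GaussianTerm:
    """One Gaussian basis term: height*exp(-(s-center)^2/(2 sigma^2)).

    Negative height = well, positive = barrier. Units: center/sigma in CV
    units, height in kcal/mol.
    """

    center: float
    height: float
    sigma: float


@dataclass(frozen=True)
class StationaryPoint:
    name: str
    kind: str  # "min" or "ts"
    s: float
    F: float


@dataclass(frozen=True)
class Feature:
    """Requested topographic feature used by :func:`make_landscape`."""

    name: str
    kind: str  # "min" or "ts"
    s: float
    F: float
    width: float = 1.0


@dataclass(frozen=True)
class FlipAxis:
    """Double-well DFG-flip-like axis coupled bilinearly to s.

    V(q; s) = barrier*(q^2-1)^2 + tilt*q + coupling*(s - s_ref)*q
    so that q = -1 ("in") and q = +1 ("out") are the two conformers and the
    tilt sets the flip penalty; the coupling lets ligand progress along s
    modulate that penalty.
    """

    barrier: float = 3.0
    tilt: float = 0.0
    coupling: float = 0.0
    s_ref: float = 0.0


@dataclass(frozen=True)
class ToyLandscape:
    terms: tuple[GaussianTerm, ...]
    baseline: float = 0.0
    domain: tuple[float, float] = (0.0, 30.0)
    temperature: float = T_DEFAULT
    wall_k: float = 20.0
    harmonic_k: float = 0.0
    harmonic_center: float = 0.0
    stationary_points: tuple[StationaryPoint, ...] = ()
    flip: FlipAxis | None = None
    labels: tuple[str, ...] = ("s",)

    # ------------------------------------------------------------------ 1D
    @property
    def dimensionality(self) -> int:
        return 2 if self.flip is not None else 1

    def potential(self, s):
        """U(s) in kcal/mol; works on scalars or arrays."""
        s = np.asarray(s, dtype=float)
        u = np.full_like(s, self.baseline, dtype=float)
        for t in self.terms:
            u += t.height * np.exp(-((s - t.center) ** 2) / (2.0 * t.sigma**2))
        if self.harmonic_k:
            u += 0.5 * self.harmonic_k * (s - self.harmonic_center) ** 2
        lo, hi = self.domain
        u += np.where(s < lo, 0.5 * self.wall_k * (s - lo) ** 2, 0.0)
        u += np.where(s > hi, 0.5 * self.wall_k * (s - hi) ** 2, 0.0)
        return u if u.ndim else float(u)

    def gradient(self, s):
        """dU/ds in kcal/mol per CV unit."""
        s = np.asarray(s, dtype=float)
        g = np.zeros_like(s, dtype=float)
        for t in self.terms:
            g += (
                t.height
                * (-(s - t.center) / t.sigma**2)
                * np.exp(-((s - t.center) ** 2) / (2.0 * t.sigma**2))
            )
        if self.harmonic_k:
            g += self.harmonic_k * (s - self.harmonic_center)
        lo, hi = self.domain
        g += np.where(s < lo, self.wall_k * (s - lo), 0.0)
        g += np.where(s > hi, self.wall_k * (s - hi), 0.0)
        return g if g.ndim else float(g)

    def tabulate(self, spacing: float = 0.002, pad: float = 2.0):
        """Dense (grid, U, force) tables used by the fast integrators."""
        lo, hi = self.domain
        grid = np.arange(lo - pad, hi + pad + spacing, spacing)
        return grid, self.potential(grid), -self.gradient(grid)

    # ------------------------------------------------------------------ 2D
    def potential2d(self, s, q):
        if self.flip is None:
            raise ValueError("landscape has no flip axis")
        f = self.flip
        s = np.asarray(s, dtype=float)
        q = np.asarray(q, dtype=float)
        return (
            self.potential(s)
            + f.barrier * (q**2 - 1.0) ** 2
            + f.tilt * q
            + f.coupling * (s - f.s_ref) * q
        )

    def flip_penalty(self, s: float, qgrid=None) -> float:
        """Free energy of the q>0 conformer relative to q<0 at fixed s.

        Computed by quadrature of exp(-beta V(q; s)) over each half-axis.
        """
        from .constants import kt

        if self.flip is None:
            raise ValueError("landscape has no flip axis")
        if qgrid is None:
            qgrid = np.linspace(-2.5, 2.5, 2001)
        beta = 1.0 / kt(self.temperature)
        v = self.potential2d(np.full_like(qgrid, s), qgrid)
        v = v - v.min()
        w = np.exp(-beta * v)
        pos = qgrid > 0
        z_out = np.trapezoid(w[pos], qgrid[pos])
        z_in = np.trapezoid(w[~pos], qgrid[~pos])
        return -kt(self.temperature) * np.log(z_out / z_in)

    # ------------------------------------------------------------ utilities
    def point(self, name: str) -> StationaryPoint:
        for p in self.stationary_points:
            if p.name == name:
                return p
        raise KeyError(f"no stationary point named {name!r}")

    def minima(self) -> list[StationaryPoint]:
        return [p for p in self.stationary_points if p.kind == "min"]

    def saddles(self) -> list[StationaryPoint]:
        return [p for p in self.stationary_points if p.kind == "ts"]

    def validate(self, gtol: float = 1e-6) -> None:
        """Check declared stationary points against the analytic form."""
        for p in self.stationary_points:
            g = abs(self.gradient(p.s))
            if g > gtol:
                raise ValueError(
                    f"declared point {p.name} at s={p.s} has |dU/ds|={g:.2e} > {gtol}"
                )
            curv = _curvature(self, p.s)
            if p.kind == "min" and curv <= 0:
                raise ValueError(f"declared minimum {p.name} is not a local minimum")
            if p.kind == "ts" and curv >= 0:
                raise ValueError(f"declared saddle {p.name} is not a local maximum")


def _curvature(land: ToyLandscape, s: float, h: float = 1e-4) -> float:
    return (land.potential(s + h) - 2.0 * land.potential(s) + land.potential(s - h)) / h**2


# ---------------------------------------------------------------------------
# construction / calibration
# ---------------------------------------------------------------------------


def make_landscape(
    features: Sequence[Feature],
    baseline: float = 0.0,
    domain: tuple[float, float] | None = None,
    temperature: float = T_DEFAULT,
    wall_k: float = 20.0,
    flip: FlipAxis | None = None,
    open_right: bool = False,
    tol: float = 1e-10,
) -> ToyLandscape:
    """Build a calibrated landscape from a list of requested features.

    Each feature becomes one Gaussian term; heights are solved linearly so
    that U at the feature positions matches the requested free energies, and
    centers are nudged iteratively until the actual stationary points
    coincide with the requested positions.

    With ``open_right=True`` the landscape is declared to end in an unbound
    plateau at the baseline free energy, which then counts as the right-hand
    basin of the outermost saddle (the exit barrier of a binding profile).

    Raises
    ------
    ValueError
        for negative widths, overlapping minima (centre separation smaller
        than half the summed widths), or a saddle request without a basin on
        both sides ("no saddle").
    """
    features = list(features)
    if not features:
        raise ValueError("need at least one feature")
    for f in features:
        if f.width <= 0:
            raise ValueError(f"negative or zero width for feature {f.name}")
        if f.kind not in ("min", "ts"):
            raise ValueError(f"unknown feature kind {f.kind!r}")
    minima = sorted((f for f in features if f.kind == "min"), key=lambda f: f.s)
    for a, b in zip(minima, minima[1:]):
        if abs(a.s - b.s) < 0.5 * (a.width + b.width):
            raise ValueError(f"overlapping minima {a.name} and {b.name}")
    for f in features:
        if f.kind == "ts":
            left = any(m.s < f.s for m in minima)
            right = any(m.s > f.s for m in minima)
            if open_right and f.F > baseline:
                right = right or all(o.s < f.s for o in features if o is not f)
            if not (left and right):
                raise ValueError(f"no saddle possible at {f.name}: needs flanking basins")

    if domain is None:
        lo = min(f.s for f in features) - 3.0
        hi = max(f.s for f in features) + 3.0
        domain = (lo, hi)

    targets_s = np.array([f.s for f in features])
    targets_f = np.array([f.F for f in features])
    widths = np.array([f.width for f in features])
    n = len(features)

    def build(params):
        centers = params[:n]
        heights = params[n:]
        terms = tuple(GaussianTerm(c, h, w) for c, h, w in zip(centers, heights, widths))
        return ToyLandscape(
            terms=terms,
            baseline=baseline,
            domain=domain,
            temperature=temperature,
            wall_k=wall_k,
            flip=flip,
        )

    def residuals(params):
        land = build(params)
        return np.concatenate(
            [
                land.potential(targets_s) - targets_f,
                land.gradient(targets_s) * widths,
            ]
        )

    # initial guess: centers at the targets, heights from the value conditions
    a0 = np.exp(-((targets_s[:, None] - targets_s[None, :]) ** 2) / (2.0 * widths[None, :] ** 2))
    h0 = np.linalg.solve(a0, targets_f - baseline)
    from scipy.optimize import root

    sol = root(residuals, np.concatenate([targets_s, h0]), method="hybr", tol=tol)
    if not sol.success or np.max(np.abs(residuals(sol.x))) > 1e-7:
        raise RuntimeError(f"landscape calibration did not converge: {sol.message}")
    centers = sol.x[:n]
    if np.any(np.abs(centers - targets_s) > widths):
        raise RuntimeError(
            "landscape calibration drifted: Gaussian centers moved more than "
            "one width from their features; adjust widths or spacing"
        )
    land = build(sol.x)

    pts = tuple(
        StationaryPoint(f.name, f.kind, f.s, float(land.potential(f.s))) for f in features
    )
    land = replace(land, stationary_points=pts)
    land.validate()
    return land


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def _match_well_curvatures(features, ref_name: str, n_iter: int = 4, **kwargs):
    """Rescale minimum widths so all wells share the reference curvature.

    Equal curvatures make the basin free-energy differences equal to the
    minimum offsets (harmonic wells of equal width), which keeps the preset
    quadrature oracles at their nominal values.
    """
    feats = list(features)
    land = make_landscape(feats, **kwargs)
    for _ in range(n_iter):
        cref = _curvature(land, next(f for f in feats if f.name == ref_name).s)
        changed = False
        for i, f in enumerate(feats):
            if f.kind != "min" or f.name == ref_name:
                continue
            c = _curvature(land, f.s)
            ratio = np.sqrt(c / cref)
            if abs(ratio - 1.0) > 1e-4:
                feats[i] = replace(f, width=f.width * ratio)
                changed = True
        land = make_landscape(feats, **kwargs)
        if not changed:
            break
    return land


def src_imatinib_profile(
    barrier: float = 7.0,
    full_scale: bool = False,
    temperature: float = T_DEFAULT,
    flip: FlipAxis | None = None,
) -> ToyLandscape:
    """Kinase–inhibitor style binding profile along s in [0, 30].

    Bound poses A (s=3, F=0) and B (s=6, F=0.3), main unbinding barrier TS1
    at s=12, external metastable pose C at s=15.5 (F=+4.0), a smaller exit
    barrier TS2, and a flat unbound plateau for s > 22.

    ``barrier`` sets the main barrier height; the default 7 kcal/mol keeps
    brute-force rate estimates affordable, while ``full_scale=True`` selects
    the 16.5 kcal/mol barrier with the unbound plateau 14 kcal/mol above the
    bound minimum.
    """
    if full_scale:
        barrier = 16.5
        plateau = 14.0
    else:
        plateau = max(barrier - 2.0, 4.5)
    features = [
        Feature("A", "min", 3.0, 0.0, 1.0),
        Feature("B", "min", 6.0, 0.3, 1.0),
        Feature("TS1", "ts", 12.0, barrier, 1.2),
        Feature("C", "min", 15.5, 4.0, 0.7),
        Feature("TS2", "ts", 19.0, plateau + 1.0, 1.2),
    ]
    return _match_well_curvatures(
        features,
        "A",
        baseline=plateau,
        domain=(0.0, 30.0),
        temperature=temperature,
        flip=flip,
        open_right=True,
    )


def symmetric_double_well(
    barrier: float = 3.0,
    centers: tuple[float, float] = (-1.0, 1.0),
    width: float = 0.5,
    temperature: float = T_DEFAULT,
) -> ToyLandscape:
    """Two equal minima at ``centers`` (F=0) with a saddle midway."""
    mid = 0.5 * (centers[0] + centers[1])
    features = [
        Feature("A", "min", centers[0], 0.0, width),
        Feature("B", "min", centers[1], 0.0, width),
        Feature("TS", "ts", mid, barrier, width),
    ]
    return make_landscape(features, baseline=0.5 * barrier, temperature=temperature)


def asymmetric_double_well(
    delta: float = 1.0,
    barrier: float = 3.5,
    temperature: float = T_DEFAULT,
) -> ToyLandscape:
    """Double well with minima at s=2 (F=0) and s=5 (F=delta).

    The well widths are matched so both minima have equal curvature; the
    basin free-energy difference is then the minimum offset ``delta`` up to
    small anharmonic corrections.
    """
    features = [
        Feature("A", "min", 2.0, 0.0, 0.6),
        Feature("B", "min", 5.0, delta, 0.6),
        Feature("TS", "ts", 3.5, barrier, 0.8),
    ]
    return _match_well_curvatures(
        features,
        "A",
        baseline=barrier - 0.75,
        domain=(0.8, 6.2),
        temperature=temperature,
    )


def harmonic_well(
    k: float = 2.0, center: float = 0.0, temperature: float = T_DEFAULT
) -> ToyLandscape:
    """Pure harmonic well U = k/2 (s-center)^2 (walls pushed far out)."""
    land = ToyLandscape(
        terms=(),
        baseline=0.0,
        domain=(center - 50.0, center + 50.0),
        temperature=temperature,
        harmonic_k=k,
        harmonic_center=center,
        stationary_points=(StationaryPoint("A", "min", center, 0.0),),
    )
    land.validate()
    return land


def boltzmann_weights(land: ToyLandscape, grid: np.ndarray) -> np.ndarray:
    """Normalized Boltzmann density on ``grid`` (quadrature oracle)."""
    from .constants import kt

    u = land.potential(grid)
    u = u - u.min()
    w = np.exp(-u / kt(land.temperature))
    return w / np.trapezoid(w, grid)
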