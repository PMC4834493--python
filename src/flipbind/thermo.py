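"""Thermodynamics of a binding free-energy profile.

Turns a gridded F(s) into the quantities a binding study reports: labelled
critical points, basin free-energy differences by Boltzmann quadrature,
the 1 M standard-state volume correction, the conformational-selection
("flip-bind") versus induced-fit ("bind-flip") thermodynamic cycle, state
populations and barrier heights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import V0_STANDARD, kt
from .fes import FreeEnergyProfile

ROUTES = ("flip-bind", "bind-flip")


@dataclass(frozen=True)
class CriticalPoint:
    label: str
    s: float
    F: float


@dataclass(frozen=True)
class CriticalPoints:
    minima: tuple[CriticalPoint, ...]
    saddles: tuple[CriticalPoint, ...]

    def __getitem__(self, label: str) -> CriticalPoint:
        for p in self.minima + self.saddles:
            if p.label == label:
                return p
        raise KeyError(label)


@dataclass(frozen=True)
class BasinDefinition:
    """A labelled s-interval of the profile."""

    label: str
    interval: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.interval
        if not lo < hi:
            raise ValueError(f"empty basin interval for {self.label!r}")


@dataclass(frozen=True)
class BindingFreeEnergy:
    dg_raw: float
    correction: float
    uncertainty: float = 0.0

    @property
    def dg_std(self) -> float:
        return self.dg_raw + self.correction


@dataclass(frozen=True)
class ThermoCycle:
    route: str
    components: tuple[tuple[str, float], ...]
    uncertainty: float = 0.0

    def __post_init__(self):
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}; expected one of {ROUTES}")

    @property
    def total(self) -> float:
        return float(sum(v for _, v in self.components))


# ---------------------------------------------------------------------------
# critical points and basins
# ---------------------------------------------------------------------------


def find_critical_points(fes: FreeEnergyProfile, min_prominence: float = 0.2) -> CriticalPoints:
    """Label local minima (A, B, C, ...) and the saddles between them (TS1, ...).

    A minimum must be at least ``min_prominence`` kcal/mol below the lower
    of the two saddles that flank it; saddles are the highest point of the
    profile between adjacent retained minima.  Labels are assigned by
    increasing s, so the ordering is deterministic.
    """
    from scipy.signal import find_peaks

    f = fes.F
    if np.ptp(f) < min_prominence:
        warnings.warn("profile is flat: no critical points found")
        return CriticalPoints(minima=(), saddles=())
    idx_min, _ = find_peaks(-f, prominence=min_prominence)
    if len(idx_min) == 0:
        warnings.warn("no minima above the prominence threshold")
        return CriticalPoints(minima=(), saddles=())
    letters = "ABCDEFGHIJ"
    minima = tuple(
        CriticalPoint(letters[k], float(fes.grid[i]), float(f[i]))
        for k, i in enumerate(idx_min)
    )
    saddles = []
    for k in range(len(idx_min) - 1):
        lo, hi = idx_min[k], idx_min[k + 1]
        j = lo + int(np.argmax(f[lo : hi + 1]))
        saddles.append(CriticalPoint(f"TS{k + 1}", float(fes.grid[j]), float(f[j])))
    return CriticalPoints(minima=minima, saddles=tuple(saddles))


def watershed_basins(fes: FreeEnergyProfile, min_prominence: float = 0.2) -> dict:
    """Assign each grid interval to the minimum it drains to.

    On a 1D profile the watershed boundaries are simply the saddle
    positions; the outermost basins extend to the grid edges.  Returns
    {label: BasinDefinition}.
    """
    cp = find_critical_points(fes, min_prominence)
    if not cp.minima:
        return {}
    bounds = [fes.grid[0]] + [s.s for s in cp.saddles] + [fes.grid[-1]]
    return {
        m.label: BasinDefinition(m.label, (bounds[k], bounds[k + 1]))
        for k, m in enumerate(cp.minima)
    }


# ---------------------------------------------------------------------------
# basin free energies
# ---------------------------------------------------------------------------


def _basin_interval(basin) -> tuple[float, float]:
    if isinstance(basin, BasinDefinition):
        return basin.interval
    lo, hi = basin
    if not lo < hi:
        raise ValueError("empty basin interval")
    return float(lo), float(hi)


def _log_basin_weight(grid, f, interval, beta) -> float:
    lo, hi = interval
    mask = (grid >= lo) & (grid <= hi)
    if mask.sum() < 2:
        raise ValueError("basin contains fewer than 2 grid points")
    if np.all(f[mask] >= f.max() - 1e-9):
        raise ValueError("unsampled basin: free energy at grid maximum throughout")
    fm = f[mask]
    shift = fm.min()
    z = np.trapezoid(np.exp(-beta * (fm - shift)), grid[mask])
    return -beta * shift + np.log(z)


def basin_free_energy(
    fes: FreeEnergyProfile,
    basin_x,
    basin_y,
    temperature: float = 300.0,
    nresample: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """dG = -kT ln(Z_X/Z_Y) with Z the Boltzmann quadrature over each basin.

    Uncertainty is propagated from the per-bin profile errors (if present)
    by Gaussian resampling of the profile.
    Returns (dG, uncertainty) in kcal/mol; dG < 0 means X is more stable.
    """
    beta = 1.0 / kt(temperature)
    ix = _basin_interval(basin_x)
    iy = _basin_interval(basin_y)
    dg = -(_log_basin_weight(fes.grid, fes.F, ix, beta) - _log_basin_weight(fes.grid, fes.F, iy, beta)) / beta
    if fes.err is None or not np.any(fes.err > 0):
        return float(dg), 0.0
    rng = np.random.default_rng(seed)
    samples = np.empty(nresample)
    for k in range(nresample):
        f = fes.F + rng.standard_normal(len(fes.F)) * fes.err
        samples[k] = -(_log_basin_weight(fes.grid, f, ix, beta) - _log_basin_weight(fes.grid, f, iy, beta)) / beta
    return float(dg), float(samples.std(ddof=1))


def standard_state_correction(v_unbound: float, temperature: float = 300.0) -> float:
    """kT ln(V_unbound/V0) with V0 = 1660 A^3 (1 M standard state)."""
    if v_unbound <= 0:
        raise ValueError("unbound volume must be positive")
    return kt(temperature) * float(np.log(v_unbound / V0_STANDARD))


def binding_free_energy(
    fes: FreeEnergyProfile,
    bound_basin,
    unbound_basin,
    v_unbound: float = V0_STANDARD,
    temperature: float = 300.0,
    seed: int = 0,
) -> BindingFreeEnergy:
    """Standard-state corrected absolute binding free energy."""
    blo, bhi = _basin_interval(bound_basin)
    ulo, uhi = _basin_interval(unbound_basin)
    if max(blo, ulo) < min(bhi, uhi):
        raise ValueError("bound and unbound basins must be disjoint")
    dg, unc = basin_free_energy(fes, (blo, bhi), (ulo, uhi), temperature, seed=seed)
    corr = standard_state_correction(v_unbound, temperature)
    return BindingFreeEnergy(dg_raw=dg, correction=corr, uncertainty=unc)


# ---------------------------------------------------------------------------
# cycle, populations, barriers
# ---------------------------------------------------------------------------


def combine_cycle(components, route: str, uncertainty: float = 0.0) -> ThermoCycle:
    """Assemble one route of the binding thermodynamic cycle.

    ``components`` is a sequence of (label, dG) pairs, e.g. the path
    association dG plus the conformational-flip penalty for the
    "flip-bind" (conformational selection) route.
    """
    comps = tuple((str(k), float(v)) for k, v in components)
    for _, v in comps:
        if not np.isfinite(v):
            raise ValueError("cycle components must be finite")
    return ThermoCycle(route=route, components=comps, uncertainty=uncertainty)


def cycle_closure(a: ThermoCycle, b: ThermoCycle) -> dict:
    """Check that two routes of the same cycle agree within uncertainties."""
    gap = abs(a.total - b.total)
    budget = a.uncertainty + b.uncertainty
    return {
        "difference": gap,
        "budget": budget,
        "closes": bool(gap <= budget + 1e-12),
    }


def boltzmann_population(dgs, temperature: float = 300.0) -> np.ndarray:
    """Normalized populations of point states with free energies dgs."""
    dgs = np.asarray(dgs, dtype=float)
    if dgs.size < 2:
        raise ValueError("need at least 2 states")
    w = np.exp(-(dgs - dgs.min()) / kt(temperature))
    return w / w.sum()


def population_from_profile(
    fes: FreeEnergyProfile, basins, temperature: float = 300.0
) -> dict:
    """Basin-integrated populations {label: p} for a dict of basins."""
    beta = 1.0 / kt(temperature)
    logz = {
        label: _log_basin_weight(fes.grid, fes.F, _basin_interval(b), beta)
        for label, b in basins.items()
    }
    shift = max(logz.values())
    z = {k: np.exp(v - shift) for k, v in logz.items()}
    total = sum(z.values())
    return {k: float(v / total) for k, v in z.items()}


def barrier_height(
    fes: FreeEnergyProfile, basin, saddle_s: float
) -> tuple[float, float]:
    """dG_barrier = F(saddle) - min F over the basin, with quadrature-summed
    per-bin uncertainty.  Returns (dG_barrier, uncertainty)."""
    lo, hi = _basin_interval(basin)
    mask = (fes.grid >= lo) & (fes.grid <= hi)
    if not np.any(mask):
        raise ValueError("basin outside the profile grid")
    i_min = np.where(mask)[0][np.argmin(fes.F[mask])]
    f_min = float(fes.F[i_min])
    f_sad = fes.value_at(saddle_s)
    if f_sad < f_min - 1e-12:
        raise ValueError("saddle free energy is below the basin minimum")
    err = 0.0
    if fes.err is not None:
        err = float(np.hypot(fes.err[i_min], fes.err_at(saddle_s)))
    return f_sad - f_min, err
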