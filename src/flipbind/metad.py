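"""Well-tempered metadynamics with multiple walkers, and FES reconstruction.

The sampler deposits Gaussian hills along the progress coordinate s of a
toy landscape; in well-tempered mode the deposited height decays as

    w_k = w0 * exp(-V_bias(s_k) / (kB * dT)),   dT = (gamma - 1) * T

and the free energy is recovered from the accumulated bias as

    F(s) = -(gamma / (gamma - 1)) * V_bias(s)   (min-shifted to 0).

Hills are exchanged through a PLUMED-style text log so that sampling and
reconstruction are decoupled.  A parallel-tempering swap move between
replicas at different temperatures is provided as a standalone step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .constants import KB, MASS_DEFAULT, kt
from .dynamics import Trajectory, check_timestep
from .fes import FreeEnergyProfile
from .landscape import ToyLandscape

HILLS_FIELDS = ["time", "s", "sigma_s", "height", "biasf", "walker"]


@dataclass(frozen=True)
class MetadParams:
    """Deposition schedule: initial height w0 (kcal/mol), width sigma
    (CV units), bias factor gamma, pace in integrator steps."""

    w0: float = 0.1
    sigma: float = 0.3
    gamma: float = 8.0
    pace: int = 500
    well_tempered: bool = True


@dataclass(frozen=True)
class HillsLog:
    """Deposited bias Gaussians (one record per hill)."""

    time: np.ndarray  # ps
    center: np.ndarray  # CV units
    sigma: np.ndarray
    height: np.ndarray  # kcal/mol, as deposited (tempered)
    biasf: np.ndarray  # gamma; inf for standard metadynamics
    walker: np.ndarray

    def __post_init__(self):
        arrays = {k: np.asarray(getattr(self, k)) for k in HILLS_FIELDS_ATTR}
        n = len(arrays["time"])
        for k, a in arrays.items():
            if len(a) != n:
                raise ValueError("hills columns must have equal length")
            object.__setattr__(self, k, a)
        if np.any(self.height <= 0):
            raise ValueError("hill heights must be positive")
        if np.any(self.sigma <= 0):
            raise ValueError("hill widths must be positive")
        for w in np.unique(self.walker):
            t = self.time[self.walker == w]
            if np.any(np.diff(t) < 0):
                raise ValueError(f"times must be non-decreasing for walker {w}")

    def __len__(self) -> int:
        return len(self.time)

    def bias_potential(self, grid: np.ndarray, upto: int | None = None) -> np.ndarray:
        """Sum of the first ``upto`` hills evaluated on ``grid``."""
        grid = np.asarray(grid, dtype=float)
        n = len(self) if upto is None else int(upto)
        v = np.zeros_like(grid)
        chunk = max(1, 10_000_000 // max(len(grid), 1))
        for k0 in range(0, n, chunk):
            k1 = min(k0 + chunk, n)
            d = grid[None, :] - self.center[k0:k1, None]
            v += np.einsum(
                "k,kg->g",
                self.height[k0:k1],
                np.exp(-(d**2) / (2.0 * self.sigma[k0:k1, None] ** 2)),
            )
        return v


HILLS_FIELDS_ATTR = ["time", "center", "sigma", "height", "biasf", "walker"]


def run_metad(
    landscape: ToyLandscape,
    params: MetadParams = MetadParams(),
    nsteps: int = 10**6,
    nwalkers: int = 1,
    dt: float = 0.02,
    friction: float = 1.0,
    seed: int = 0,
    x0=None,
    stride: int = 50,
    mass: float = MASS_DEFAULT,
) -> tuple[HillsLog, list[Trajectory]]:
    """Metadynamics run; all walkers deposit into one shared bias.

    Returns the hills log and one strided trajectory per walker.
    """
    if params.well_tempered and params.gamma <= 1:
        raise ValueError("well-tempered metadynamics requires gamma > 1")
    if params.pace < 10:
        raise ValueError("pace must be at least 10 integrator steps")
    check_timestep(landscape, dt, mass)
    grid, _, force = landscape.tabulate()
    if x0 is None:
        mins = landscape.minima()
        start = mins[0].s if mins else 0.5 * sum(landscape.domain)
        x0s = np.full(nwalkers, float(start))
    else:
        x0s = np.broadcast_to(np.asarray(x0, dtype=float), (nwalkers,)).copy()
    ncycles = int(nsteps) // params.pace
    wt_dkt = KB * (params.gamma - 1.0) * landscape.temperature if params.well_tempered else -1.0
    h_t, h_c, h_h, h_w, traj, status = _kernels.metad_run_kernel(
        x0s,
        ncycles,
        int(params.pace),
        float(dt),
        float(friction),
        kt(landscape.temperature),
        float(mass),
        grid[0],
        grid[1] - grid[0],
        force,
        float(params.w0),
        float(params.sigma),
        float(wt_dkt),
        int(stride),
        int(seed) % 2**31,
    )
    if status == _kernels.STATUS_DIVERGED:
        raise RuntimeError(
            "metadynamics walker diverged (left the tabulated domain); "
            f"deposited {len(h_t)} hills before the failure"
        )
    biasf = params.gamma if params.well_tempered else math.inf
    hills = HillsLog(
        time=h_t,
        center=h_c,
        sigma=np.full_like(h_c, params.sigma),
        height=h_h,
        biasf=np.full_like(h_c, biasf),
        walker=h_w,
    )
    times = dt * stride * np.arange(1, traj.shape[0] + 1)
    trajs = [
        Trajectory(
            times=times,
            s=traj[:, w],
            v=None,
            dt=dt,
            stride=stride,
            temperature=landscape.temperature,
            seed=seed,
        )
        for w in range(nwalkers)
    ]
    return hills, trajs


def default_grid(hills: HillsLog, spacing: float = 0.05) -> np.ndarray:
    lo = float(np.min(hills.center - 3.0 * hills.sigma))
    hi = float(np.max(hills.center + 3.0 * hills.sigma))
    return np.arange(lo, hi + spacing, spacing)


def reconstruct_fes(hills: HillsLog, grid=None, upto: int | None = None) -> FreeEnergyProfile:
    """Free energy from the accumulated bias.

    F(s) = -(gamma/(gamma-1)) * V_bias(s) in well-tempered mode, -V_bias(s)
    for standard metadynamics; min-shifted so F >= 0.
    """
    if len(hills) == 0:
        warnings.warn("empty hills log: returning a flat profile")
        grid = np.asarray(grid if grid is not None else np.linspace(0, 1, 11), dtype=float)
        return FreeEnergyProfile(grid=grid, F=np.zeros_like(grid))
    if grid is None:
        grid = default_grid(hills)
    grid = np.asarray(grid, dtype=float)
    n = len(hills) if upto is None else int(upto)
    tol = 1e-9
    if grid[0] > np.min(hills.center[:n] - 3.0 * hills.sigma[:n]) + tol or grid[-1] < np.max(
        hills.center[:n] + 3.0 * hills.sigma[:n]
    ) - tol:
        raise ValueError("grid must cover all hill centers +- 3 sigma")
    v = hills.bias_potential(grid, upto=n)
    gamma = hills.biasf[0]
    factor = gamma / (gamma - 1.0) if np.isfinite(gamma) and gamma > 1 else 1.0
    return FreeEnergyProfile(grid=grid, F=-factor * v)


def fes_uncertainty(
    hills: HillsLog,
    grid=None,
    window: float = 0.2,
    nsnapshots: int = 10,
    align_region=None,
) -> np.ndarray:
    """Per-bin standard deviation over mean-aligned reconstruction snapshots.

    Profiles are reconstructed at ``nsnapshots`` evenly spaced deposition
    counts inside the final ``window`` fraction of the run, aligned by
    subtracting each snapshot's mean over ``align_region`` (a boolean grid
    mask; default: the whole grid) -- metadynamics profiles are defined up
    to a constant.
    """
    if not 0 < window <= 1:
        raise ValueError("window must be a fraction in (0, 1]")
    if nsnapshots < 5:
        raise ValueError("need at least 5 snapshots inside the window")
    if grid is None:
        grid = default_grid(hills)
    grid = np.asarray(grid, dtype=float)
    n = len(hills)
    n0 = int(round((1.0 - window) * n))
    counts = np.unique(np.linspace(max(n0, 1), n, nsnapshots).astype(int))
    if len(counts) < 5:
        raise ValueError("window too short: fewer than 5 distinct snapshots")
    profiles = [reconstruct_fes(hills, grid, upto=int(c)).F for c in counts]
    aligned = align_profiles(np.asarray(profiles), align_region)
    return np.std(aligned, axis=0, ddof=1)


def align_profiles(profiles: np.ndarray, region=None) -> np.ndarray:
    """Remove the arbitrary constant from each profile snapshot.

    Metadynamics free energies are defined up to an additive constant, so
    snapshots are compared after subtracting each one's mean over
    ``region`` (a boolean mask over the grid; default the whole grid).
    Snapshots differing only by a constant become identical.
    """
    profiles = np.asarray(profiles, dtype=float)
    mask = np.ones(profiles.shape[1], dtype=bool) if region is None else np.asarray(region)
    return profiles - profiles[:, mask].mean(axis=1, keepdims=True)


def reconstruct_with_uncertainty(
    hills: HillsLog, grid=None, window: float = 0.2, nsnapshots: int = 10
) -> FreeEnergyProfile:
    if grid is None:
        grid = default_grid(hills)
    fes = reconstruct_fes(hills, grid)
    err = fes_uncertainty(hills, grid, window=window, nsnapshots=nsnapshots)
    return FreeEnergyProfile(grid=fes.grid, F=fes.F, err=err)


# ---------------------------------------------------------------------------
# parallel tempering
# ---------------------------------------------------------------------------


def replica_exchange_step(
    positions,
    temperatures,
    landscape: ToyLandscape | list,
    seed: int | np.random.Generator = 0,
    bias=None,
):
    """One sweep of Metropolis swap attempts between neighbouring replicas.

    Acceptance for the pair (i, j): min(1, exp[(beta_i - beta_j)(U_i - U_j)])
    with U the potential (landscape plus optional bias) at each replica's
    position.  Returns (new_positions, list of (i, j, accepted)).
    """
    if isinstance(landscape, (list, tuple)):
        if any(l is not landscape[0] for l in landscape):
            raise ValueError("all replicas must share the same landscape")
        landscape = landscape[0]
    x = np.array(positions, dtype=float)
    temps = np.asarray(temperatures, dtype=float)
    if len(x) != len(temps) or len(x) < 2:
        raise ValueError("need >= 2 replicas with one temperature each")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def energy(s):
        u = landscape.potential(s)
        if bias is not None:
            u = u + bias(s)
        return u

    record = []
    for i in range(len(x) - 1):
        j = i + 1
        bi, bj = 1.0 / kt(temps[i]), 1.0 / kt(temps[j])
        du = energy(x[i]) - energy(x[j])
        acc = min(1.0, math.exp(min(700.0, (bi - bj) * du)))
        accepted = rng.random() < acc
        if accepted:
            x[i], x[j] = x[j], x[i]
        record.append((i, j, bool(accepted)))
    return x, record


# ---------------------------------------------------------------------------
# PLUMED-style HILLS text IO
# ---------------------------------------------------------------------------


def write_hills(hills: HillsLog, path) -> None:
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(HILLS_FIELDS) + "\n")
        for k in range(len(hills)):
            fh.write(
                f"{hills.time[k]:.4f} {hills.center[k]:.6f} {hills.sigma[k]:.6f} "
                f"{hills.height[k]:.8f} {hills.biasf[k]:.4f} {int(hills.walker[k])}\n"
            )


def read_hills(path) -> HillsLog:
    """Strict PLUMED-dialect reader; malformed widths/heights are rejected."""
    rows = []
    header = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#!"):
                if header is None and "FIELDS" in line:
                    header = line.split()[2:]
                continue
            parts = line.split()
            if header is not None and len(parts) != len(header):
                raise ValueError(f"malformed hills record: {line!r}")
            rows.append([float(p) for p in parts])
    if header is None:
        raise ValueError("missing '#! FIELDS' header")
    want = HILLS_FIELDS
    if header[: len(want) - 1] != want[:-1]:
        raise ValueError(f"unexpected FIELDS header {header!r}")
    data = np.asarray(rows, dtype=float)
    if data.size == 0:
        data = np.empty((0, len(header)))
    walker = data[:, 5] if data.shape[1] > 5 else np.zeros(len(data))
    return HillsLog(
        time=data[:, 0],
        center=data[:, 1],
        sigma=data[:, 2],
        height=data[:, 3],
        biasf=data[:, 4],
        walker=walker.astype(int),
    )
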