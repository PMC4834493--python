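"""Langevin dynamics on toy landscapes (BAOAB splitting)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .constants import MASS_DEFAULT, kt
from .landscape import ToyLandscape


@dataclass(frozen=True)
class Trajectory:
    """Strided record of a Langevin run along the progress coordinate."""

    times: np.ndarray  # ps
    s: np.ndarray
    v: np.ndarray | None
    dt: float  # ps, integrator step
    stride: int
    temperature: float  # K, thermostat target
    seed: int

    def __len__(self) -> int:
        return len(self.s)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_ps": self.times, "s": self.s})


def check_timestep(landscape: ToyLandscape, dt: float, mass: float = MASS_DEFAULT) -> None:
    """Reject timesteps too large for the stiffest part of the landscape.

    The criterion is the standard harmonic-stability proxy: the local
    angular frequency sqrt(U''_max/m) times dt must stay well below the
    Verlet stability limit, which keeps the per-step energy error of the
    unbiased integrator far below 1e-3 kT.
    """
    grid, u, _ = landscape.tabulate(spacing=0.01)
    curv = np.gradient(np.gradient(u, grid), grid)
    k_max = max(float(np.nanmax(curv)), landscape.wall_k)
    omega = np.sqrt(k_max / mass)
    if omega * dt > 0.5:
        raise ValueError(
            f"dt={dt} ps too large: omega_max*dt={omega * dt:.2f} > 0.5 "
            f"(stiffest curvature {k_max:.2f} kcal/mol/u^2)"
        )


def langevin_run(
    landscape: ToyLandscape,
    nsteps: int,
    dt: float = 0.02,
    friction: float = 1.0,
    seed: int = 0,
    x0: float | None = None,
    stride: int = 10,
    mass: float = MASS_DEFAULT,
    bias=None,
) -> Trajectory:
    """Unbiased (or externally biased) Langevin run.

    Parameters
    ----------
    friction : ps^-1 Langevin friction.
    bias : optional callable U_bias(s) in kcal/mol added to the landscape.
    seed : identical (landscape, parameters, seed) give identical output.
    """
    check_timestep(landscape, dt, mass)
    grid, u, force = landscape.tabulate()
    if bias is not None:
        ub = np.asarray(bias(grid), dtype=float)
        force = force - np.gradient(ub, grid)
    if x0 is None:
        mins = landscape.minima()
        x0 = mins[0].s if mins else 0.5 * sum(landscape.domain)
    kt_ = kt(landscape.temperature)
    rng = np.random.default_rng(seed)
    v0 = float(np.sqrt(kt_ / mass)) * float(rng.standard_normal()) if kt_ > 0 else 0.0
    xs, vs, status = _kernels.baoab_run(
        float(x0),
        v0,
        int(nsteps),
        float(dt),
        float(friction),
        kt_,
        float(mass),
        grid[0],
        grid[1] - grid[0],
        force,
        int(stride),
        int(seed) % 2**31,
    )
    if status == _kernels.STATUS_DIVERGED:
        last = xs[-1] if len(xs) else x0
        raise RuntimeError(
            f"trajectory diverged: coordinate left the tabulated domain "
            f"{landscape.domain} (last recorded s={last:.3f}); reduce dt or "
            f"check the bias"
        )
    times = dt * stride * np.arange(1, len(xs) + 1)
    return Trajectory(
        times=times,
        s=xs,
        v=vs,
        dt=dt,
        stride=stride,
        temperature=landscape.temperature,
        seed=seed,
    )
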