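"""Numba kernels for Langevin propagation, metadynamics and shooting.

All kernels work on a dense tabulated force grid (linear interpolation);
the tables are produced by ``ToyLandscape.tabulate`` on a 0.002 CV-unit
spacing, so interpolation error is far below thermal noise.  A trajectory
that leaves the tabulated region (domain plus the confining-wall pad) is
reported as diverged.

BAOAB splitting of the Langevin equation is used throughout: half kick,
half drift, Ornstein-Uhlenbeck velocity update, half drift, half kick.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_DIVERGED = 1

OUT_TIMEOUT = 0
OUT_BOUND = 1
OUT_UNBOUND = 2


@njit(cache=True, inline="always")
def _interp_force(x, glo, dx, fgrid):
    pos = (x - glo) / dx
    i = int(pos)
    if i < 0 or i >= fgrid.shape[0] - 1:
        return 0.0, False
    frac = pos - i
    return fgrid[i] * (1.0 - frac) + fgrid[i + 1] * frac, True


@njit(cache=True)
def baoab_run(
    x0,
    v0,
    nsteps,
    dt,
    gamma,
    kt_,
    mass,
    glo,
    dx,
    fgrid,
    stride,
    seed,
):
    """Single-particle BAOAB run; returns (xs, vs, status)."""
    np.random.seed(seed)
    nrec = nsteps // stride
    xs = np.empty(nrec)
    vs = np.empty(nrec)
    if gamma > 0.0:
        c1 = np.exp(-gamma * dt)
    else:
        c1 = 1.0
    c2 = np.sqrt(kt_ / mass * (1.0 - c1 * c1))
    x = x0
    v = v0
    f, ok = _interp_force(x, glo, dx, fgrid)
    if not ok:
        return xs[:0], vs[:0], STATUS_DIVERGED
    irec = 0
    for step in range(nsteps):
        v += 0.5 * dt * f / mass
        x += 0.5 * dt * v
        v = c1 * v + c2 * np.random.normal()
        x += 0.5 * dt * v
        f, ok = _interp_force(x, glo, dx, fgrid)
        if not ok:
            return xs[:irec], vs[:irec], STATUS_DIVERGED
        v += 0.5 * dt * f / mass
        if (step + 1) % stride == 0:
            xs[irec] = x
            vs[irec] = v
            irec += 1
    return xs, vs, STATUS_OK


@njit(cache=True)
def metad_run_kernel(
    x0s,
    ncycles,
    pace,
    dt,
    gamma_f,
    kt_,
    mass,
    glo,
    dx,
    fgrid,
    w0,
    sigma,
    wt_dkt,
    stride,
    seed,
):
    """Multiple-walker (well-tempered) metadynamics on a shared bias.

    wt_dkt = kB*(gamma-1)*T for well-tempered scaling; pass <= 0 for
    standard (constant-height) metadynamics.

    Returns (hill_times, hill_centers, hill_heights, hill_walkers,
    traj (nrec, nwalkers), status).
    """
    np.random.seed(seed)
    nwalkers = x0s.shape[0]
    npts = fgrid.shape[0]
    vbias = np.zeros(npts)
    fbias = np.zeros(npts)
    nhills = ncycles * nwalkers
    h_time = np.empty(nhills)
    h_center = np.empty(nhills)
    h_height = np.empty(nhills)
    h_walker = np.empty(nhills, np.int64)
    nrec_per_cycle = pace // stride
    traj = np.empty((ncycles * nrec_per_cycle, nwalkers))

    if gamma_f > 0.0:
        c1 = np.exp(-gamma_f * dt)
    else:
        c1 = 1.0
    c2 = np.sqrt(kt_ / mass * (1.0 - c1 * c1))

    xs = x0s.copy()
    vs = np.zeros(nwalkers)
    for w in range(nwalkers):
        vs[w] = np.sqrt(kt_ / mass) * np.random.normal()

    win = int(5.0 * sigma / dx) + 1
    ih = 0
    for cyc in range(ncycles):
        for w in range(nwalkers):
            x = xs[w]
            v = vs[w]
            f1, ok = _interp_force(x, glo, dx, fgrid)
            f2, ok2 = _interp_force(x, glo, dx, fbias)
            if not (ok and ok2):
                return h_time[:ih], h_center[:ih], h_height[:ih], h_walker[:ih], traj, STATUS_DIVERGED
            f = f1 + f2
            for step in range(pace):
                v += 0.5 * dt * f / mass
                x += 0.5 * dt * v
                v = c1 * v + c2 * np.random.normal()
                x += 0.5 * dt * v
                f1, ok = _interp_force(x, glo, dx, fgrid)
                f2, ok2 = _interp_force(x, glo, dx, fbias)
                if not (ok and ok2):
                    return h_time[:ih], h_center[:ih], h_height[:ih], h_walker[:ih], traj, STATUS_DIVERGED
                f = f1 + f2
                v += 0.5 * dt * f / mass
                if (step + 1) % stride == 0:
                    traj[cyc * nrec_per_cycle + (step + 1) // stride - 1, w] = x
            xs[w] = x
            vs[w] = v
        # deposit one hill per walker at the end of the cycle
        for w in range(nwalkers):
            x = xs[w]
            # current bias at the walker position (for tempering)
            vb, _ = _interp_force(x, glo, dx, vbias)  # reuse interp on vbias
            if wt_dkt > 0.0:
                h = w0 * np.exp(-vb / wt_dkt)
            else:
                h = w0
            ic = int((x - glo) / dx)
            j0 = max(ic - win, 0)
            j1 = min(ic + win, npts - 1)
            for j in range(j0, j1 + 1):
                g = glo + j * dx
                d = g - x
                e = h * np.exp(-d * d / (2.0 * sigma * sigma))
                vbias[j] += e
                fbias[j] += e * d / (sigma * sigma)
            h_time[ih] = (cyc + 1) * pace * dt
            h_center[ih] = x
            h_height[ih] = h
            h_walker[ih] = w
            ih += 1
    return h_time, h_center, h_height, h_walker, traj, STATUS_OK


@njit(cache=True)
def committor_batch(
    starts,
    vels,
    max_steps,
    dt,
    gamma,
    kt_,
    mass,
    glo,
    dx,
    fgrid,
    lo_b,
    hi_b,
    seed,
):
    """Integrate each (start, velocity) pair until it commits.

    Commitment: x <= lo_b -> OUT_BOUND; x >= hi_b -> OUT_UNBOUND; else
    OUT_TIMEOUT after max_steps.  Returns (outcomes, first-passage times).
    """
    np.random.seed(seed)
    n = starts.shape[0]
    outcomes = np.zeros(n, np.int8)
    fpt = np.zeros(n)
    if gamma > 0.0:
        c1 = np.exp(-gamma * dt)
    else:
        c1 = 1.0
    c2 = np.sqrt(kt_ / mass * (1.0 - c1 * c1))
    for k in range(n):
        x = starts[k]
        v = vels[k]
        f, ok = _interp_force(x, glo, dx, fgrid)
        done = False
        for step in range(max_steps):
            v += 0.5 * dt * f / mass
            x += 0.5 * dt * v
            v = c1 * v + c2 * np.random.normal()
            x += 0.5 * dt * v
            f, ok = _interp_force(x, glo, dx, fgrid)
            if not ok:
                outcomes[k] = OUT_TIMEOUT
                done = True
                break
            v += 0.5 * dt * f / mass
            if x <= lo_b:
                outcomes[k] = OUT_BOUND
                fpt[k] = (step + 1) * dt
                done = True
                break
            if x >= hi_b:
                outcomes[k] = OUT_UNBOUND
                fpt[k] = (step + 1) * dt
                done = True
                break
        if not done:
            outcomes[k] = OUT_TIMEOUT
            fpt[k] = max_steps * dt
    return outcomes, fpt


@njit(cache=True)
def mfpt_batch(
    x0,
    n_runs,
    absorb_at,
    max_steps,
    dt,
    gamma,
    kt_,
    mass,
    glo,
    dx,
    fgrid,
    seed,
):
    """First-passage times from x0 to x >= absorb_at for n_runs trajectories."""
    np.random.seed(seed)
    times = np.empty(n_runs)
    ok_flags = np.zeros(n_runs, np.int8)
    if gamma > 0.0:
        c1 = np.exp(-gamma * dt)
    else:
        c1 = 1.0
    c2 = np.sqrt(kt_ / mass * (1.0 - c1 * c1))
    for k in range(n_runs):
        x = x0
        v = np.sqrt(kt_ / mass) * np.random.normal()
        f, ok = _interp_force(x, glo, dx, fgrid)
        for step in range(max_steps):
            v += 0.5 * dt * f / mass
            x += 0.5 * dt * v
            v = c1 * v + c2 * np.random.normal()
            x += 0.5 * dt * v
            f, ok = _interp_force(x, glo, dx, fgrid)
            if not ok:
                break
            v += 0.5 * dt * f / mass
            if x >= absorb_at:
                times[k] = (step + 1) * dt
                ok_flags[k] = 1
                break
        else:
            times[k] = max_steps * dt
    return times, ok_flags
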