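"""Trajectory-derived fast dynamics: RMSF and bond-vector order parameters.

The trajectory order parameter is the long-time plateau of the internal
P2 autocorrelation of the (unit) bond vector,

    C(t) = < P2( u(0) . u(t) ) >  ->  S^2  as t -> inf,

computed efficiently through the five second-rank spherical components of
u (an FFT-based correlation), with the plateau taken as the mean of C(t)
over the final plateau window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TrajectoryDynamics:
    """Per-residue RMSF and trajectory order parameters."""

    results: pd.DataFrame  # residue, rmsf, S2 (either may be NaN)
    window: tuple[int, int] | None = None  # plateau lag window used for S2


def rmsf(coords: np.ndarray) -> float:
    """sqrt(<|x - <x>|^2>) for one coordinate series (nframes[, ndim])."""
    x = np.asarray(coords, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    dev = x - x.mean(axis=0, keepdims=True)
    return float(np.sqrt(np.mean(np.sum(dev**2, axis=1))))


def _second_rank_components(u: np.ndarray) -> np.ndarray:
    """Real second-rank basis: C(t) = (4pi/5) sum_m <Y2m*(0) Y2m(t)> becomes
    an ordinary correlation of these five real series."""
    x, y, z = u[:, 0], u[:, 1], u[:, 2]
    return np.stack(
        [
            np.sqrt(3.0) * x * y,
            np.sqrt(3.0) * x * z,
            np.sqrt(3.0) * y * z,
            np.sqrt(3.0) / 2.0 * (x**2 - y**2),
            0.5 * (3.0 * z**2 - 1.0),
        ],
        axis=1,
    )


def p2_autocorrelation(u: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """C(t) = <P2(u(0).u(t))> by FFT over the component series."""
    u = np.asarray(u, dtype=float)
    n = len(u)
    if max_lag is None:
        max_lag = n // 5
    comp = _second_rank_components(u)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    c = np.zeros(max_lag + 1)
    for k in range(comp.shape[1]):
        f = np.fft.rfft(comp[:, k], nfft)
        acf = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
        c += acf
    counts = n - np.arange(max_lag + 1)
    return c / counts


def s2_from_vectors(
    u: np.ndarray, plateau_fraction: float = 0.5, max_lag: int | None = None
) -> float:
    """Order parameter as the mean of C(t) over the final plateau window.

    ``plateau_fraction`` sets the fraction of the computed lag range (which
    defaults to one fifth of the series) averaged as the plateau.
    """
    u = np.asarray(u, dtype=float)
    norms = np.linalg.norm(u, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("bond vectors must be unit vectors")
    if len(u) < 100:
        raise ValueError("series too short for a plateau estimate")
    c = p2_autocorrelation(u, max_lag=max_lag)
    start = int(len(c) * (1.0 - plateau_fraction))
    return float(np.clip(np.mean(c[start:]), 0.0, 1.0))


def traj_dynamics(
    vectors: dict | None = None,
    coords: dict | None = None,
    plateau_fraction: float = 0.5,
) -> TrajectoryDynamics:
    """Compute per-residue RMSF (from coords) and/or S2 (from unit vectors).

    ``vectors``/``coords`` map residue id to an (nframes, 3) unit-vector
    series or an (nframes[, ndim]) coordinate series.
    """
    residues = sorted(set(vectors or {}) | set(coords or {}))
    if not residues:
        raise ValueError("no residues supplied")
    rows = []
    for res in residues:
        s2 = np.nan
        rf = np.nan
        if vectors and res in vectors:
            s2 = s2_from_vectors(np.asarray(vectors[res]), plateau_fraction)
        if coords and res in coords:
            rf = rmsf(np.asarray(coords[res]))
        rows.append({"residue": res, "rmsf": rf, "S2": s2})
    return TrajectoryDynamics(results=pd.DataFrame(rows))


def compare_s2(md: pd.DataFrame, nmr: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Mean absolute percentage deviation between simulated and
    experimental order parameters over the shared residues.

    ``md`` needs columns (residue, S2); ``nmr`` likewise (e.g. the
    model-free results table).  Returns (deviation_pct, per-residue table).
    """
    m = md[["residue", "S2"]].dropna().rename(columns={"S2": "S2_md"})
    n = nmr[["residue", "S2"]].dropna().rename(columns={"S2": "S2_nmr"})
    merged = m.merge(n, on="residue")
    if merged.empty:
        raise ValueError("no overlapping residues between MD and NMR tables")
    merged["abs_pct_dev"] = 100.0 * (merged["S2_md"] - merged["S2_nmr"]).abs() / merged["S2_nmr"]
    return float(merged["abs_pct_dev"].mean()), merged
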