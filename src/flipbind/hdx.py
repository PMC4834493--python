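"""Hydrogen/deuterium exchange: protection factors and local-unfolding
free energies.

In the EX2 limit the observed exchange rate of an amide is the intrinsic
(unstructured-chain) rate divided by the protection factor,

    P = k_intr / k_exch,      dG_unfold = RT ln P,

so a protection factor of 10^3-10^6 maps onto local-unfolding free
energies of roughly 4-8 kcal/mol at 298 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import T_HDX, kt


@dataclass(frozen=True)
class ExchangeFit:
    """Per-residue exchange fit; identity dG = RT ln P holds exactly."""

    results: pd.DataFrame  # residue, k_exch_min, k_intr_min, P, dG_unfold, flag
    temperature: float

    def summary(self) -> str:
        ok = self.results[self.results["flag"] == "ok"]
        return (
            f"H/D exchange at {self.temperature:.0f} K: {len(ok)}/{len(self.results)} "
            f"residues fit cleanly; dG_unfold {ok['dG_unfold'].min():.2f}-"
            f"{ok['dG_unfold'].max():.2f} kcal/mol"
        )


def protection_factor(k_intr: float, k_exch: float) -> float:
    if k_intr <= 0 or k_exch <= 0:
        raise ValueError("rates must be positive")
    return k_intr / k_exch


def unfolding_free_energy(p: float, temperature: float = T_HDX) -> float:
    """dG_unfold = RT ln P (kcal/mol)."""
    if p <= 0:
        raise ValueError("protection factor must be positive")
    return kt(temperature) * math.log(p)


def _fit_single_exponential(t, y):
    """Least squares of y = A exp(-k t); returns (A, k, rms)."""
    from scipy.optimize import curve_fit

    k0 = 1.0 / max(t[-1] / 3.0, 1e-9)
    span = y[0] - y[-1]
    if span > 0.1:
        # crude log-linear slope on the decaying part
        pos = y > 0.05
        if pos.sum() >= 2:
            k0 = max(
                (math.log(max(y[pos][0], 1e-9)) - math.log(max(y[pos][-1], 1e-9)))
                / max(t[pos][-1] - t[pos][0], 1e-9),
                1e-6,
            )
    popt, _ = curve_fit(
        lambda t, a, k: a * np.exp(-k * t), t, y, p0=[max(y[0], 0.5), k0], maxfev=20000
    )
    a, k = popt
    rms = float(np.sqrt(np.mean((y - a * np.exp(-k * t)) ** 2)))
    return float(a), float(k), rms


def hdx_fit(
    curves: pd.DataFrame,
    k_intr=None,
    temperature: float = T_HDX,
    exhausted_level: float = 0.05,
) -> ExchangeFit:
    """Fit every residue's exchange curve and derive P and dG_unfold.

    ``curves``: long table (residue, time_min, intensity[, k_intr_min]).
    ``k_intr``: per-residue intrinsic rates (min^-1) as a dict/Series;
    optional when the table carries a k_intr_min column.

    Flags: "exhausted" when the signal is already below ``exhausted_level``
    at the first timepoint (only a lower bound on k_exch, hence an upper
    bound on P); "no_decay" when the curve does not decay (P is a lower
    bound).
    """
    if k_intr is None:
        if "k_intr_min" not in curves.columns:
            raise ValueError("k_intr must be given or present as a k_intr_min column")
        k_intr = curves.groupby("residue")["k_intr_min"].first()
    k_intr = pd.Series(k_intr)
    if np.any(k_intr <= 0):
        raise ValueError("intrinsic rates must be positive")
    rows = []
    for res, grp in curves.groupby("residue"):
        t = grp["time_min"].to_numpy(dtype=float)
        y = grp["intensity"].to_numpy(dtype=float)
        if len(t) < 4:
            raise ValueError(f"residue {res}: need at least 4 timepoints")
        ki = float(k_intr.loc[res])
        if y[0] < exhausted_level:
            # fully exchanged before the first point: k >= ~3/t1
            k_lb = 3.0 / t[0]
            p = ki / k_lb
            rows.append((res, k_lb, ki, p, unfolding_free_energy(p, temperature), "exhausted"))
            continue
        a, k, rms = _fit_single_exponential(t, y)
        if k <= 0 or k * t[-1] < 0.05 or (y[0] - y[-1]) < 3.0 * max(rms, 1e-6):
            # no observable decay: k <= resolution limit over the window
            k_ub = math.log(2.0) / t[-1] / 2.0
            p = ki / k_ub
            rows.append((res, k_ub, ki, p, unfolding_free_energy(p, temperature), "no_decay"))
            continue
        p = ki / k
        rows.append((res, k, ki, p, unfolding_free_energy(p, temperature), "ok"))
    df = pd.DataFrame(
        rows, columns=["residue", "k_exch_min", "k_intr_min", "P", "dG_unfold", "flag"]
    )
    return ExchangeFit(results=df, temperature=temperature)


# ---------------------------------------------------------------------------
# simplified intrinsic (unstructured-chain) exchange rates
# ---------------------------------------------------------------------------

# Side-chain log10 factors for base-catalysed amide exchange, simplified to
# a single left/right pair per residue type.  These are coarse,
# order-of-magnitude values for generating and normalising *synthetic*
# exchange data, not a substitute for a full reference-table calculation;
# ground-truth tests always supply explicit k_intr values.
_BASE_FACTORS_L = {
    "A": 0.00, "C": 0.46, "D": 0.10, "E": -0.11, "F": -0.24, "G": 0.27,
    "H": 0.14, "I": -0.73, "K": -0.04, "L": -0.58, "M": -0.01, "N": 0.38,
    "P": 0.00, "Q": 0.20, "R": 0.08, "S": 0.37, "T": -0.07, "V": -0.70,
    "W": -0.41, "Y": -0.27,
}
_BASE_FACTORS_R = {
    "A": 0.00, "C": 0.62, "D": 0.69, "E": 0.31, "F": 0.06, "G": 0.17,
    "H": 0.20, "I": -0.23, "K": 0.12, "L": -0.13, "M": 0.11, "N": 0.58,
    "P": -0.24, "Q": 0.39, "R": 0.22, "S": 0.30, "T": 0.20, "V": -0.14,
    "W": -0.11, "Y": 0.05,
}


def intrinsic_rates(
    sequence: str,
    ph: float = 7.4,
    temperature: float = T_HDX,
    k_ref: float = 1.0e1,
) -> pd.Series:
    """Simplified sequence-based intrinsic exchange rates (min^-1).

    Base-catalysed regime only: k_intr(i) = k_ref * 10^(L(aa_i) + R(aa_{i-1}))
    * 10^(ph - 7.4) * Q10 temperature scaling (Q10 = 3).  The first residue
    and prolines have no exchangeable amide (rate = NaN).
    """
    q10 = 3.0 ** ((temperature - 298.0) / 10.0)
    rates = []
    for i, aa in enumerate(sequence):
        if i == 0 or aa == "P":
            rates.append(np.nan)
            continue
        left = _BASE_FACTORS_L.get(aa, 0.0)
        right = _BASE_FACTORS_R.get(sequence[i - 1], 0.0)
        rates.append(k_ref * 10.0 ** (left + right + (ph - 7.4)) * q10)
    return pd.Series(rates, index=np.arange(1, len(sequence) + 1), name="k_intr_min")
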