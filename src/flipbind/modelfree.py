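"""Lipari-Szabo model-free analysis of 15N backbone relaxation.

Forward model: isotropic overall tumbling with correlation time tau_c plus
fast internal motion of the N-H bond vector characterised by an order
parameter S^2 and an internal correlation time tau_e, giving the spectral
density

    J(w) = (2/5) [ S^2 tau_c / (1 + (w tau_c)^2)
                   + (1 - S^2) tau' / (1 + (w tau')^2) ],
    1/tau' = 1/tau_c + 1/tau_e.

R1, R2 and the heteronuclear NOE follow from the standard dipolar (N-H,
1.02 A) and CSA (-160 ppm) expressions; an exchange term Rex adds to R2.

The fit is two-stage: a global tau_c from the trimmed R2/R1 ratio of the
rigid subset, refined by minimising the pooled per-residue misfit, then
per-residue model selection among (S2), (S2, tau_e) and (S2, Rex).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

# gyromagnetic ratios (rad s^-1 T^-1), bond length (m), CSA (dimensionless)
GAMMA_H = 2.6752218744e8
GAMMA_N = -2.71261804e7
R_NH = 1.02e-10
CSA_N = -160e-6
MU0 = 4e-7 * math.pi
HBAR = 1.054571817e-34

MODEL_NAMES = {1: "S2", 2: "S2,te", 3: "S2,Rex"}


def _frequencies(field_mhz: float):
    """Angular frequencies (rad/s) of 1H and 15N at the given 1H field."""
    w_h = 2.0 * math.pi * field_mhz * 1e6
    b0 = w_h / GAMMA_H
    w_n = GAMMA_N * b0
    return w_h, w_n


def _interaction_constants(field_mhz: float):
    _, w_n = _frequencies(field_mhz)
    d = MU0 / (4.0 * math.pi) * HBAR * GAMMA_H * GAMMA_N / R_NH**3
    c = w_n * CSA_N / math.sqrt(3.0)
    return d, c


def spectral_density(w, s2, tc_s, te_s):
    """Model-free J(w); tc_s and te_s in seconds, w in rad/s."""
    w = np.asarray(w, dtype=float)
    j = s2 * tc_s / (1.0 + (w * tc_s) ** 2)
    if te_s > 0:
        tp = 1.0 / (1.0 / tc_s + 1.0 / te_s)
        j = j + (1.0 - s2) * tp / (1.0 + (w * tp) ** 2)
    return 0.4 * j


def relaxation_rates(s2, tc_ns, te_ps=0.0, rex=0.0, field_mhz=700.0):
    """(R1, R2, NOE) for one residue; tc in ns, te in ps, Rex in s^-1."""
    w_h, w_n = _frequencies(field_mhz)
    d, c = _interaction_constants(field_mhz)
    tc = tc_ns * 1e-9
    te = te_ps * 1e-12
    j = lambda w: spectral_density(w, s2, tc, te)
    j0 = j(0.0)
    jn = j(w_n)
    jh = j(w_h)
    jhmn = j(w_h - w_n)
    jhpn = j(w_h + w_n)
    r1 = d**2 / 4.0 * (jhmn + 3.0 * jn + 6.0 * jhpn) + c**2 * jn
    r2 = (
        d**2 / 8.0 * (4.0 * j0 + jhmn + 3.0 * jn + 6.0 * jh + 6.0 * jhpn)
        + c**2 / 6.0 * (4.0 * j0 + 3.0 * jn)
        + rex
    )
    noe = 1.0 + d**2 / 4.0 * (GAMMA_H / GAMMA_N) * (6.0 * jhpn - jhmn) / r1
    return float(r1), float(r2), float(noe)


@dataclass(frozen=True)
class RelaxationDataset:
    """Per-residue R1/R2/NOE with errors at one spectrometer field."""

    data: pd.DataFrame  # residue, R1, R2, NOE, R1_err, R2_err, NOE_err
    field_mhz: float

    def __post_init__(self):
        req = {"residue", "R1", "R2", "NOE"}
        if not req.issubset(self.data.columns):
            raise ValueError(f"relaxation table must have columns {sorted(req)}")
        if np.any(self.data["R1"] <= 0) or np.any(self.data["R2"] <= 0):
            raise ValueError("R1 and R2 must be positive")
        df = self.data.copy()
        for col, ref in (("R1_err", "R1"), ("R2_err", "R2"), ("NOE_err", "NOE")):
            if col not in df:
                df[col] = 0.02 * df[ref].abs().clip(lower=1e-3)
        # R2 < R1 is unphysical for slow tumbling: flag, don't reject
        df["r2_lt_r1_flag"] = df["R2"] < df["R1"]
        object.__setattr__(self, "data", df)

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class ModelFreeFit:
    tau_c_ns: float
    results: pd.DataFrame  # residue, S2, te_ps, Rex, model, chi2
    field_mhz: float

    @property
    def mean_s2(self) -> float:
        return float(self.results["S2"].mean())

    def summary(self) -> str:
        counts = self.results["model"].value_counts().to_dict()
        return (
            f"model-free fit at {self.field_mhz:.0f} MHz: tau_c = "
            f"{self.tau_c_ns:.2f} ns, <S2> = {self.mean_s2:.3f}, "
            f"models {counts}"
        )


def _ratio_tauc(r2_over_r1: float, field_mhz: float) -> float:
    """Solve R2/R1 for tau_c assuming a rigid residue (S2-independent)."""
    from scipy.optimize import brentq

    def g(tc_ns):
        r1, r2, _ = relaxation_rates(1.0, tc_ns, 0.0, 0.0, field_mhz)
        return r2 / r1 - r2_over_r1

    lo, hi = 0.5, 100.0
    if g(lo) > 0 or g(hi) < 0:
        raise ValueError("R2/R1 ratio outside the solvable tumbling range")
    return brentq(g, lo, hi, xtol=1e-6)


def _fit_residue(obs, err, tc_ns, field_mhz, model):
    """Chi-square fit of one residue for one model; returns params, chi2."""
    from scipy.optimize import least_squares

    obs = np.asarray(obs)
    err = np.asarray(err)

    def unpack(p):
        if model == 1:
            return float(np.clip(p[0], 0.0, 1.0)), 0.0, 0.0
        if model == 2:
            return float(np.clip(p[0], 0.0, 1.0)), float(abs(p[1])), 0.0
        return float(np.clip(p[0], 0.0, 1.0)), 0.0, float(abs(p[1]))

    def resid(p):
        s2, te, rex = unpack(p)
        calc = np.array(relaxation_rates(s2, tc_ns, te, rex, field_mhz))
        return (calc - obs) / err

    p0 = [0.85] if model == 1 else ([0.85, 30.0] if model == 2 else [0.85, 1.0])
    sol = least_squares(resid, p0, method="lm", xtol=1e-12, ftol=1e-12)
    s2, te, rex = unpack(sol.x)
    chi2 = float(np.sum(sol.fun**2))
    return s2, te, rex, chi2


def fit_modelfree(
    dataset: RelaxationDataset,
    noe_cutoff: float = 0.65,
    tc_bounds: tuple[float, float] = (2.0, 60.0),
    refine: bool = True,
) -> ModelFreeFit:
    """Two-stage model-free fit.

    Stage 1: per-residue tau_c from the R2/R1 ratio over the rigid subset
    (NOE above ``noe_cutoff``, ratio within one standard deviation of the
    10%-trimmed mean), averaged; optionally refined by minimising the
    pooled (S2, tau_e) misfit of that subset.  Stage 2: per-residue model
    selection among (S2), (S2, tau_e), (S2, Rex) by a small-sample
    information score chi^2 + 2k with ties broken toward the simpler model.
    """
    df = dataset.data
    if len(df) < 10:
        raise ValueError("need at least 10 residues for the global tau_c stage")
    ratio = (df["R2"] / df["R1"]).to_numpy()
    rigid = (df["NOE"] >= noe_cutoff).to_numpy()
    if rigid.sum() < 5:
        raise ValueError("tau_c unidentifiable: too few rigid residues")
    from scipy.stats import trim_mean

    r_trim = trim_mean(ratio[rigid], 0.1)
    r_sd = ratio[rigid].std(ddof=1)
    subset = rigid & (np.abs(ratio - r_trim) <= max(r_sd, 1e-9))
    if subset.sum() < 5:
        subset = rigid
    tcs = []
    for r in ratio[subset]:
        try:
            tcs.append(_ratio_tauc(r, dataset.field_mhz))
        except ValueError:
            continue
    if not tcs:
        raise ValueError("tau_c unidentifiable: no residue in the solvable range")
    tc0 = float(np.clip(np.mean(tcs), *tc_bounds))

    obs_all = df[["R1", "R2", "NOE"]].to_numpy()
    err_all = df[["R1_err", "R2_err", "NOE_err"]].to_numpy()
    err_all = np.clip(err_all, 1e-6, None)
    sub_idx = np.where(subset)[0]

    if refine:
        from scipy.optimize import minimize_scalar

        def pooled(tc):
            total = 0.0
            for i in sub_idx:
                _, _, _, chi2 = _fit_residue(obs_all[i], err_all[i], tc, dataset.field_mhz, 2)
                total += chi2
            return total

        lo = max(tc_bounds[0], 0.8 * tc0)
        hi = min(tc_bounds[1], 1.2 * tc0)
        res = minimize_scalar(pooled, bounds=(lo, hi), method="bounded", options={"xatol": 1e-3})
        tau_c = float(res.x)
    else:
        tau_c = tc0

    rows = []
    for i in range(len(df)):
        fits = {m: _fit_residue(obs_all[i], err_all[i], tau_c, dataset.field_mhz, m) for m in (1, 2, 3)}
        scores = {m: fits[m][3] + 2.0 * (1 if m == 1 else 2) for m in fits}
        best = min(scores, key=lambda m: (round(scores[m], 6), m))
        # parsimony: keep the simple model unless a complex one wins by > 2
        if best != 1 and scores[1] - scores[best] <= 2.0:
            best = 1
        s2, te, rex, chi2 = fits[best]
        rows.append(
            {
                "residue": df["residue"].iloc[i],
                "S2": s2,
                "te_ps": te if best == 2 else np.nan,
                "Rex": rex if best == 3 else 0.0,
                "model": MODEL_NAMES[best],
                "chi2": chi2,
            }
        )
    return ModelFreeFit(tau_c_ns=tau_c, results=pd.DataFrame(rows), field_mhz=dataset.field_mhz)


def r1r2_exchange_flag(dataset: RelaxationDataset, n_sd: float = 1.5):
    """Residues whose R1*R2 product flags us-ms exchange broadening.

    The product is compared against the 10%-trimmed mean plus ``n_sd``
    trimmed standard deviations; elevated products mark Rex candidates
    while depressed ones (high mobility) are left alone.
    """
    from scipy.stats import trim_mean

    df = dataset.data
    if len(df) < 5:
        raise ValueError("need at least 5 residues to estimate the R1R2 baseline")
    prod = (df["R1"] * df["R2"]).to_numpy()
    center = trim_mean(prod, 0.1)
    lo_q, hi_q = np.quantile(prod, [0.05, 0.95])
    core = prod[(prod >= lo_q) & (prod <= hi_q)]
    sd = core.std(ddof=1) if len(core) > 1 else 0.0
    if not np.isfinite(n_sd):
        return set()
    flagged = df.loc[prod > center + n_sd * sd, "residue"]
    return set(flagged.tolist())
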