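"""Chemical-shift perturbation mapping, spectral bookkeeping and CSI.

Shift tables are per-residue DataFrames with columns
(residue, aa, dH_ppm, dN_ppm, visible, assigned) for one state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

SHIFT_COLUMNS = ["residue", "aa", "dH_ppm", "dN_ppm", "visible", "assigned"]

#: default 15N weight in the combined perturbation
ALPHA_N = 0.15


def validate_shift_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SHIFT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"shift table missing columns {missing}")
    if (df["assigned"] & ~df["visible"]).any():
        raise ValueError("assigned residues must be visible")
    vis = df["visible"].to_numpy(dtype=bool)
    for col in ("dH_ppm", "dN_ppm"):
        if not np.all(np.isfinite(df.loc[vis, col].to_numpy(dtype=float))):
            raise ValueError(f"non-finite {col} for a visible residue")
    return df


@dataclass(frozen=True)
class CSPResult:
    table: pd.DataFrame  # residue, delta_ppm, signal_class
    report: dict  # bookkeeping block

    @property
    def appearing(self) -> set:
        return set(self.table.loc[self.table["signal_class"] == "appearing", "residue"])

    @property
    def disappearing(self) -> set:
        return set(self.table.loc[self.table["signal_class"] == "disappearing", "residue"])


def signal_bookkeeping(total: int, visible: int, assigned: int) -> dict:
    """Counts and percentages of the spectral bookkeeping block."""
    if not 0 <= assigned <= visible <= total:
        raise ValueError("need assigned <= visible <= total")
    pct = 100.0 * assigned / visible if visible else 0.0
    return {
        "total": int(total),
        "visible": int(visible),
        "assigned": int(assigned),
        "visible_pct_of_total": round(100.0 * visible / total, 1) if total else 0.0,
        "assigned_pct_of_visible": round(pct, 1),
        "assigned_pct_label": f"{pct:.0f}%",
    }


def csp(apo: pd.DataFrame, bound: pd.DataFrame, alpha: float = ALPHA_N) -> CSPResult:
    """Combined 1H/15N perturbation and signal-class report.

    delta = sqrt(ddH^2 + (alpha * ddN)^2) for residues visible in both
    states; residues are classed as appearing (invisible -> visible),
    disappearing, or unchanged.  The report carries the apo bookkeeping
    (total / visible / assigned counts and percentages).
    """
    validate_shift_table(apo)
    validate_shift_table(bound)
    if len(apo) != len(bound) or not np.array_equal(
        apo["residue"].to_numpy(), bound["residue"].to_numpy()
    ):
        a = apo["residue"].to_numpy()
        b = bound["residue"].to_numpy()
        n = min(len(a), len(b))
        mismatch = next((i for i in range(n) if a[i] != b[i]), n)
        first = a[mismatch] if mismatch < len(a) else b[mismatch]
        raise ValueError(f"residue numbering mismatch starting at residue {first}")
    both = apo["visible"].to_numpy() & bound["visible"].to_numpy()
    ddh = bound["dH_ppm"].to_numpy() - apo["dH_ppm"].to_numpy()
    ddn = bound["dN_ppm"].to_numpy() - apo["dN_ppm"].to_numpy()
    delta = np.where(both, np.sqrt(ddh**2 + (alpha * ddn) ** 2), np.nan)
    cls = np.where(
        ~apo["visible"] & bound["visible"],
        "appearing",
        np.where(apo["visible"] & ~bound["visible"], "disappearing", "unchanged"),
    )
    table = pd.DataFrame(
        {"residue": apo["residue"], "delta_ppm": delta, "signal_class": cls}
    )
    report = {
        "apo": signal_bookkeeping(
            len(apo), int(apo["visible"].sum()), int(apo["assigned"].sum())
        ),
        "bound": signal_bookkeeping(
            len(bound), int(bound["visible"].sum()), int(bound["assigned"].sum())
        ),
        "n_appearing": int((cls == "appearing").sum()),
        "n_disappearing": int((cls == "disappearing").sum()),
    }
    return CSPResult(table=table, report=report)


def csi(
    shifts: pd.DataFrame,
    random_coil: pd.DataFrame,
    threshold: float = 0.7,
    shift_col: str = "dH_ppm",
) -> pd.DataFrame:
    """Three-level chemical shift index against random-coil references.

    ``random_coil`` maps amino-acid type to a reference shift (columns
    aa, ``shift_col``).  Secondary shift = observed - reference; index is
    +1 / -1 beyond +-threshold, else 0.  Residues whose type is missing
    from the reference are skipped with a warning.
    """
    ref = dict(zip(random_coil["aa"], random_coil[shift_col]))
    rows = []
    skipped = []
    for _, r in shifts.iterrows():
        if not r.get("visible", True):
            continue
        if r["aa"] not in ref:
            skipped.append(r["aa"])
            continue
        sec = float(r[shift_col]) - float(ref[r["aa"]])
        idx = 1 if sec > threshold else (-1 if sec < -threshold else 0)
        rows.append({"residue": r["residue"], "secondary_shift": sec, "csi": idx})
    if skipped:
        warnings.warn(f"no random-coil reference for residue types {sorted(set(skipped))}")
    return pd.DataFrame(rows, columns=["residue", "secondary_shift", "csi"])


def read_shift_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_shift_table(df)


def write_shift_table(df: pd.DataFrame, path) -> None:
    validate_shift_table(df).to_csv(path, sep="\t", index=False)


def read_nmrstar_shifts(path) -> pd.DataFrame:
    """Minimal reader for an NMR-STAR chemical-shift loop (H/N amides).

    Parses Atom_chem_shift loops of the kind deposited with backbone
    assignments; returns a shift table with every parsed residue marked
    visible and assigned.  Only _Atom_chem_shift.* tags are understood.
    """
    tags = []
    rows = []
    in_loop = False
    with open(path) as fh:
        for line in fh:
            ls = line.strip()
            if ls == "loop_":
                in_loop = True
                tags = []
                continue
            if in_loop and ls.startswith("_Atom_chem_shift."):
                tags.append(ls.split(".", 1)[1])
                continue
            if in_loop and tags:
                if ls in ("stop_", "") or ls.startswith("_"):
                    if ls == "stop_":
                        in_loop = False
                    continue
                parts = ls.split()
                if len(parts) == len(tags):
                    rows.append(dict(zip(tags, parts)))
    if not rows:
        raise ValueError("no _Atom_chem_shift loop found")
    raw = pd.DataFrame(rows)
    need = {"Seq_ID", "Comp_ID", "Atom_ID", "Val"}
    if not need.issubset(raw.columns):
        raise ValueError(f"chemical-shift loop lacks tags {sorted(need - set(raw.columns))}")
    raw = raw[raw["Atom_ID"].isin(["H", "N"])]
    out = {}
    for _, r in raw.iterrows():
        res = int(r["Seq_ID"])
        rec = out.setdefault(res, {"residue": res, "aa": r["Comp_ID"][0], "dH_ppm": np.nan, "dN_ppm": np.nan})
        rec["dH_ppm" if r["Atom_ID"] == "H" else "dN_ppm"] = float(r["Val"])
    df = pd.DataFrame(sorted(out.values(), key=lambda d: d["residue"]))
    df["visible"] = True
    df["assigned"] = True
    return validate_shift_table(df)
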