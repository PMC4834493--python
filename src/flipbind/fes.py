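"""Gridded free-energy profile F(s) with per-bin uncertainty."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class FreeEnergyProfile:
    """F(s) on a strictly increasing grid, shifted so min(F) = 0."""

    grid: np.ndarray
    F: np.ndarray
    err: np.ndarray | None = None

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        f = np.asarray(self.F, dtype=float)
        if grid.ndim != 1 or grid.shape != f.shape:
            raise ValueError("grid and F must be 1D arrays of equal length")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        f = f - f.min()
        err = self.err
        if err is not None:
            err = np.asarray(err, dtype=float)
            if err.shape != f.shape:
                raise ValueError("err must match the grid shape")
            if np.any(err < 0):
                raise ValueError("uncertainties must be non-negative")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "F", f)
        object.__setattr__(self, "err", err)

    @classmethod
    def from_landscape(cls, landscape, grid=None, spacing: float = 0.01):
        """Exact profile of a 1D toy landscape (F(s) = U(s) - min U)."""
        if grid is None:
            lo, hi = landscape.domain
            grid = np.arange(lo, hi + spacing, spacing)
        grid = np.asarray(grid, dtype=float)
        return cls(grid=grid, F=landscape.potential(grid))

    def value_at(self, s: float) -> float:
        return float(np.interp(s, self.grid, self.F))

    def err_at(self, s: float) -> float:
        if self.err is None:
            return 0.0
        return float(np.interp(s, self.grid, self.err))

    def shifted(self, offset: float) -> "FreeEnergyProfile":
        """Adding a constant is a gauge transformation: the stored profile
        is re-anchored at min(F)=0, so this returns an identical object by
        construction (kept for explicitness in gauge-invariance tests)."""
        return FreeEnergyProfile(self.grid, self.F + offset, self.err)

    def to_frame(self):
        import pandas as pd

        data = {"s": self.grid, "F_kcal_mol": self.F}
        data["err_kcal_mol"] = self.err if self.err is not None else np.zeros_like(self.F)
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "FreeEnergyProfile":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        err = df["err_kcal_mol"].to_numpy() if "err_kcal_mol" in df else None
        return cls(grid=df["s"].to_numpy(), F=df["F_kcal_mol"].to_numpy(), err=err)
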