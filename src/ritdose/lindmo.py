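"""Cell-binding assay reduction and Lindmo immunoreactive-fraction fit.

In the Lindmo assay a fixed trace of radiolabeled antibody is incubated with
serially diluted cell suspensions.  Under the binding model
bound/applied = IRF * q c / (1 + q c), the double-reciprocal transform

    applied/bound = 1/IRF + (1/(IRF q)) * (1/c)

is linear in 1/c, and the immunoreactive fraction (IRF) -- the fraction of
labeled antibody able to bind at infinite antigen excess -- is the inverse
of the intercept.  Classical unweighted OLS on the transformed duplicate
means is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decay import InvalidDataError


@dataclass
class LindmoAssay:
    """One binding assay: per-tube cell concentration, applied and bound activity."""

    cell_conc_per_ml: np.ndarray
    applied: np.ndarray
    bound: np.ndarray
    replicate: np.ndarray

    def __post_init__(self) -> None:
        self.cell_conc_per_ml = np.asarray(self.cell_conc_per_ml, dtype=float)
        self.applied = np.asarray(self.applied, dtype=float)
        self.bound = np.asarray(self.bound, dtype=float)
        self.replicate = np.asarray(self.replicate, dtype=int)
        n = self.cell_conc_per_ml.size
        if not (self.applied.size == self.bound.size == self.replicate.size == n):
            raise InvalidDataError("assay columns must have equal length")
        if np.any(self.cell_conc_per_ml <= 0):
            raise InvalidDataError("cell concentrations must be > 0")
        if np.any(self.applied <= 0):
            raise InvalidDataError("applied activity must be > 0")
        if np.any(self.bound < 0) or np.any(self.bound > self.applied):
            raise InvalidDataError("need 0 <= bound <= applied")
        if np.unique(self.cell_conc_per_ml).size < 3:
            raise InvalidDataError("need >= 3 distinct cell concentrations for fitting")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_conc_per_ml": self.cell_conc_per_ml,
                "applied_counts": self.applied,
                "bound_counts": self.bound,
                "replicate": self.replicate,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LindmoAssay":
        df = pd.read_csv(path, comment="#")
        required = {"cell_conc_per_ml", "applied_counts", "bound_counts", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidDataError(f"assay CSV missing columns: {sorted(missing)}")
        return cls(
            cell_conc_per_ml=df["cell_conc_per_ml"].to_numpy(),
            applied=df["applied_counts"].to_numpy(),
            bound=df["bound_counts"].to_numpy(),
            replicate=df["replicate"].to_numpy(),
        )


def bound_fractions(assay: LindmoAssay) -> pd.DataFrame:
    """Replicate-averaged bound/applied fraction per cell concentration."""
    df = assay.to_frame()
    df["fraction"] = df["bound_counts"] / df["applied_counts"]
    out = (
        df.groupby("cell_conc_per_ml")["fraction"]
        .mean()
        .reset_index()
        .sort_values("cell_conc_per_ml", ascending=False)
        .reset_index(drop=True)
    )
    return out


@dataclass(frozen=True)
class LindmoFit:
    immunoreactive_fraction: float
    slope: float
    intercept: float
    r_squared: float
    intercept_stderr: float


def lindmo_fit(assay: LindmoAssay) -> LindmoFit:
    """Immunoreactive fraction by double-reciprocal extrapolation.

    Per-tube applied/bound values are averaged over replicates after the
    transform, then regressed against 1/cell_conc by unweighted OLS; the IRF
    is 1/intercept.  A non-positive fitted intercept (no finite extrapolated
    binding) raises ``InvalidDataError``.
    """
    if np.any(assay.bound <= 0):
        raise InvalidDataError("all bound activities must be > 0 for the Lindmo transform")
    df = assay.to_frame()
    df["inv_fraction"] = df["applied_counts"] / df["bound_counts"]
    mean_y = df.groupby("cell_conc_per_ml")["inv_fraction"].mean()
    x = 1.0 / mean_y.index.to_numpy()
    y = mean_y.to_numpy()
    res = stats.linregress(x, y)
    if res.intercept <= 0:
        raise InvalidDataError(
            f"degenerate Lindmo fit: non-positive intercept {res.intercept:.4g}"
        )
    return LindmoFit(
        immunoreactive_fraction=1.0 / res.intercept,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        intercept_stderr=float(res.intercept_stderr),
    )
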