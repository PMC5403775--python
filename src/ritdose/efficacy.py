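"""Efficacy statistics: tumor-free fractions, exact 2x2 inference, hematology.

The tumor-free fraction (TFF) of a treatment group is the fraction of
evaluable animals with no macroscopic or microscopic tumors and no ascites
at necropsy.  Counts follow the nesting convention: animals with macroscopic
tumors are included in the microscopic-tumor count, and ascites animals are
assumed tumor-bearing (so the tumor-bearing count is the microscopic count,
extended only if ascites animals outnumber it).

Fisher's exact test is implemented from first principles: the two-sided
p-value sums the hypergeometric point probabilities of every table with the
observed margins whose probability does not exceed the observed one
(minimum-likelihood rule, with a 1 + 1e-7 relative guard against float ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decay import InvalidDataError


@dataclass(frozen=True)
class GroupOutcome:
    """Necropsy outcome counts for one treatment group."""

    group: str
    n_evaluable: int
    n_macro: int
    n_micro: int
    n_ascites: int

    def __post_init__(self) -> None:
        if self.n_evaluable < 0:
            raise InvalidDataError("n_evaluable must be >= 0")
        if not 0 <= self.n_macro <= self.n_micro <= self.n_evaluable:
            raise InvalidDataError(
                f"need 0 <= n_macro <= n_micro <= n_evaluable, got "
                f"{self.n_macro}/{self.n_micro}/{self.n_evaluable}"
            )
        if not 0 <= self.n_ascites <= self.n_evaluable:
            raise InvalidDataError("n_ascites must be in [0, n_evaluable]")

    @property
    def n_tumor_bearing(self) -> int:
        """Micro count (macro nested inside) extended by any excess ascites animals."""
        return max(self.n_micro, self.n_ascites)

    @property
    def n_tumor_free(self) -> int:
        return self.n_evaluable - self.n_tumor_bearing


def tumor_free_fraction(outcome: GroupOutcome) -> float:
    """Fraction of evaluable animals free of tumors and ascites."""
    if outcome.n_evaluable == 0:
        raise InvalidDataError("tumor-free fraction undefined for n_evaluable = 0")
    return outcome.n_tumor_free / outcome.n_evaluable


def study_outcome_table() -> list[GroupOutcome]:
    """Necropsy counts of the Bi-213-MX35 ovarian-cancer mouse study.

    Three groups: 3 MBq/mL (n=20), 9 MBq/mL (n=18 evaluable; two animals
    excluded), and an unlabeled-antibody control (n=20).
    """
    return [
        GroupOutcome("Bi213-MX35 3 MBq/mL", 20, 4, 9, 0),
        GroupOutcome("Bi213-MX35 9 MBq/mL", 18, 1, 4, 0),
        GroupOutcome("cold MX35 control", 20, 7, 17, 4),
    ]


def outcomes_to_frame(outcomes: list[GroupOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": o.group,
                "n_evaluable": o.n_evaluable,
                "n_macro": o.n_macro,
                "n_micro": o.n_micro,
                "n_ascites": o.n_ascites,
            }
            for o in outcomes
        ]
    )


def outcomes_from_frame(df: pd.DataFrame) -> list[GroupOutcome]:
    required = {"group", "n_evaluable", "n_macro", "n_micro", "n_ascites"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidDataError(f"outcome table missing columns: {sorted(missing)}")
    return [
        GroupOutcome(
            str(r.group),
            int(r.n_evaluable),
            int(r.n_macro),
            int(r.n_micro),
            int(r.n_ascites),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Exact 2x2 inference
# ---------------------------------------------------------------------------

_TIE_GUARD = 1.0 + 1e-7


def _hypergeom_pmf(k: int, r1: int, r2: int, c1: int) -> float:
    """P(X = k) for the number of column-1 successes in row 1, fixed margins."""
    return math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(r1 + r2, c1)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test p-value of the table [[a, b], [c, d]].

    Degenerate margins (an empty row or column) give p = 1 by definition.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise InvalidDataError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    c1 = a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or b + d == 0:
        return 1.0
    p_obs = _hypergeom_pmf(a, r1, r2, c1)
    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    total = 0.0
    for k in range(k_min, k_max + 1):
        p_k = _hypergeom_pmf(k, r1, r2, c1)
        if p_k <= p_obs * _TIE_GUARD:
            total += p_k
    return min(total, 1.0)


def pairwise_fisher(outcomes: list[GroupOutcome]) -> pd.DataFrame:
    """All pairwise two-sided exact tests on tumor-free vs tumor-bearing counts."""
    rows = []
    for i in range(len(outcomes)):
        for j in range(i + 1, len(outcomes)):
            gi, gj = outcomes[i], outcomes[j]
            p = fisher_exact_two_sided(
                gi.n_tumor_free, gi.n_tumor_bearing, gj.n_tumor_free, gj.n_tumor_bearing
            )
            rows.append({"group_a": gi.group, "group_b": gj.group, "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hematology summaries
# ---------------------------------------------------------------------------

def hematology_summary(series: pd.DataFrame) -> pd.DataFrame:
    """Per-group, per-day mean and SEM of blood counts, plus day-6 -> 14 change.

    Expects columns ``animal, group, day, wbc_e9_per_l, platelets_e9_per_l``
    with day in {6, 14}.  SEM is sd/sqrt(n) with the population standard
    deviation.  Percent change is 100*(mean14 - mean6)/mean6 per analyte; a
    missing day leaves the change as NaN rather than erroring.
    """
    required = {"animal", "group", "day", "wbc_e9_per_l", "platelets_e9_per_l"}
    missing = required - set(series.columns)
    if missing:
        raise InvalidDataError(f"hematology table missing columns: {sorted(missing)}")
    if np.any(series[["wbc_e9_per_l", "platelets_e9_per_l"]].to_numpy() < 0):
        raise InvalidDataError("blood counts must be >= 0")

    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=0) / math.sqrt(len(x))) if len(x) > 1 else 0.0

    agg = (
        series.groupby(["group", "day"])
        .agg(
            n=("animal", "count"),
            wbc_mean=("wbc_e9_per_l", "mean"),
            wbc_sem=("wbc_e9_per_l", _sem),
            platelets_mean=("platelets_e9_per_l", "mean"),
            platelets_sem=("platelets_e9_per_l", _sem),
        )
        .reset_index()
    )
    for analyte in ("wbc", "platelets"):
        pivot = agg.pivot(index="group", columns="day", values=f"{analyte}_mean")
        if 6 in pivot.columns and 14 in pivot.columns:
            change = 100.0 * (pivot[14] - pivot[6]) / pivot[6]
        else:
            change = pd.Series(np.nan, index=pivot.index)
        agg = agg.merge(
            change.rename(f"{analyte}_pct_change_6_to_14"), left_on="group", right_index=True
        )
    return agg
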