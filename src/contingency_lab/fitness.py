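"""Fitness from serial-transfer competition assays.

Two marker-distinguishable strains are mixed, diluted (100-fold per day by
default) into the competition environment, and colony counts taken at the
start and end of ``d`` days.  The absolute (Malthusian) fitness of
competitor a is

    w_a = ln(dilution^d * N_a(f) / N_a(i)),

the natural log of its net fold-expansion including the growth required to
offset dilution.  Relative fitness is w_a/b = w_a / w_b and the selective
advantage s = w_a/b - 1.  Counts may be raw colonies or dilution-adjusted
densities; only within-competitor ratios enter the formula, but initial and
final counts must refer to a common effective plated volume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "CompetitionAssay",
    "FitnessResult",
    "absolute_fitness",
    "relative_fitness",
    "batch_fitness",
]


@dataclass(frozen=True)
class CompetitionAssay:
    """Counts (or common-volume densities) for one replicate competition."""

    n_a_initial: float
    n_a_final: float
    n_b_initial: float
    n_b_final: float
    d: int = 1
    dilution: float = 100.0

    def __post_init__(self) -> None:
        if self.d < 1 or int(self.d) != self.d:
            raise ValueError(f"d (competition days) must be a positive integer, got {self.d}")
        if self.dilution <= 1:
            raise ValueError(f"dilution must exceed 1, got {self.dilution}")
        for name in ("n_a_initial", "n_a_final", "n_b_initial", "n_b_final"):
            val = getattr(self, name)
            if val == 0 and name.endswith("final"):
                raise ValueError(f"{name} = 0: competitor went extinct (or below detection); "
                                 "fitness is undefined for this replicate")
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")


@dataclass(frozen=True)
class FitnessResult:
    """Absolute fitnesses, their ratio, and the selective advantage s."""

    w_a: float
    w_b: float
    w_rel: float
    s: float


def absolute_fitness(n_i: float, n_f: float, d: int = 1, dilution: float = 100.0) -> float:
    """Malthusian fitness ln(dilution^d * n_f / n_i) over d transfer days."""
    if d < 1 or int(d) != d:
        raise ValueError(f"d must be a positive integer, got {d}")
    if n_f == 0:
        raise ValueError("final count is zero: competitor extinct, fitness undefined")
    if n_i <= 0 or n_f < 0:
        raise ValueError(f"counts must be positive, got n_i={n_i}, n_f={n_f}")
    return d * math.log(dilution) + math.log(n_f / n_i)


def relative_fitness(assay: CompetitionAssay) -> FitnessResult:
    """Relative fitness of competitor a versus b from one assay."""
    w_a = absolute_fitness(assay.n_a_initial, assay.n_a_final, assay.d, assay.dilution)
    w_b = absolute_fitness(assay.n_b_initial, assay.n_b_final, assay.d, assay.dilution)
    if abs(w_b) < 1e-12:
        raise ValueError("reference competitor has zero Malthusian fitness: "
                         "relative fitness undefined")
    w_rel = w_a / w_b
    return FitnessResult(w_a=w_a, w_b=w_b, w_rel=w_rel, s=w_rel - 1.0)


def batch_fitness(table: pd.DataFrame) -> pd.DataFrame:
    """Per-pair mean relative fitness with t-based 95% CIs.

    Expects one replicate per row with columns ``pair_id, n_a_initial,
    n_a_final, n_b_initial, n_b_final, d`` (optional ``dilution``).
    Replicates with an extinct competitor are flagged and excluded.
    Returns one row per pair: mean w_rel, mean s, 95% CI bounds (NaN with a
    warning when only a single usable replicate exists) and counts of used
    and excluded replicates.
    """
    required = {"pair_id", "n_a_initial", "n_a_final", "n_b_initial", "n_b_final", "d"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for pair_id, grp in table.groupby("pair_id", sort=True):
        w_vals, excluded = [], 0
        for _, row in grp.iterrows():
            try:
                assay = CompetitionAssay(
                    n_a_initial=row["n_a_initial"], n_a_final=row["n_a_final"],
                    n_b_initial=row["n_b_initial"], n_b_final=row["n_b_final"],
                    d=int(row["d"]), dilution=float(row.get("dilution", 100.0)),
                )
                w_vals.append(relative_fitness(assay).w_rel)
            except ValueError as err:
                excluded += 1
                warnings.warn(f"pair {pair_id}: replicate excluded ({err})",
                              UserWarning, stacklevel=2)
        if not w_vals:
            rows.append({"pair_id": pair_id, "n": 0, "n_excluded": excluded,
                         "w_rel_mean": np.nan, "s_mean": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan})
            continue
        w = np.asarray(w_vals)
        mean = float(w.mean())
        if w.size >= 2:
            sd = float(w.std(ddof=1))
            half = _st.t.ppf(0.975, w.size - 1) * sd / math.sqrt(w.size)
        else:
            warnings.warn(f"pair {pair_id}: single replicate, CI not available",
                          UserWarning, stacklevel=2)
            half = np.nan
        rows.append({"pair_id": pair_id, "n": int(w.size), "n_excluded": excluded,
                     "w_rel_mean": mean, "s_mean": mean - 1.0,
                     "ci_low": mean - half, "ci_high": mean + half})
    return pd.DataFrame(rows)
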