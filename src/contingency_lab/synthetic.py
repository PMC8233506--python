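"""Synthetic laboratory-shaped inputs for every downstream module.

Generates, with the statistical structure the analyses assume:

* plate-reader OD growth curves (Baranyi-Roberts trajectory + additive
  Gaussian noise truncated at zero, readings every few minutes);
* fluctuation-assay mutant counts (Luria-Delbruck branching construction:
  binomial mutation seeding at each doubling of the expanding culture,
  deterministic doubling of mutant clones);
* two-strain competition plate counts whose fitness-estimator expectation
  is a chosen relative fitness;
* clone-by-locus mutation incidence tables with tunable within-group and
  shared-between-group structure.

All generators take an explicit seed and are bit-reproducible; none uses
global random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .fitness import CompetitionAssay
from .growth import GrowthParams, br_trajectory
from .similarity import MutationProfile

__all__ = [
    "NoiseModel",
    "gen_growth_curve",
    "gen_fluctuation_counts",
    "gen_competition_counts",
    "gen_mutation_profiles",
    "save_table",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings for the generators.

    od_sd           additive SD on OD readings (OD units), truncated so
                    readings stay non-negative
    count_sampling  'multinomial' or 'poisson' plating noise, or 'none'
    """

    od_sd: float = 0.0
    count_sampling: str = "multinomial"

    def __post_init__(self) -> None:
        if self.od_sd < 0:
            raise ValueError(f"od_sd must be non-negative, got {self.od_sd}")
        if self.count_sampling not in ("multinomial", "poisson", "none"):
            raise ValueError(f"unknown count_sampling {self.count_sampling!r}")


def gen_growth_curve(params: GrowthParams, horizon: float, interval: float,
                     noise: NoiseModel = NoiseModel(), seed=0) -> pd.DataFrame:
    """Simulated plate-reader curve: readings every ``interval`` minutes.

    horizon is in hours, interval in minutes; readings run t = 0,
    interval, 2*interval, ... <= horizon.  Returns a tidy DataFrame with
    columns ``time_h`` and ``od``.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    if interval <= 0:
        raise ValueError(f"interval must be positive, got {interval}")
    n_steps = int(math.floor(horizon * 60.0 / interval + 1e-9))
    t = np.arange(n_steps + 1) * (interval / 60.0)
    od = br_trajectory(params, t)
    if noise.od_sd > 0:
        rng = np.random.default_rng(seed)
        od = np.maximum(od + rng.normal(0.0, noise.od_sd, size=od.shape), 0.0)
    return pd.DataFrame({"time_h": t, "od": od})


def gen_fluctuation_counts(rate: float, n_final: int, n_cultures: int,
                           seed=0) -> np.ndarray:
    """Mutant counts per culture under the Luria-Delbruck branching model.

    Each culture expands by doublings from a single cell to ~n_final cells.
    At each doubling step, every newly created wild-type cell mutates with
    probability ``rate``; a mutant arising when the culture has n cells
    leaves n_final / n descendants (deterministic doubling of mutant
    clones).  The expected number of mutation events per culture is
    m ~= rate * n_final, and P(count = 0) ~= exp(-m).
    """
    if not 0 <= rate < 1:
        raise ValueError(f"rate must lie in [0, 1), got {rate}")
    if n_final < 1:
        raise ValueError(f"n_final must be >= 1, got {n_final}")
    if n_cultures < 1:
        raise ValueError(f"n_cultures must be >= 1, got {n_cultures}")
    rng = np.random.default_rng(seed)
    n_gen = max(1, int(round(math.log2(n_final))))
    counts = np.zeros(n_cultures, dtype=np.int64)
    if rate == 0.0:
        return counts
    # new wild-type cells created at doubling step g (population 2^g after it)
    new_cells = np.array([n_final * 2.0 ** (g - n_gen) / 2.0 for g in range(1, n_gen + 1)])
    new_cells = np.maximum(np.round(new_cells).astype(np.int64), 0)
    clone_sizes = np.array([max(1, int(round(n_final / 2.0 ** g)))
                            for g in range(1, n_gen + 1)], dtype=np.int64)
    for i in range(n_cultures):
        mutants = rng.binomial(new_cells, rate)
        counts[i] = int(np.dot(mutants, clone_sizes))
    return counts


def gen_competition_counts(w_ratio: float, n_plated_initial: int,
                           n_plated_final: int, d: int = 1, seed=0,
                           noise: NoiseModel = NoiseModel(),
                           dilution: float = 100.0) -> CompetitionAssay:
    """Plate counts from a two-strain competition with known relative fitness.

    The reference competitor b regrows exactly to the pre-dilution density
    each day (Malthusian fitness d*ln(dilution)); competitor a's
    deterministic trajectory is set so that w_a / w_b = w_ratio.  Counts
    are sampled around the implied colony frequencies (multinomial or
    Poisson per ``noise.count_sampling``; 'none' gives expected counts) and
    final counts are rescaled to the initial effective plated volume, so
    the four entries are directly comparable densities.
    """
    if w_ratio <= 0:
        raise ValueError(f"w_ratio must be positive, got {w_ratio}")
    if d < 1 or int(d) != d:
        raise ValueError(f"d must be a positive integer (days), got {d}")
    if n_plated_initial < 1 or n_plated_final < 1:
        raise ValueError("plated counts must be >= 1")
    rng = np.random.default_rng(seed)
    w_b = d * math.log(dilution)
    w_a = w_ratio * w_b
    # density ratios across the competition (per unit initial density)
    ratio_a = math.exp(w_a) / dilution ** d
    ratio_b = 1.0
    d_ai = d_bi = 0.5
    d_af, d_bf = d_ai * ratio_a, d_bi * ratio_b
    p_init = np.array([0.5, 0.5])
    p_fin = np.array([d_af, d_bf]) / (d_af + d_bf)
    if noise.count_sampling == "none":
        c_init = p_init * n_plated_initial
        c_fin = p_fin * n_plated_final
    elif noise.count_sampling == "poisson":
        c_init = rng.poisson(p_init * n_plated_initial).astype(float)
        c_fin = rng.poisson(p_fin * n_plated_final).astype(float)
    else:
        c_init = rng.multinomial(n_plated_initial, p_init).astype(float)
        c_fin = rng.multinomial(n_plated_final, p_fin).astype(float)
    if np.any(c_init == 0) or np.any(c_fin == 0):
        raise RuntimeError("sampling produced a zero count; increase plated counts")
    # rescale final counts to the initial plated volume so counts are densities
    vol_init = n_plated_initial / (d_ai + d_bi)
    vol_fin = n_plated_final / (d_af + d_bf)
    c_fin = c_fin * (vol_init / vol_fin)
    return CompetitionAssay(n_a_initial=float(c_init[0]), n_a_final=float(c_fin[0]),
                            n_b_initial=float(c_init[1]), n_b_final=float(c_fin[1]),
                            d=d, dilution=dilution)


def gen_mutation_profiles(n_group_a: int, n_group_b: int, pool_size: int,
                          p_within: float, p_shared: float, seed=0,
                          n_private: int = 0, marker_fraction: float = 0.5,
                          group_a: str = "A", group_b: str = "B") -> list[MutationProfile]:
    """Clone-by-locus incidence tables with tunable group structure.

    For each pool locus and each group, a group marker M ~ Bernoulli(
    ``marker_fraction``) is drawn; a clone then carries the locus
    independently with probability p_within when its group's marker is set
    and p_shared otherwise.  Within-group pairs share their marker vector,
    so for p_within != p_shared the expected within-group overlap,
    pool_size * (f p_within^2 + (1-f) p_shared^2), exceeds the
    between-group overlap pool_size * (f p_within + (1-f) p_shared)^2 by
    Jensen's inequality (f = marker_fraction).  With p_within == p_shared
    all clones are i.i.d. regardless of label, giving an exchangeable null.
    ``n_private`` adds that many loci unique to each clone.
    """
    if n_group_a < 1 or n_group_b < 1:
        raise ValueError("both groups need at least one clone")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    for name, p in (("p_within", p_within), ("p_shared", p_shared),
                    ("marker_fraction", marker_fraction)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    markers = {group_a: rng.random(pool_size) < marker_fraction,
               group_b: rng.random(pool_size) < marker_fraction}
    if p_within == p_shared:
        # exchangeable null: identical inclusion probability everywhere
        markers = {g: np.zeros(pool_size, dtype=bool) for g in markers}
        p_within = p_shared
    profiles = []
    private_counter = 0
    for group, n_clones in ((group_a, n_group_a), (group_b, n_group_b)):
        probs = np.where(markers[group], p_within, p_shared)
        for c in range(n_clones):
            carried = np.nonzero(rng.random(pool_size) < probs)[0]
            loci = {f"locus{j:04d}" for j in carried}
            for _ in range(n_private):
                loci.add(f"private{private_counter:05d}")
                private_counter += 1
            profiles.append(MutationProfile(clone_id=f"{group}{c + 1}",
                                            group=group, loci=frozenset(loci)))
    return profiles


def save_table(df: pd.DataFrame, path, params: dict, seed) -> None:
    """Write a generated table as tidy CSV with a JSON parameter sidecar."""
    path = Path(path)
    df.to_csv(path, index=False)
    sidecar = {"seed": seed, "params": {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
                                        for k, v in params.items()}}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
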