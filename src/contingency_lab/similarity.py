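"""Parallelism of mutation sets between evolved clones.

Compares the sets of mutated loci carried by sequenced clones using the
Sorensen-Dice coefficient, 2|A n B| / (|A| + |B|): 0 for completely
dissimilar sets, 1 for identical ones.  Group structure (e.g. populations
that did vs did not fix the focal allele) is assessed by comparing mean
pairwise similarity within each group and between groups against a null
built by randomly reassigning clones to group labels while preserving
group sizes.

Loci are matched by identifier; callers choosing gene-level labels get
gene-granularity matching (two different substitutions in the same gene
count as shared), while position-level identifiers give site granularity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MutationProfile",
    "GroupSimilarity",
    "SimilarityResult",
    "dice",
    "group_mean_similarity",
    "permutation_test",
]


@dataclass(frozen=True)
class MutationProfile:
    """Set of mutated loci observed in one sequenced clone."""

    clone_id: str
    group: str
    loci: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", frozenset(self.loci))


def dice(a, b) -> float:
    """Sorensen-Dice similarity 2|a n b| / (|a| + |b|) between two locus sets."""
    a, b = frozenset(a), frozenset(b)
    if not a and not b:
        raise ValueError("Dice similarity is undefined for two empty sets")
    return 2.0 * len(a & b) / (len(a) + len(b))


def _pairwise_matrix(profiles) -> np.ndarray:
    """Dense pairwise Dice matrix; both-empty pairs are NaN (undefined)."""
    universe = sorted(set().union(*(p.loci for p in profiles)) or {None})
    idx = {locus: j for j, locus in enumerate(universe)}
    m = np.zeros((len(profiles), len(universe)))
    for i, p in enumerate(profiles):
        for locus in p.loci:
            m[i, idx[locus]] = 1.0
    sizes = m.sum(axis=1)
    inter = m @ m.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 2.0 * inter / (sizes[:, None] + sizes[None, :])
    return d


@dataclass(frozen=True)
class GroupSimilarity:
    """Mean pairwise Dice within each group and between groups."""

    within: dict          # group label -> mean (None when < 2 clones)
    between: float


def _masked_means(dvals: np.ndarray, gi: np.ndarray, gj: np.ndarray,
                  labels: tuple) -> tuple:
    """Within-group and between-group means over the condensed pair vector."""
    la, lb = labels
    wa_mask = (gi == la) & (gj == la)
    wb_mask = (gi == lb) & (gj == lb)
    bt_mask = gi != gj
    out = []
    for mask in (wa_mask, wb_mask, bt_mask):
        vals = dvals[mask]
        vals = vals[~np.isnan(vals)]
        out.append(float(vals.mean()) if vals.size else float("nan"))
    return tuple(out)


def group_mean_similarity(profiles) -> GroupSimilarity:
    """Mean pairwise Dice within each group and across groups.

    Pairs of clones that both carry no mutations are undefined and skipped
    with a warning.  A group with a single clone has no within-group pairs;
    its mean is reported as None with a warning.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least two clones")
    labels = sorted({p.group for p in profiles})
    d = _pairwise_matrix(profiles)
    iu = np.triu_indices(len(profiles), k=1)
    if np.isnan(d[iu]).any():
        warnings.warn("pairs of mutation-free clones skipped (Dice undefined)",
                      UserWarning, stacklevel=2)
    groups = np.array([p.group for p in profiles])
    within = {}
    for lab in labels:
        members = np.nonzero(groups == lab)[0]
        if members.size < 2:
            warnings.warn(f"group {lab!r} has a single clone: no within-group mean",
                          UserWarning, stacklevel=2)
            within[lab] = None
            continue
        sub = d[np.ix_(members, members)][np.triu_indices(members.size, k=1)]
        sub = sub[~np.isnan(sub)]
        within[lab] = float(sub.mean()) if sub.size else None
    gi, gj = groups[iu[0]], groups[iu[1]]
    vals = d[iu][gi != gj]
    vals = vals[~np.isnan(vals)]
    between = float(vals.mean()) if vals.size else float("nan")
    return GroupSimilarity(within=within, between=between)


@dataclass(frozen=True)
class SimilarityResult:
    """Observed similarity means and their label-permutation p-values."""

    within_a: float
    within_b: float
    between: float
    p_within_a: float
    p_within_b: float
    p_between: float
    n_perm: int
    labels: tuple

    def summary(self) -> str:
        la, lb = self.labels
        return (
            f"Mean pairwise Dice similarity ({self.n_perm} label permutations)\n"
            f"  within {la}: {self.within_a:.3f}  (p = {self.p_within_a:.3f})\n"
            f"  within {lb}: {self.within_b:.3f}  (p = {self.p_within_b:.3f})\n"
            f"  between:   {self.between:.3f}  (p = {self.p_between:.3f})\n"
        )


def permutation_test(profiles, n_perm: int = 1000, seed=0) -> SimilarityResult:
    """Label-permutation test of within/between-group similarity means.

    Clones are randomly reassigned to the two group labels (group sizes
    preserved).  Each statistic's p-value is two-sided by absolute
    deviation from the permutation mean:

        p = (1 + #{|T_perm - mean| >= |T_obs - mean|}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a meaningful null")
    profiles = list(profiles)
    labels = tuple(sorted({p.group for p in profiles}))
    if len(labels) != 2:
        raise ValueError(f"exactly two group labels required, got {labels}")
    groups = np.array([p.group for p in profiles])
    sizes = {lab: int((groups == lab).sum()) for lab in labels}
    if any(s < 2 for s in sizes.values()):
        raise ValueError("each group needs at least two clones")
    d = _pairwise_matrix(profiles)
    n = len(profiles)
    iu = np.triu_indices(n, k=1)
    dvals = d[iu]
    obs = _masked_means(dvals, groups[iu[0]], groups[iu[1]], labels)
    rng = np.random.default_rng(seed)
    perm_stats = np.empty((n_perm, 3))
    for j in range(n_perm):
        perm = groups[rng.permutation(n)]
        perm_stats[j] = _masked_means(dvals, perm[iu[0]], perm[iu[1]], labels)
    pvals = []
    for t in range(3):
        col = perm_stats[:, t]
        center = float(np.nanmean(col))
        dev_obs = abs(obs[t] - center)
        dev_perm = np.abs(col - center)
        hits = int(np.sum(dev_perm >= dev_obs - 1e-12))
        pvals.append((1 + hits) / (1 + n_perm))
    return SimilarityResult(
        within_a=obs[0], within_b=obs[1], between=obs[2],
        p_within_a=pvals[0], p_within_b=pvals[1], p_between=pvals[2],
        n_perm=n_perm, labels=labels,
    )
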