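"""Partitioning incidence-based dissimilarity into turnover and nestedness.

Pairwise Sorensen dissimilarity splits additively into a Simpson (turnover)
component and a nestedness-resultant remainder:

    beta_sor = (b + c) / (2a + b + c)
    beta_sim = min(b, c) / (a + min(b, c))
    beta_sne = beta_sor - beta_sim
             = |b - c| / (2a + b + c) * a / (a + min(b, c))

with a = species shared by the two sites and b, c the species exclusive to
each. The multiple-site analogues replace b and c with the sums of pairwise
exclusive richness minima and maxima, and a with sum(S_i) - S_T (the total
richness surplus over gamma). beta_ratio = beta_SNE / beta_SOR classifies a
system as turnover-dominated (< 0.5) or nestedness-dominated (> 0.5).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .community import CommunityMatrix, DistanceMatrix, ValidationError, site_richness


class PairCounts(NamedTuple):
    """Shared (a) and exclusive (b, c) species counts for a pair of sites."""
    a: int
    b: int
    c: int


class PairwiseBeta(NamedTuple):
    beta_sor: float
    beta_sim: float
    beta_sne: float


@dataclass(frozen=True)
class MultiSiteBeta:
    """Multiple-site Sorensen dissimilarity and its additive components."""
    beta_SOR: float
    beta_SIM: float
    beta_SNE: float
    n_sites: int

    @property
    def beta_ratio(self) -> float:
        return beta_ratio(self)

    @property
    def dominance(self) -> str:
        return classify_ratio(self.beta_ratio)


@dataclass(frozen=True)
class ResampledMultiSiteBeta:
    """Mean and sample SD of multiple-site components over random subsets of
    sites, drawn without replacement within each sample."""
    mean: MultiSiteBeta
    sd_SOR: float
    sd_SIM: float
    sd_SNE: float
    subset_size: int
    n_samples: int

    @property
    def beta_ratio(self) -> float:
        return self.mean.beta_ratio


def pair_counts(x: np.ndarray, y: np.ndarray) -> PairCounts:
    """Shared/exclusive species counts for two incidence vectors over the
    same species list."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValidationError("incidence vectors cover different species lists")
    x = x.astype(bool)
    y = y.astype(bool)
    return PairCounts(int((x & y).sum()), int((x & ~y).sum()), int((~x & y).sum()))


def sorensen_partition(p: PairCounts) -> PairwiseBeta:
    a, b, c = p
    if a + b + c == 0:
        raise ValidationError("dissimilarity undefined: both sites empty")
    bsor = (b + c) / (2 * a + b + c)
    bsim = min(b, c) / (a + min(b, c)) if (a + min(b, c)) > 0 else 0.0
    return PairwiseBeta(bsor, bsim, bsor - bsim)


def sorensen_nestedness_product(p: PairCounts) -> float:
    """Closed-form nestedness-resultant component: richness-difference
    fraction times Simpson similarity. Equals beta_sor - beta_sim."""
    a, b, c = p
    if a + b + c == 0:
        raise ValidationError("dissimilarity undefined: both sites empty")
    # min(b, c) = 0 is perfect nestedness: the poorer site shares its whole
    # assemblage, so the Simpson-similarity factor is 1 (also covers a = 0
    # with one empty side, where the direct ratio is 0/0)
    simpson_sim = 1.0 if min(b, c) == 0 else a / (a + min(b, c))
    return abs(b - c) / (2 * a + b + c) * simpson_sim


def jaccard_partition(p: PairCounts) -> PairwiseBeta:
    """Jaccard-family partition: beta_jac = beta_jtu + beta_jne."""
    a, b, c = p
    if a + b + c == 0:
        raise ValidationError("dissimilarity undefined: both sites empty")
    bjac = (b + c) / (a + b + c)
    denom = a + 2 * min(b, c)
    bjtu = 2 * min(b, c) / denom if denom > 0 else 0.0
    return PairwiseBeta(bjac, bjtu, bjac - bjtu)


def carvalho_partition(p: PairCounts) -> PairwiseBeta:
    """Replacement/richness-difference partition: beta_cc = beta_repl + beta_rich."""
    a, b, c = p
    if a + b + c == 0:
        raise ValidationError("dissimilarity undefined: both sites empty")
    tot = a + b + c
    return PairwiseBeta((b + c) / tot, 2 * min(b, c) / tot, abs(b - c) / tot)


_FAMILIES = {
    "sorensen": sorensen_partition,
    "jaccard": jaccard_partition,
    "carvalho": carvalho_partition,
}


def alternative_partitions(p: PairCounts, family: str) -> PairwiseBeta:
    """Pairwise partition under an alternative index family
    (``jaccard`` or ``carvalho``); ``sorensen`` is also accepted."""
    try:
        fn = _FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown index family {family!r}") from None
    return fn(p)


def pairwise_matrices(
    m: CommunityMatrix, family: str = "sorensen"
) -> tuple[DistanceMatrix, DistanceMatrix, DistanceMatrix]:
    """All pairwise dissimilarities as three aligned symmetric matrices
    (total, turnover component, nestedness-resultant component)."""
    if m.n_sites < 2:
        raise ValidationError("need at least two sites")
    if (site_richness(m) == 0).any():
        raise ValidationError(
            "empty site present: apply drop_empty_sites before pairwise dissimilarity"
        )
    fn = _FAMILIES[family]
    inc = np.asarray(m.incidence, dtype=np.int64)
    shared = inc @ inc.T                      # a for every pair
    rich = shared.diagonal()
    n = m.n_sites
    tot = np.zeros((n, n))
    turn = np.zeros((n, n))
    nest = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = int(shared[i, j])
            pb = fn(PairCounts(a, int(rich[i] - a), int(rich[j] - a)))
            tot[i, j] = tot[j, i] = pb.beta_sor
            turn[i, j] = turn[j, i] = pb.beta_sim
            nest[i, j] = nest[j, i] = pb.beta_sne
    lab = m.site_ids
    return (DistanceMatrix(lab, tot), DistanceMatrix(lab, turn),
            DistanceMatrix(lab, nest))


def _multisite_counts(inc: np.ndarray) -> tuple[int, int, int]:
    inc = np.asarray(inc, dtype=np.int64)
    shared = inc @ inc.T
    rich = shared.diagonal()
    iu = np.triu_indices(inc.shape[0], k=1)
    b_ij = rich[iu[0]] - shared[iu]           # exclusive to i
    b_ji = rich[iu[1]] - shared[iu]           # exclusive to j
    sum_min = int(np.minimum(b_ij, b_ji).sum())
    sum_max = int(np.maximum(b_ij, b_ji).sum())
    gamma = int((inc.sum(axis=0) > 0).sum())
    shared_total = int(rich.sum()) - gamma    # sum S_i - S_T
    return sum_min, sum_max, shared_total


def multisite_partition(m: CommunityMatrix | np.ndarray) -> MultiSiteBeta:
    """Multiple-site Sorensen dissimilarity partitioned into turnover and
    nestedness-resultant components. Reduces to the pairwise partition at
    exactly two sites."""
    inc = np.asarray(m.incidence if isinstance(m, CommunityMatrix) else m)
    n = inc.shape[0]
    if n < 2:
        raise ValidationError("multiple-site dissimilarity needs >= 2 sites")
    if (inc.sum(axis=1) == 0).any():
        raise ValidationError(
            "empty site present: apply drop_empty_sites before multisite_partition"
        )
    sum_min, sum_max, shared = _multisite_counts(inc)
    denom_sor = 2 * shared + sum_min + sum_max
    if denom_sor == 0:
        raise ValidationError("dissimilarity undefined: no species present")
    b_sor = (sum_min + sum_max) / denom_sor
    b_sim = sum_min / (shared + sum_min) if (shared + sum_min) > 0 else 0.0
    return MultiSiteBeta(b_sor, b_sim, b_sor - b_sim, n)


def beta_ratio(msb: MultiSiteBeta) -> float:
    """Share of overall dissimilarity due to nestedness: beta_SNE/beta_SOR."""
    if msb.beta_SOR == 0:
        raise ValidationError("beta_ratio undefined: beta_SOR is zero")
    return msb.beta_SNE / msb.beta_SOR


def classify_ratio(ratio: float) -> str:
    return "nestedness-dominated" if ratio > 0.5 else "turnover-dominated"


def resampled_multisite(
    m: CommunityMatrix,
    subset_size: int,
    n_samples: int = 100,
    seed: int | np.random.Generator | None = None,
) -> ResampledMultiSiteBeta:
    """Average multiple-site components over ``n_samples`` random subsets of
    ``subset_size`` sites, making systems with different site counts
    comparable. Subsets are drawn without replacement; the component means
    retain additivity because the mean is linear."""
    if subset_size < 2:
        raise ValidationError("subset_size must be >= 2")
    if subset_size > m.n_sites:
        raise ValidationError("subset_size exceeds the number of sites")
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    inc = np.asarray(m.incidence)
    sor, sim, sne = (np.empty(n_samples) for _ in range(3))
    for k in range(n_samples):
        idx = rng.choice(m.n_sites, size=subset_size, replace=False)
        msb = multisite_partition(inc[idx, :])
        sor[k], sim[k], sne[k] = msb.beta_SOR, msb.beta_SIM, msb.beta_SNE
    sd = (lambda v: float(v.std(ddof=1)) if n_samples > 1 else 0.0)
    mean = MultiSiteBeta(float(sor.mean()), float(sim.mean()), float(sne.mean()),
                         subset_size)
    return ResampledMultiSiteBeta(mean, sd(sor), sd(sim), sd(sne),
                                  subset_size, n_samples)
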