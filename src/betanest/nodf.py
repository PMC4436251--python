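"""NODF nestedness metric and the proportional-proportional null model.

NODF (Nestedness metric based on Overlap and Decreasing Filling) scores a
binary matrix by paired overlap: for every pair of lines along an axis with
strictly decreasing marginal totals, the percentage of the poorer line's
presences that also occur in the richer line; pairs with equal totals score
zero. Axis scores are means over pairs; the total score pools row pairs and
column pairs. Significance is assessed against a proportional-proportional
(PP) null in which each cell is an independent Bernoulli draw with
probability equal to the average of its row and column fill fractions, which
preserves matrix fill in expectation.

Site nestedness ("NODF for sites") compares site incidence vectors, i.e.
asks whether species-poor sites are subsets of species-rich sites.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .community import CommunityMatrix, ValidationError


@dataclass(frozen=True)
class PackedMatrix:
    """A community matrix with rows and columns reordered by decreasing
    marginal totals (maximal packing; ties keep original order)."""
    matrix: CommunityMatrix
    site_order: tuple[int, ...]
    species_order: tuple[int, ...]


@dataclass(frozen=True)
class NodfResult:
    """NODF scores in [0, 100] for site pairs, species pairs and their pool."""
    nodf_sites: float
    nodf_species: float
    nodf_total: float


@dataclass(frozen=True)
class NodfNullResult:
    """Observed NODF against a PP-null distribution."""
    n_obs: float
    n_exp_mean: float
    n_exp_sd: float
    z: float | None
    p: float
    direction: str            # "nested" or "anti-nested"
    n_sim: int
    axis: str
    seed: int | None = None


def max_pack(m: CommunityMatrix) -> PackedMatrix:
    """Sort sites and species by decreasing marginal totals (stable)."""
    inc = np.asarray(m.incidence)
    if inc.size == 0:
        raise ValidationError("cannot pack an empty matrix")
    site_order = np.argsort(-inc.sum(axis=1), kind="stable")
    species_order = np.argsort(-inc.sum(axis=0), kind="stable")
    packed = CommunityMatrix(
        tuple(m.site_ids[i] for i in site_order),
        tuple(m.species_ids[j] for j in species_order),
        inc[np.ix_(site_order, species_order)],
    )
    return PackedMatrix(packed, tuple(int(i) for i in site_order),
                        tuple(int(j) for j in species_order))


def _axis_paired_overlap(rows: np.ndarray) -> np.ndarray:
    """Paired-overlap scores for all unordered pairs of rows of a 0/1 array."""
    rows = np.asarray(rows, dtype=np.int64)
    fills = rows.sum(axis=1)
    overlap = rows @ rows.T
    iu = np.triu_indices(rows.shape[0], k=1)
    f_i, f_j = fills[iu[0]], fills[iu[1]]
    decreasing = f_i != f_j
    poorer = np.minimum(f_i, f_j)
    scores = np.zeros(len(iu[0]))
    np.divide(100.0 * overlap[iu], poorer, out=scores,
              where=decreasing & (poorer > 0))
    scores[~decreasing] = 0.0
    return scores


def nodf(m: CommunityMatrix | np.ndarray, axis: str = "total") -> float:
    """NODF score for ``axis`` in {"sites", "species", "total"}.

    Requires at least two lines on each axis and no empty lines (drop empty
    sites/species first; an all-zero line makes paired overlap ill-defined).
    """
    res = nodf_result(m)
    return {"sites": res.nodf_sites, "species": res.nodf_species,
            "total": res.nodf_total}[_check_axis(axis)]


def _check_axis(axis: str) -> str:
    if axis not in ("sites", "species", "total"):
        raise ValueError(f"unknown NODF axis {axis!r}")
    return axis


def nodf_result(m: CommunityMatrix | np.ndarray) -> NodfResult:
    inc = np.asarray(m.incidence if isinstance(m, CommunityMatrix) else m)
    if inc.shape[0] < 2 or inc.shape[1] < 2:
        raise ValidationError("NODF needs at least 2 sites and 2 species")
    if (inc.sum(axis=1) == 0).any() or (inc.sum(axis=0) == 0).any():
        raise ValidationError("NODF undefined with empty sites or species")
    site_scores = _axis_paired_overlap(inc)
    species_scores = _axis_paired_overlap(inc.T)
    return NodfResult(
        float(site_scores.mean()),
        float(species_scores.mean()),
        float(np.concatenate([site_scores, species_scores]).mean()),
    )


def pp_null_sample(
    m: CommunityMatrix | np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One PP-null matrix: cell (i, j) present with probability
    (row fill_i + column fill_j) / 2."""
    inc = np.asarray(m.incidence if isinstance(m, CommunityMatrix) else m)
    prob = pp_cell_probabilities(inc)
    return (rng.random(inc.shape) < prob).astype(np.int8)


def pp_cell_probabilities(inc: np.ndarray) -> np.ndarray:
    inc = np.asarray(inc, dtype=float)
    row_fill = inc.mean(axis=1, keepdims=True)
    col_fill = inc.mean(axis=0, keepdims=True)
    return (row_fill + col_fill) / 2.0


def _drop_empty_lines(inc: np.ndarray) -> np.ndarray:
    inc = inc[inc.sum(axis=1) > 0, :]
    return inc[:, inc.sum(axis=0) > 0]


def nodf_null_test(
    m: CommunityMatrix,
    n_sim: int = 1000,
    seed: int | np.random.Generator | None = None,
    axis: str = "sites",
) -> NodfNullResult:
    """Monte Carlo test of observed NODF against the PP null.

    Null matrices that contain empty lines have those lines removed before
    scoring (mirroring the exclusion of empty sites in the observed data); a
    sample still degenerate after removal (< 2 lines on an axis) is dropped
    from the null distribution. Z = (N_obs - null mean) / null SD; the
    Monte Carlo p is one-tailed toward the observed deviation with the
    (k + 1)/(n + 1) correction.
    """
    _check_axis(axis)
    if n_sim < 1:
        raise ValidationError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    # empty lines (never-observed species, empty sites) carry no nestedness
    # information; remove them from the observed matrix exactly as from the
    # null samples
    inc = _drop_empty_lines(np.asarray(m.incidence))
    n_obs = nodf(inc, axis=axis)
    null = []
    for _ in range(n_sim):
        sample = _drop_empty_lines(pp_null_sample(inc, rng))
        if sample.shape[0] < 2 or sample.shape[1] < 2:
            continue
        null.append(nodf(sample, axis=axis))
    null = np.asarray(null)
    if null.size == 0:
        raise ValidationError("all null samples degenerate")
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if null.size > 1 else 0.0
    z = (n_obs - mean) / sd if sd > 0 else None
    if n_obs >= mean:
        direction = "nested"
        k = int((null >= n_obs).sum())
    else:
        direction = "anti-nested"
        k = int((null <= n_obs).sum())
    p = (k + 1) / (null.size + 1)
    return NodfNullResult(
        n_obs=n_obs, n_exp_mean=mean, n_exp_sd=sd, z=z, p=float(p),
        direction=direction, n_sim=int(null.size), axis=axis,
        seed=seed if isinstance(seed, int) else None,
    )
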