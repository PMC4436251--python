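"""Synthetic community matrices and island systems with controlled structure.

Two archetypes span the beta-diversity partition:

* a *nested* gradient — species-poor sites hold subsets of the species of
  richer sites, so all dissimilarity is nestedness-resultant; and
* a *turnover* gradient — sites occupy sliding windows along a ranked
  species list, so equal-richness sites differ purely by replacement.

A mixture assigns each species to one dynamic with a given weight,
producing intermediate beta_ratio values. ``generate_island_system``
emulates a land-bridge island survey: lognormal island areas, habitat
richness tied to log-area, richness following a power-law species-area
relationship with lognormal scatter, and nested ranked-occupancy community
assembly. Defaults mirror the observed 37-island system (area scale and
spread, SAR slope 0.09 and intercept 1.34 on the log10 scale).

Also exposes the fixed 37-island attribute table used throughout the
analyses (areas 0.57-1289.23 ha, isolation fractions, habitat and per-taxon
richness, coordinates in decimal degrees).
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .community import CommunityMatrix, ValidationError, validate_attributes


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters for mixture community generation."""
    n_sites: int
    n_species: int
    nested_weight: float = 1.0     # 1 = pure nested, 0 = pure turnover
    noise: float = 0.0             # per-cell flip probability
    seed: int | None = None

    def __post_init__(self):
        if self.n_sites < 1 or self.n_species < 1:
            raise ValidationError("counts must be positive")
        if not 0 <= self.nested_weight <= 1:
            raise ValidationError("nested_weight must lie in [0, 1]")
        if not 0 <= self.noise <= 1:
            raise ValidationError("noise must lie in [0, 1]")


def _site_labels(n):
    return tuple(f"site{i+1}" for i in range(n))


def _species_labels(n, prefix="sp"):
    return tuple(f"{prefix}{j+1}" for j in range(n))


def _apply_noise(inc: np.ndarray, noise: float, rng: np.random.Generator,
                 preserve_richness: bool = False) -> np.ndarray:
    if noise == 0:
        return inc
    if not preserve_richness:
        flip = rng.random(inc.shape) < noise
        return np.where(flip, 1 - inc, inc).astype(np.int8)
    # richness-preserving variant: swap a present and an absent species
    out = inc.copy()
    for i in range(out.shape[0]):
        ones = np.flatnonzero(out[i] == 1)
        zeros = np.flatnonzero(out[i] == 0)
        k = min(rng.binomial(out.shape[1], noise), len(ones), len(zeros))
        if k:
            out[i, rng.choice(ones, k, replace=False)] = 0
            out[i, rng.choice(zeros, k, replace=False)] = 1
    return out


def generate_nested(
    richness_profile,
    n_species: int,
    noise: float = 0.0,
    seed: int | np.random.Generator | None = None,
    preserve_richness: bool = False,
) -> CommunityMatrix:
    """Nested-gradient matrix: site k contains the top ``richness_profile[k]``
    species of a fixed ranking; at ``noise=0`` the matrix is perfectly nested
    and per-site richness equals the profile exactly."""
    profile = np.asarray(richness_profile, dtype=int)
    if (profile > n_species).any():
        raise ValidationError("richness profile exceeds the species pool")
    if (profile < 0).any():
        raise ValidationError("richness profile must be non-negative")
    rng = np.random.default_rng(seed)
    inc = (np.arange(n_species)[None, :] < profile[:, None]).astype(np.int8)
    inc = _apply_noise(inc, noise, rng, preserve_richness)
    return CommunityMatrix(_site_labels(len(profile)), _species_labels(n_species),
                           inc)


def generate_turnover(
    n_sites: int,
    width: int,
    step: int,
    noise: float = 0.0,
    seed: int | np.random.Generator | None = None,
    n_species: int | None = None,
) -> CommunityMatrix:
    """Turnover-gradient matrix: site k occupies a window of ``width``
    species starting at ``k * step`` along the ranked species list. With
    ``step == width`` windows are disjoint (pure replacement); ``step == 0``
    makes all sites identical."""
    if width < 1:
        raise ValidationError("window width must be >= 1")
    if step < 0 or step > width:
        raise ValidationError("step must lie in [0, width]")
    needed = (n_sites - 1) * step + width
    if n_species is None:
        n_species = needed
    if needed > n_species:
        raise ValidationError(
            f"windows need {needed} species but pool has {n_species}"
        )
    rng = np.random.default_rng(seed)
    inc = np.zeros((n_sites, n_species), dtype=np.int8)
    for k in range(n_sites):
        inc[k, k * step: k * step + width] = 1
    inc = _apply_noise(inc, noise, rng)
    return CommunityMatrix(_site_labels(n_sites), _species_labels(n_species), inc)


def generate_mixture(spec: GeneratorSpec) -> CommunityMatrix:
    """Mixture matrix: each species follows nested dynamics with probability
    ``nested_weight``, turnover dynamics otherwise; interpolates beta_ratio
    between the two archetypes."""
    rng = np.random.default_rng(spec.seed)
    n, s = spec.n_sites, spec.n_species
    nested_mask = rng.random(s) < spec.nested_weight
    inc = np.zeros((n, s), dtype=np.int8)
    # nested species: species with rank r is present at the r richest sites
    # (site order doubles as the richness gradient)
    ranks = rng.permutation(np.flatnonzero(nested_mask))
    for r, j in enumerate(ranks):
        n_occ = max(1, round(n * (1 - r / max(1, len(ranks)))))
        inc[:n_occ, j] = 1
    # turnover species: occupied by a random contiguous run of sites
    run = max(1, n // 4)
    for j in np.flatnonzero(~nested_mask):
        start = rng.integers(0, max(1, n - run + 1))
        inc[start:start + run, j] = 1
    inc = _apply_noise(inc, spec.noise, rng)
    return CommunityMatrix(_site_labels(n), _species_labels(s), inc)


def generate_island_system(
    n_islands: int = 37,
    n_species: int = 60,
    area_log10_mean: float = 0.46,
    area_log10_sd: float = 0.80,
    sar_slope: float = 0.09,
    sar_intercept: float = 1.34,
    sar_sigma: float = 0.04,
    habitat_link_strength: float = 0.95,
    max_habitats: int = 7,
    community_noise: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, CommunityMatrix]:
    """Simulate an island attribute table plus a community matrix.

    Areas are lognormal (base-10 parameters); habitat richness is a noisy
    monotone function of log-area whose correlation is tuned by
    ``habitat_link_strength`` in [0, 1]; species richness follows
    log10(S) = sar_intercept + sar_slope * log10(A) + N(0, sar_sigma);
    the community is assembled by ranked occupancy (site with richness S
    holds the top S species), i.e. a nested species-loss scenario;
    ``community_noise`` then flips cells independently, superimposing
    random turnover.
    """
    if area_log10_sd <= 0 or sar_sigma < 0:
        raise ValidationError("dispersion parameters must be positive")
    if not 0 <= habitat_link_strength <= 1:
        raise ValidationError("habitat_link_strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    log_area = rng.normal(area_log10_mean, area_log10_sd, n_islands)
    area = 10 ** log_area

    za = (log_area - log_area.mean()) / log_area.std()
    latent = (habitat_link_strength * za
              + np.sqrt(1 - habitat_link_strength ** 2) * rng.normal(size=n_islands))
    # map latent gradient onto 1..max_habitats preserving order
    order = latent.argsort().argsort()
    habitat = 1 + np.floor(order / n_islands * max_habitats).astype(int)
    habitat = np.clip(habitat, 1, max_habitats)

    log_s = sar_intercept + sar_slope * log_area + rng.normal(0, sar_sigma, n_islands)
    richness = np.clip(np.rint(10 ** log_s).astype(int), 0, n_species)

    attrs = validate_attributes(pd.DataFrame({
        "island": [str(i + 1) for i in range(n_islands)],
        "lat": 29.4 + rng.random(n_islands) * 0.2,
        "lon": 118.8 + rng.random(n_islands) * 0.3,
        "area_ha": area,
        "isolation": rng.uniform(0.42, 0.98, n_islands),
        "habitat_richness": habitat,
        "richness": richness,
    }))
    community = generate_nested(richness, n_species, noise=community_noise,
                                seed=rng)
    community = CommunityMatrix(tuple(attrs["island"]), community.species_ids,
                                np.asarray(community.incidence))
    return attrs, community


def table1_fixture() -> pd.DataFrame:
    """The fixed 37-island attribute table (coordinates converted once from
    degrees-minutes-seconds to decimal degrees, 6 decimals)."""
    with resources.files("betanest.data").joinpath("table1_islands.csv").open() as fh:
        return validate_attributes(pd.read_csv(fh))
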