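"""Incidence-matrix data model, island attribute tables and distance matrices.

The canonical in-memory orientation is sites in rows, species in columns,
regardless of how a CSV on disk is oriented. All dissimilarity and
nestedness code in this package consumes :class:`CommunityMatrix`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


# ---------------------------------------------------------------------------
# CommunityMatrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunityMatrix:
    """Binary site-by-species incidence matrix.

    Parameters
    ----------
    site_ids : ordered unique site labels (rows).
    species_ids : ordered unique species labels (columns).
    incidence : ``(n_sites, n_species)`` array of 0/1 presences.
    """

    site_ids: tuple[str, ...]
    species_ids: tuple[str, ...]
    incidence: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence)
        if inc.ndim != 2:
            raise ValidationError("incidence must be a 2-D array")
        sites = tuple(str(s) for s in self.site_ids)
        species = tuple(str(s) for s in self.species_ids)
        if inc.shape != (len(sites), len(species)):
            raise ValidationError(
                f"incidence shape {inc.shape} does not match "
                f"{len(sites)} sites x {len(species)} species"
            )
        if len(set(sites)) != len(sites):
            raise ValidationError("duplicate site labels")
        if len(set(species)) != len(species):
            raise ValidationError("duplicate species labels")
        bad = ~np.isin(inc, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary cell at site {sites[i]!r}, species {species[j]!r}: "
                f"{inc[i, j]!r}"
            )
        object.__setattr__(self, "site_ids", sites)
        object.__setattr__(self, "species_ids", species)
        inc = inc.astype(np.int8)
        inc.setflags(write=False)
        object.__setattr__(self, "incidence", inc)

    # -- basic descriptors --------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.asarray(self.incidence), index=list(self.site_ids),
            columns=list(self.species_ids),
        )

    def select_sites(self, sites: Sequence[str]) -> "CommunityMatrix":
        idx = [self.site_ids.index(str(s)) for s in sites]
        return CommunityMatrix(
            tuple(self.site_ids[i] for i in idx), self.species_ids,
            np.asarray(self.incidence)[idx, :],
        )


def from_frame(df: pd.DataFrame) -> CommunityMatrix:
    """Build a CommunityMatrix from a sites-in-rows DataFrame."""
    return CommunityMatrix(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                           df.to_numpy())


def _coerce_binary(df: pd.DataFrame, truncate_abundance: bool) -> np.ndarray:
    try:
        vals = df.astype(float).to_numpy()
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in community table: {exc}") from exc
    if truncate_abundance:
        if (vals < 0).any():
            raise ValidationError("negative abundance in community table")
        return (vals > 0).astype(np.int8)
    if not np.isin(vals, (0.0, 1.0)).all():
        i, j = np.argwhere(~np.isin(vals, (0.0, 1.0)))[0]
        raise ValidationError(
            f"non-binary cell at row {df.index[i]!r}, column {df.columns[j]!r}: "
            f"{df.iat[i, j]!r} (pass truncate_abundance=True to threshold counts)"
        )
    return vals.astype(np.int8)


def read_community_csv(
    path: str | Path,
    orientation: str = "sites_in_rows",
    truncate_abundance: bool = False,
) -> CommunityMatrix:
    """Read a labelled 0/1 community CSV.

    ``orientation`` is one of ``"sites_in_rows"``, ``"species_in_rows"`` or
    ``"auto"``. Auto-detection accepts a file whose row labels parse as island
    codes (integers) while column labels do not, or vice versa; ambiguous
    files must state their orientation explicitly.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if orientation == "auto":
        rows_numeric = all(_is_int(x) for x in df.index)
        cols_numeric = all(_is_int(x) for x in df.columns)
        if rows_numeric and not cols_numeric:
            orientation = "sites_in_rows"
        elif cols_numeric and not rows_numeric:
            orientation = "species_in_rows"
        else:
            raise ValidationError(
                "cannot sniff orientation: specify sites_in_rows or species_in_rows"
            )
    if orientation == "species_in_rows":
        df = df.T
    elif orientation != "sites_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    inc = _coerce_binary(df, truncate_abundance)
    return CommunityMatrix(tuple(df.index), tuple(df.columns), inc)


def _is_int(x: str) -> bool:
    try:
        int(str(x))
    except ValueError:
        return False
    return True


def write_community_csv(m: CommunityMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, index_label="site")


def drop_empty_sites(m: CommunityMatrix) -> tuple[CommunityMatrix, list[str]]:
    """Remove sites with zero presences, returning the kept matrix and the
    labels removed (e.g. islands where no individual of the taxon was found)."""
    rich = site_richness(m)
    keep = rich > 0
    if not keep.any():
        raise ValidationError("all sites are empty")
    removed = [s for s, k in zip(m.site_ids, keep) if not k]
    if not removed:
        return m, []
    kept = CommunityMatrix(
        tuple(s for s, k in zip(m.site_ids, keep) if k),
        m.species_ids, np.asarray(m.incidence)[keep, :],
    )
    return kept, removed


def drop_empty_species(m: CommunityMatrix) -> tuple[CommunityMatrix, list[str]]:
    """Remove species observed at no site."""
    prev = np.asarray(m.incidence).sum(axis=0)
    keep = prev > 0
    if not keep.any():
        raise ValidationError("all species are absent")
    removed = [s for s, k in zip(m.species_ids, keep) if not k]
    if not removed:
        return m, []
    kept = CommunityMatrix(
        m.site_ids, tuple(s for s, k in zip(m.species_ids, keep) if k),
        np.asarray(m.incidence)[:, keep],
    )
    return kept, removed


def site_richness(m: CommunityMatrix) -> np.ndarray:
    """Number of species present at each site (alpha diversity)."""
    return np.asarray(m.incidence).sum(axis=1)


def matrix_fill(m: CommunityMatrix) -> float:
    """Percentage of matrix cells that are presences."""
    if m.n_sites == 0 or m.n_species == 0:
        raise ValidationError("matrix_fill undefined for an empty matrix")
    return 100.0 * float(np.asarray(m.incidence).sum()) / (m.n_sites * m.n_species)


def richness_cv(richness: Sequence[float], exclude_empty: bool = False) -> float:
    """Coefficient of variation (sample SD / mean) of per-site richness."""
    r = np.asarray(richness, dtype=float)
    if exclude_empty:
        r = r[r > 0]
    if r.size < 2:
        raise ValidationError("need at least two sites for a CV")
    mean = r.mean()
    if mean == 0:
        raise ValidationError("CV undefined: mean richness is zero")
    return float(r.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# Island attributes
# ---------------------------------------------------------------------------

ATTRIBUTE_COLUMNS = ("island", "lat", "lon", "area_ha", "isolation",
                     "habitat_richness")


def validate_attributes(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ATTRIBUTE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"attribute table missing columns: {missing}")
    df = df.copy()
    df["island"] = df["island"].map(str)
    if df["island"].duplicated().any():
        raise ValidationError("duplicate island codes")
    if (df["area_ha"] <= 0).any():
        raise ValidationError("island area must be positive")
    if ((df["isolation"] <= 0) | (df["isolation"] > 1)).any():
        raise ValidationError("isolation must lie in (0, 1]")
    if (df["habitat_richness"] < 1).any():
        raise ValidationError("habitat richness must be >= 1")
    if ((df["lat"].abs() > 90) | (df["lon"].abs() > 180)).any():
        raise ValidationError("coordinates outside valid ranges")
    return df.set_index("island", drop=False)


def read_attributes_csv(path: str | Path) -> pd.DataFrame:
    """Read an island attribute table (one row per island; columns
    island, lat, lon, area_ha, isolation, habitat_richness and optional
    richness_<taxon> counts)."""
    return validate_attributes(pd.read_csv(path))


# ---------------------------------------------------------------------------
# DistanceMatrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric matrix of non-negative pairwise distances or
    dissimilarities over labelled sites."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        vals = np.asarray(self.values, dtype=float)
        n = len(labels)
        if len(set(labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        if vals.shape != (n, n):
            raise ValidationError(f"distance matrix shape {vals.shape} != ({n}, {n})")
        if not np.allclose(vals, vals.T, atol=1e-10):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(vals), 0.0, atol=1e-10):
            raise ValidationError("distance matrix diagonal is not zero")
        if (vals < -1e-12).any():
            raise ValidationError("negative distance")
        vals = (vals + vals.T) / 2.0
        np.fill_diagonal(vals, 0.0)
        vals.setflags(write=False)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (scipy squareform) order."""
        iu = np.triu_indices(self.n, k=1)
        return np.asarray(self.values)[iu]

    def permuted(self, order: Sequence[int]) -> np.ndarray:
        order = np.asarray(order)
        return np.asarray(self.values)[np.ix_(order, order)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(np.asarray(self.values), index=list(self.labels),
                            columns=list(self.labels))


def write_distance_csv(d: DistanceMatrix, path: str | Path) -> None:
    d.to_frame().to_csv(path, index_label="site", float_format="%.10g")


def read_distance_csv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(map(str, df.index)) != list(map(str, df.columns)):
        raise ValidationError("distance CSV row and column labels differ")
    return DistanceMatrix(tuple(map(str, df.index)), df.to_numpy())
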