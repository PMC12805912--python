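"""Phylogenetically weighted effective abundance of competitors (Nz).

The index sums, over every species censused in a season (the focal species
included), its abundance weighted by a Gaussian kernel of normalised
patristic distance to the focal species:

    Nz = sum_z' N(z') * alpha(z, z')
    alpha(z, z') = exp(-d(z, z')^2 / (2 * sigma2_alpha))

Conspecifics have d = 0 and weight 1, so Nz >= N(focal) always.  Patristic
distances come from an ultrametric tree with branch lengths and are divided
by the maximum pairwise distance, so kernel inputs lie in [0, 1]; the decay
rate sigma2_alpha defaults to 0.05, under which the most distant pair
contributes a weight of exp(-10) ~= 4.5e-5.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import dendropy
import numpy as np
import pandas as pd

from .errors import ConfigurationError, CoverageError, TreeError


@dataclass(frozen=True)
class CompetitionKernel:
    """Gaussian decay of competitive weight with normalised distance."""

    sigma2_alpha: float = 0.05

    def __post_init__(self):
        if self.sigma2_alpha <= 0:
            raise ValueError("sigma2_alpha must be > 0")


@dataclass(frozen=True)
class PhyloDistances:
    """Normalised pairwise patristic distances among community species."""

    species: tuple[str, ...]
    matrix: np.ndarray            # symmetric, zero diagonal, entries in [0, 1]
    normalization: float          # the max raw patristic distance divided out

    def distance(self, a: str, b: str) -> float:
        idx = {s: i for i, s in enumerate(self.species)}
        return float(self.matrix[idx[a], idx[b]])


def patristic_distances(newick: str) -> PhyloDistances:
    """Max-normalised patristic distance matrix from a Newick tree (>= 2 leaves).

    ``newick`` may be a Newick string or a path to a Newick file.  Raises
    :class:`TreeError` for missing branch lengths or duplicate leaf labels.
    """
    text = newick
    if "(" not in newick:  # treat as a path
        with open(newick, "r", encoding="utf-8") as fh:
            text = fh.read()
    try:
        tree = dendropy.Tree.get(
            file=StringIO(text), schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"could not parse Newick tree: {exc}") from exc

    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) < 2:
        raise TreeError("tree must have >= 2 leaves")
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate leaf labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise TreeError("tree has edges with missing branch lengths")

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    labels = sorted(labels)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[labels[i]],
                                                       taxa[labels[j]])
    dmax = float(D.max())
    if dmax <= 0:
        raise TreeError("all patristic distances are zero")
    return PhyloDistances(species=tuple(labels), matrix=D / dmax,
                          normalization=dmax)


def alpha(d: float | np.ndarray, kernel: CompetitionKernel) -> float | np.ndarray:
    """Competitive weight exp(-d^2 / (2 sigma2_alpha)); alpha(0) = 1."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    out = np.exp(-(d ** 2) / (2.0 * kernel.sigma2_alpha))
    return float(out) if out.ndim == 0 else out


def read_census(path: str, delimiter: str = ",") -> pd.DataFrame:
    """Read a census table (species, season[, year], abundance)."""
    df = pd.read_csv(path, sep=delimiter)
    for col in ("species", "season", "abundance"):
        if col not in df.columns:
            raise ConfigurationError(f"census missing column {col!r}")
    return df


def effective_abundance(
    census: pd.DataFrame,
    dist: PhyloDistances,
    kernel: CompetitionKernel,
    focal: str,
    season: str,
) -> float:
    """Nz for one focal species in one season.

    Multi-year censuses (a ``year`` column) are averaged within species and
    season before summing.  Species censused that season must all appear in
    the distance matrix (else :class:`CoverageError`); the focal species
    itself contributes with weight 1, and species absent from that season's
    census contribute zero.
    """
    if focal not in dist.species:
        raise CoverageError(f"focal species {focal!r} absent from tree")
    sub = census[census["season"] == season]
    if "year" in sub.columns:
        sub = sub.groupby("species", as_index=False)["abundance"].mean()
    missing = sorted(set(sub["species"]) - set(dist.species))
    if missing:
        raise CoverageError(
            "census species absent from distance matrix: " + ", ".join(missing)
        )
    if np.any(sub["abundance"].to_numpy() < 0):
        raise ValueError("abundances must be nonnegative")
    total = 0.0
    for _, row in sub.iterrows():
        d = dist.distance(focal, row["species"])
        total += float(row["abundance"]) * float(alpha(d, kernel))
    return total


def seasonal_competition_table(
    census: pd.DataFrame,
    dist: PhyloDistances,
    kernel: CompetitionKernel,
    focal_species: list[str],
) -> pd.DataFrame:
    """Nz per focal species and season, plus the breeding:non-breeding change."""
    rows = []
    for sp in focal_species:
        nz = {
            season: effective_abundance(census, dist, kernel, sp, season)
            for season in ("non_breeding", "breeding")
        }
        change = 100.0 * (nz["breeding"] - nz["non_breeding"]) / nz["non_breeding"]
        rows.append((sp, nz["non_breeding"], nz["breeding"], change))
    return pd.DataFrame(
        rows,
        columns=["species", "Nz_non_breeding", "Nz_breeding",
                 "percent_increase_breeding"],
    )
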