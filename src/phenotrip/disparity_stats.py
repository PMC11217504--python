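"""Morphospace disparity and sexual-dimorphism statistics.

All statistics operate on subset centroids in the embedding space: the mean
embedding location over the photographs in a (species, sex, surface) subset.
The sexual disparity difference for a species pair is the inter-male centroid
distance minus the inter-female centroid distance — positive when males of
the two species are further apart in morphospace than their females.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, spearmanr

from .dataset_io import DatasetManifest
from .errors import (
    DegenerateTestError,
    InvalidArgumentError,
    UndefinedCorrelationError,
)
from .triplet_embed import EmbeddingTable

logger = logging.getLogger(__name__)


class SubsetKey(NamedTuple):
    species: str
    sex: str = "both"
    surface: str = "both"


@dataclass
class SubsetDistanceMatrix:
    """Symmetric Euclidean centroid-distance matrix over labelled subsets."""

    keys: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.keys), len(self.keys)):
            raise InvalidArgumentError("matrix shape must match key count")
        if not np.allclose(v, v.T):
            raise InvalidArgumentError("matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise InvalidArgumentError("diagonal must be zero")
        if np.any(v < 0):
            raise InvalidArgumentError("distances must be non-negative")
        self.values = v

    @property
    def labels(self) -> list[str]:
        return [k.species if isinstance(k, SubsetKey) else str(k)
                for k in self.keys]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def entry(self, a, b) -> float:
        la = self.labels
        return float(self.values[la.index(a), la.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path):
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SubsetDistanceMatrix":
        keys = [SubsetKey(str(s)) for s in df.index]
        return cls(keys=keys, values=df.to_numpy(dtype=float))


@dataclass
class DisparityDifferenceMatrix:
    """Male-minus-female pairwise inter-species centroid distances."""

    species: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.species)
        if v.shape != (n, n) or not np.allclose(v, v.T):
            raise InvalidArgumentError("difference matrix must be symmetric")
        self.values = v

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def entry(self, a, b) -> float:
        return float(self.values[self.species.index(a), self.species.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.species)


def subset_centroids(embedding: EmbeddingTable, manifest: DatasetManifest,
                     sex: str = "both", surface: str = "both"
                     ) -> dict[SubsetKey, np.ndarray]:
    """Mean embedding per species subset under the given sex/surface filter.

    ``sex`` / ``surface`` are either a concrete label or ``"both"`` (pooled).
    Species with no images in the filter are omitted with a log entry.
    """
    if len(embedding) == 0:
        raise InvalidArgumentError("empty embedding")
    out = {}
    vec = embedding.vectors
    for species in manifest.species_list:
        recs = manifest.subset(species=species, sex=sex, surface=surface)
        ids = [r.image_id for r in recs if r.image_id in vec.index]
        if not ids:
            logger.info("subset (%s, %s, %s) empty; omitted",
                        species, sex, surface)
            continue
        out[SubsetKey(species, sex, surface)] = (
            vec.loc[ids].mean(axis=0).to_numpy()
        )
    return out


def pairwise_centroid_distances(centroids: dict) -> SubsetDistanceMatrix:
    """Euclidean distances between all subset centroid pairs."""
    if len(centroids) < 2:
        raise InvalidArgumentError("need >= 2 subsets")
    keys = sorted(centroids, key=lambda k: tuple(k))
    mat = squareform(pdist(np.stack([centroids[k] for k in keys])))
    return SubsetDistanceMatrix(keys=keys, values=mat)


def sexual_disparity_difference(male: SubsetDistanceMatrix,
                                female: SubsetDistanceMatrix
                                ) -> DisparityDifferenceMatrix:
    """Elementwise male minus female inter-species distances.

    Species present in only one matrix are dropped from both (logged);
    positive entries mean males are more disparate than females.
    """
    shared = sorted(set(male.labels) & set(female.labels))
    dropped = (set(male.labels) | set(female.labels)) - set(shared)
    if dropped:
        logger.info("species missing a sex dropped: %s", sorted(dropped))
    if not shared:
        raise InvalidArgumentError("no species shared between sexes")
    m = male.to_dataframe().loc[shared, shared].to_numpy()
    f = female.to_dataframe().loc[shared, shared].to_numpy()
    return DisparityDifferenceMatrix(species=shared, values=m - f)


def mean_disparity_difference(ddm: DisparityDifferenceMatrix,
                              species_subset=None) -> float:
    """Mean of the disparity difference over unordered species pairs."""
    species = sorted(species_subset) if species_subset else ddm.species
    missing = set(species) - set(ddm.species)
    if missing:
        raise InvalidArgumentError(f"species not in matrix: {sorted(missing)}")
    if len(species) < 2:
        raise InvalidArgumentError("need >= 2 species")
    sub = ddm.to_dataframe().loc[species, species].to_numpy()
    return float(squareform(sub, checks=False).mean())


def phenotypic_distinctiveness(m: SubsetDistanceMatrix,
                               criterion: str = "mean") -> list[tuple[str, float]]:
    """Rank species by centroid distance from the others, most distinct first.

    ``criterion="min"``: greatest distance to the nearest other species;
    ``criterion="mean"``: greatest average distance to all other species.
    Ties are broken lexicographically by species label.
    """
    if criterion not in ("mean", "min"):
        raise InvalidArgumentError(f"unknown criterion {criterion!r}")
    labels = m.labels
    if len(labels) < 2:
        raise InvalidArgumentError("need >= 2 species")
    v = m.values.copy()
    scores = {}
    for i, lab in enumerate(labels):
        others = np.delete(v[i], i)
        scores[lab] = float(others.min() if criterion == "min" else others.mean())
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if len({s for _, s in ranked}) < len(ranked):
        logger.info("ties in distinctiveness broken lexicographically")
    return ranked


def sex_distance_location_test(male_condensed, female_condensed) -> dict:
    """Kruskal-Wallis rank test for a location difference between the male
    and female condensed inter-species distance vectors.

    Returns H, p and per-sex mean/median/max summaries.  Identical samples
    give H = 0, p = 1; all-tied pooled data raise DegenerateTestError.
    """
    male = np.asarray(male_condensed, dtype=float)
    female = np.asarray(female_condensed, dtype=float)
    if male.size == 0 or female.size == 0:
        raise InvalidArgumentError("both samples must be nonempty")
    pooled = np.concatenate([male, female])
    if np.ptp(pooled) == 0:
        raise DegenerateTestError("all distances tied across both samples")
    stat = kruskal(male, female)
    return {
        "H": float(stat.statistic),
        "p": float(stat.pvalue),
        "male": {"mean": float(male.mean()), "median": float(np.median(male)),
                 "max": float(male.max()), "n": int(male.size)},
        "female": {"mean": float(female.mean()),
                   "median": float(np.median(female)),
                   "max": float(female.max()), "n": int(female.size)},
    }


def disparity_distance_correlation(ddm: DisparityDifferenceMatrix,
                                   sex_matrix: SubsetDistanceMatrix
                                   ) -> tuple[float, float]:
    """Spearman correlation between the disparity difference and one sex's
    inter-species distances, over condensed upper triangles."""
    shared = sorted(set(ddm.species) & set(sex_matrix.labels))
    if len(shared) < 4:
        raise InvalidArgumentError("need >= 4 shared species")
    a = squareform(ddm.to_dataframe().loc[shared, shared].to_numpy(),
                   checks=False)
    b = squareform(sex_matrix.to_dataframe().loc[shared, shared].to_numpy(),
                   checks=False)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("constant condensed vector")
    res = spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


def sex_distance_matrices(embedding: EmbeddingTable, manifest: DatasetManifest,
                          surface: str = "both"
                          ) -> tuple[SubsetDistanceMatrix, SubsetDistanceMatrix]:
    """Convenience: (male, female) inter-species centroid distance matrices."""
    male = pairwise_centroid_distances(
        subset_centroids(embedding, manifest, sex="male", surface=surface))
    female = pairwise_centroid_distances(
        subset_centroids(embedding, manifest, sex="female", surface=surface))
    return male, female
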