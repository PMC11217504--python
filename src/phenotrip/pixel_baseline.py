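"""Pixel-correlation baseline for whole-image similarity.

A deliberately simple comparator against which the learnt embedding is
judged: the Pearson correlation of overlying RGB pixel values between two
uniformly scaled images, turned into a species-level distance (1 - mean r)
and a neighbour-joining tree.  Ventral images are flipped horizontally
before comparison so they match the orientation of dorsal views.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from .dataset_io import (
    DatasetManifest,
    ImageRecord,
    flip_horizontal,
    rescale_image,
    resize_to,
)
from .disparity_stats import SubsetDistanceMatrix, SubsetKey
from .errors import InvalidArgumentError, UndefinedCorrelationError
from .phylo_congruence import nj_tree, rescale_matrix

logger = logging.getLogger(__name__)


@dataclass
class PixelComparisonConfig:
    resolutions: tuple[int, ...] = (64, 32, 16)
    sample_size: int = 1000
    seed: int = 0
    flip_ventral: bool = True
    channel_mode: str = "pooled"   # or "per_channel": mean of per-channel r

    def __post_init__(self):
        if any(r < 2 for r in self.resolutions):
            raise InvalidArgumentError("resolutions must be >= 2 px")
        if self.sample_size < 2:
            raise InvalidArgumentError("sample_size must be >= 2")
        if self.channel_mode not in ("pooled", "per_channel"):
            raise InvalidArgumentError(f"unknown mode {self.channel_mode!r}")


def _corr(a: np.ndarray, b: np.ndarray, on_constant: str) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        if on_constant == "zero":
            return 0.0
        raise UndefinedCorrelationError("constant pixel intensities")
    return float(pearsonr(a, b).statistic)


def pixel_correlation(a: ImageRecord, b: ImageRecord, resolution: int,
                      on_constant: str = "raise",
                      channel_mode: str = "pooled") -> float:
    """Pearson r of overlying RGB pixels after uniform rescaling.

    The first image is rescaled to ``resolution`` pixels high (aspect
    preserved); the second is then rescaled to the first's exact dimensions.
    ``channel_mode="pooled"`` correlates all channels as one vector;
    ``"per_channel"`` averages the three per-channel correlations.
    """
    ra = rescale_image(a, resolution)
    h, w = ra.pixels.shape[:2]
    rb = resize_to(b, h, w)
    pa = ra.pixels.astype(float)
    pb = rb.pixels.astype(float)
    if channel_mode == "pooled":
        return _corr(pa.ravel(), pb.ravel(), on_constant)
    rs = [_corr(pa[:, :, c].ravel(), pb[:, :, c].ravel(), on_constant)
          for c in range(3)]
    return float(np.mean(rs))


def species_pixel_distance_matrix(manifest: DatasetManifest,
                                  cfg: PixelComparisonConfig,
                                  resolution: int | None = None
                                  ) -> SubsetDistanceMatrix:
    """Inter-species distance 1 - mean pixel correlation.

    Up to ``sample_size`` images are drawn uniformly without replacement;
    every cross-species pair among the sample is compared at the requested
    resolution (default: the first configured one).  Species pairs with no
    sampled comparison are reported and left as missing (NaN is rejected by
    the matrix type, so such runs raise after the report).
    """
    res = resolution if resolution is not None else cfg.resolutions[0]
    rng = np.random.default_rng(cfg.seed)
    n = len(manifest)
    take = min(cfg.sample_size, n)
    idx = rng.choice(n, size=take, replace=False)
    sample = [manifest.records[i] for i in idx]
    if cfg.flip_ventral:
        sample = [flip_horizontal(r) if r.surface == "ventral" else r
                  for r in sample]

    species = sorted({r.species for r in sample})
    pos = {s: k for k, s in enumerate(species)}
    sums = np.zeros((len(species), len(species)))
    counts = np.zeros((len(species), len(species)), dtype=int)
    n_constant = 0
    for i in range(len(sample)):
        for j in range(i + 1, len(sample)):
            a, b = sample[i], sample[j]
            if a.species == b.species:
                continue
            r = pixel_correlation(a, b, res, on_constant="zero",
                                  channel_mode=cfg.channel_mode)
            if r == 0.0:
                n_constant += 1  # possibly a degenerate flat pair
            si, sj = pos[a.species], pos[b.species]
            sums[si, sj] += r
            sums[sj, si] += r
            counts[si, sj] += 1
            counts[sj, si] += 1
    if n_constant:
        logger.info("%d comparisons involved constant intensities (r := 0)",
                    n_constant)
    missing = [(species[i], species[j])
               for i in range(len(species)) for j in range(i + 1, len(species))
               if counts[i, j] == 0]
    if missing:
        raise InvalidArgumentError(
            f"species pairs with no sampled comparison: {missing}"
        )
    with np.errstate(invalid="ignore"):
        mean_r = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    dist = 1.0 - mean_r
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    dist = np.maximum(dist, 0.0)
    keys = [SubsetKey(s) for s in species]
    return SubsetDistanceMatrix(keys=keys, values=dist)


def baseline_tree(m: SubsetDistanceMatrix, rescale: bool = False):
    """Neighbour-joining tree from the pixel distance matrix
    (optionally rescaled to a proportion of its maximum first)."""
    if rescale:
        m = rescale_matrix(m)
    return nj_tree(m)
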