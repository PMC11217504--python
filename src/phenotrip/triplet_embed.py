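"""Triplet-margin metric learning of specimen-image embeddings.

A small convolutional encoder maps every photograph to a point in a
``embed_dim``-dimensional Euclidean space.  Training minimises the hinge
triplet loss max(0, ||a-p|| - ||a-n|| + margin) over triplets sampled
species-uniformly (the "same" species drawn with equal probability from the
species list, regardless of how many photographs it has, to neutralise
collection imbalance).  Alongside the loss, the Pearson correlation between
inter-species embedding distances and an independent genetic distance matrix
is logged at a fixed epoch interval, so embedding quality can be tracked
against evolutionary signal while training runs.

Two random streams keep runs reproducible: a data-order stream (default seed
12345) drives triplet sampling, and a training stream drives weight
initialisation and augmentation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from ._nn import (
    Adam,
    Encoder,
    affine_warp_batch,
    random_affine_mats,
    triplet_batch_loss,
)
from .dataset_io import DatasetManifest, ImageRecord
from .errors import (
    InvalidArgumentError,
    InvalidDatasetError,
    UndefinedCorrelationError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AffineLimits:
    """Bounds for random-affine augmentation (translation fraction of each
    image dimension, multiplicative scale range, shear in degrees)."""

    translate: float = 0.08
    scale: tuple[float, float] = (0.9, 1.1)
    shear: float = 5.0

    @property
    def is_identity(self) -> bool:
        return (self.translate == 0 and self.shear == 0
                and self.scale[0] == 1 and self.scale[1] == 1)


@dataclass
class EncoderConfig:
    """Hyper-parameters of the encoder and its training run.

    ``margin`` may be a single value or a sequence (a margin sweep); training
    itself always uses a single margin, see :func:`margin_sweep`.
    ``triplets_per_epoch`` defaults to ceil(n_images / 3), i.e. one expected
    presentation of each image per epoch.
    """

    embed_dim: int = 64
    margin: float = 0.2
    conv_blocks: int = 3
    channels: tuple[int, ...] = (8, 16, 32)
    learning_rate: float = 3e-4
    batch_size: int = 32
    epochs: int = 150
    checkpoint_epochs: tuple[int, ...] | None = None
    report_interval: int = 10
    data_order_seed: int = 12345
    training_seed: int = 0
    triplets_per_epoch: int | None = None
    pool: str = "flatten"   # spatial head: "flatten" keeps the feature map,
                            # "gap" collapses it to channel means
    augment: AffineLimits | None = field(default_factory=AffineLimits)

    def __post_init__(self):
        if self.embed_dim < 2:
            raise InvalidArgumentError("embed_dim must be >= 2")
        if self.report_interval < 1:
            raise InvalidArgumentError("report_interval must be >= 1")
        if len(self.channels) != self.conv_blocks:
            raise InvalidArgumentError("channels must list one width per block")
        if self.checkpoint_epochs is not None:
            bad = [e for e in self.checkpoint_epochs
                   if e < 0 or e > self.epochs]
            if bad:
                raise InvalidArgumentError(
                    f"checkpoint epochs outside [0, epochs]: {bad}"
                )

    @property
    def resolved_checkpoints(self) -> tuple[int, ...]:
        if self.checkpoint_epochs is None:
            return (self.epochs,)
        return tuple(self.checkpoint_epochs)


def margin_sweep(cfg: EncoderConfig, margins) -> list[EncoderConfig]:
    """Configs identical to ``cfg`` but spanning a range of margin values."""
    return [replace(cfg, margin=float(m)) for m in margins]


@dataclass(frozen=True)
class Triplet:
    anchor: ImageRecord
    positive: ImageRecord
    negative: ImageRecord

    def __post_init__(self):
        if self.anchor.species != self.positive.species:
            raise InvalidArgumentError("anchor and positive must share species")
        if self.negative.species == self.anchor.species:
            raise InvalidArgumentError("negative must be a different species")
        if self.anchor.image_id == self.positive.image_id:
            raise InvalidArgumentError("anchor and positive must differ")


@dataclass
class EmbeddingTable:
    """Per-image embedding coordinates, indexed by image_id."""

    vectors: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def ids(self) -> list[str]:
        return list(self.vectors.index)

    @property
    def array(self) -> np.ndarray:
        return self.vectors.to_numpy()

    def __len__(self):
        return len(self.vectors)


@dataclass
class TrainingLog:
    """Per-epoch mean loss and periodic genetic-distance correlations."""

    losses: pd.DataFrame          # columns: epoch, loss
    correlations: pd.DataFrame    # columns: epoch, genetic_r, n_pairs


def _species_index(manifest: DatasetManifest):
    by_species: dict[str, list[int]] = {}
    for i, rec in enumerate(manifest.records):
        by_species.setdefault(rec.species, []).append(i)
    return by_species


def sample_triplet(manifest: DatasetManifest, rng: np.random.Generator) -> Triplet:
    """Draw one species-uniform triplet.

    The "same" species is drawn uniformly from the species list (species with
    fewer than two images are excluded from that role, with a warning); its
    two images are drawn uniformly without replacement; the negative comes
    from a uniformly chosen different species, then a uniform image of it.
    """
    by_species = _species_index(manifest)
    if len(by_species) < 2:
        raise InvalidDatasetError("triplet sampling needs >= 2 species")
    i_a, i_p, i_n = _sample_triplet_indices(by_species, rng)
    return Triplet(
        anchor=manifest.records[i_a],
        positive=manifest.records[i_p],
        negative=manifest.records[i_n],
    )


def _sample_triplet_indices(by_species, rng):
    species = sorted(by_species)
    eligible = [s for s in species if len(by_species[s]) >= 2]
    if len(eligible) < len(species):
        logger.warning(
            "%d species with < 2 images excluded from the same-species role",
            len(species) - len(eligible),
        )
    if not eligible or len(species) < 2:
        raise InvalidDatasetError("no species with >= 2 images")
    same = eligible[int(rng.integers(len(eligible)))]
    pair = rng.choice(len(by_species[same]), size=2, replace=False)
    others = [s for s in species if s != same]
    neg_sp = others[int(rng.integers(len(others)))]
    i_n = by_species[neg_sp][int(rng.integers(len(by_species[neg_sp])))]
    return by_species[same][int(pair[0])], by_species[same][int(pair[1])], i_n


def triplet_margin_loss(a, p, n, margin: float) -> float:
    """Hinge triplet loss max(0, ||a-p|| - ||a-n|| + margin) on raw vectors."""
    a, p, n = (np.asarray(v, dtype=float) for v in (a, p, n))
    if not (a.shape == p.shape == n.shape):
        raise InvalidArgumentError("triplet vectors must share dimensions")
    return float(max(0.0, np.linalg.norm(a - p) - np.linalg.norm(a - n) + margin))


def augment(rec: ImageRecord, rng: np.random.Generator,
            limits: AffineLimits) -> ImageRecord:
    """Random-affine augmentation (translation, scale, shear) of one image."""
    if limits.is_identity:
        return rec
    x = rec.pixels.astype(np.float64).transpose(2, 0, 1)[None] / 255.0
    mats = random_affine_mats(rng, 1, x.shape[2], x.shape[3],
                              limits.translate, limits.scale, limits.shear)
    out = affine_warp_batch(x, mats)[0].transpose(1, 2, 0)
    pixels = np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)
    return replace(rec, pixels=pixels)


def _stack_images(manifest: DatasetManifest) -> np.ndarray:
    """(N, 3, H, Wmax) float array; widths padded with each image's corner
    background colour, split evenly left/right."""
    heights = {r.pixels.shape[0] for r in manifest.records}
    if len(heights) != 1:
        raise InvalidArgumentError(
            f"images must share a uniform height, got {sorted(heights)}"
        )
    w_max = max(r.pixels.shape[1] for r in manifest.records)
    h = heights.pop()
    out = np.empty((len(manifest), 3, h, w_max), dtype=np.float32)
    for i, rec in enumerate(manifest.records):
        px = rec.pixels.astype(np.float32) / 255.0
        w = px.shape[1]
        left = (w_max - w) // 2
        canvas = np.empty((h, w_max, 3), dtype=np.float32)
        canvas[:] = px[0, 0]
        canvas[:, left:left + w] = px
        out[i] = canvas.transpose(2, 0, 1)
    return out


def embed_dataset(encoder: Encoder, manifest: DatasetManifest,
                  _stacked: np.ndarray | None = None,
                  provenance: dict | None = None) -> EmbeddingTable:
    """Embed every image of the manifest; batch-order invariant."""
    x = _stacked if _stacked is not None else _stack_images(manifest)
    chunks = []
    for start in range(0, len(x), 256):
        chunks.append(encoder.forward(x[start:start + 256], train=False))
    emb = np.concatenate(chunks) if chunks else np.empty((0, encoder.embed_dim))
    if not np.all(np.isfinite(emb)):
        raise InvalidArgumentError("non-finite embedding values")
    ids = [r.image_id for r in manifest.records]
    return EmbeddingTable(
        vectors=pd.DataFrame(emb, index=pd.Index(ids, name="image_id")),
        provenance=provenance or {},
    )


def genetic_correlation(embedding: EmbeddingTable, manifest: DatasetManifest,
                        genetic_matrix: pd.DataFrame,
                        method: str = "centroid") -> tuple[float, int]:
    """Pearson r between condensed inter-species embedding and genetic
    distances over the shared species set.

    ``method="centroid"`` uses Euclidean distances between species mean
    embeddings; ``method="image_mean"`` averages all cross-species image-pair
    distances instead.
    """
    species = sorted(set(manifest.species_list) & set(genetic_matrix.index))
    skipped = len(set(manifest.species_list) - set(species))
    if skipped:
        logger.info("%d species absent from genetic matrix skipped", skipped)
    if len(species) < 3:
        raise InvalidArgumentError("need >= 3 shared species")

    vec = embedding.vectors
    by_sp = {s: [] for s in species}
    for rec in manifest.records:
        if rec.species in by_sp:
            by_sp[rec.species].append(rec.image_id)

    if method == "centroid":
        cents = np.stack([vec.loc[by_sp[s]].mean(axis=0).to_numpy()
                          for s in species])
        emb_cond = pdist(cents)
    elif method == "image_mean":
        n = len(species)
        m = np.zeros((n, n))
        for i in range(n):
            xi = vec.loc[by_sp[species[i]]].to_numpy()
            for j in range(i + 1, n):
                xj = vec.loc[by_sp[species[j]]].to_numpy()
                d = np.sqrt(((xi[:, None, :] - xj[None, :, :]) ** 2).sum(-1))
                m[i, j] = m[j, i] = d.mean()
        emb_cond = squareform(m, checks=False)
    else:
        raise InvalidArgumentError(f"unknown method {method!r}")

    gen_cond = squareform(
        genetic_matrix.loc[species, species].to_numpy(), checks=False
    )
    if np.ptp(emb_cond) == 0 or np.ptp(gen_cond) == 0:
        raise UndefinedCorrelationError("zero variance in condensed distances")
    r = float(pearsonr(emb_cond, gen_cond).statistic)
    return r, len(emb_cond)


def train(manifest: DatasetManifest,
          genetic_matrix: pd.DataFrame | None,
          cfg: EncoderConfig) -> tuple[dict[int, EmbeddingTable], TrainingLog]:
    """Train the encoder; returns checkpoint embeddings and the training log.

    Fully reproducible given ``cfg.data_order_seed`` (triplet sampling) and
    ``cfg.training_seed`` (weight init and augmentation).  Loss is logged
    every epoch; the genetic-distance correlation every ``report_interval``
    epochs (when a genetic matrix is supplied).
    """
    by_species = _species_index(manifest)
    if len(by_species) < 2:
        raise InvalidDatasetError("training needs >= 2 species")
    x_all = _stack_images(manifest)
    n = len(manifest)

    order_rng = np.random.default_rng(cfg.data_order_seed)
    train_rng = np.random.default_rng(cfg.training_seed)
    encoder = Encoder(cfg.channels, cfg.embed_dim, train_rng,
                      input_hw=x_all.shape[2:], pool=cfg.pool)
    opt = Adam(encoder.params(), lr=cfg.learning_rate)

    n_trip = cfg.triplets_per_epoch or max(1, math.ceil(n / 3))
    checkpoints: dict[int, EmbeddingTable] = {}
    prov = {"config": repr(cfg)}
    if 0 in cfg.resolved_checkpoints:
        checkpoints[0] = embed_dataset(encoder, manifest, x_all,
                                       {**prov, "epoch": 0})

    loss_rows, corr_rows = [], []
    for epoch in range(1, cfg.epochs + 1):
        idx = np.array([
            _sample_triplet_indices(by_species, order_rng)
            for _ in range(n_trip)
        ])
        epoch_losses = []
        for start in range(0, n_trip, cfg.batch_size):
            batch = idx[start:start + cfg.batch_size]
            flat = np.concatenate([batch[:, 0], batch[:, 1], batch[:, 2]])
            xb = x_all[flat]
            if cfg.augment is not None and not cfg.augment.is_identity:
                mats = random_affine_mats(
                    train_rng, len(flat), xb.shape[2], xb.shape[3],
                    cfg.augment.translate, cfg.augment.scale, cfg.augment.shear,
                )
                xb = affine_warp_batch(xb, mats)
            emb = encoder.forward(xb, train=True)
            loss, d_emb = triplet_batch_loss(emb, cfg.margin)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite triplet loss at epoch {epoch}: {loss}"
                )
            encoder.backward(d_emb)
            opt.step()
            epoch_losses.append(loss)
        loss_rows.append((epoch, float(np.mean(epoch_losses))))

        if genetic_matrix is not None and epoch % cfg.report_interval == 0:
            table = embed_dataset(encoder, manifest, x_all,
                                  {**prov, "epoch": epoch})
            try:
                r, n_pairs = genetic_correlation(table, manifest, genetic_matrix)
            except UndefinedCorrelationError:
                r, n_pairs = float("nan"), 0
            corr_rows.append((epoch, r, n_pairs))

        if epoch in cfg.resolved_checkpoints:
            checkpoints[epoch] = embed_dataset(encoder, manifest, x_all,
                                               {**prov, "epoch": epoch})

    log = TrainingLog(
        losses=pd.DataFrame(loss_rows, columns=["epoch", "loss"]),
        correlations=pd.DataFrame(
            corr_rows, columns=["epoch", "genetic_r", "n_pairs"]
        ),
    )
    return checkpoints, log


def ensemble_species_distance_matrix(manifest: DatasetManifest,
                                     cfg: EncoderConfig, n_runs: int = 3,
                                     sex: str = "both",
                                     surface: str = "both"):
    """Species centroid-distance matrix averaged over independent runs.

    A single short training run leaves run-specific distortion in the
    inter-species distances; averaging the centroid-distance matrices of
    ``n_runs`` runs (run ``k`` offsets both seeds by ``100 * k``) gives a
    steadier estimate of morphospace structure, and is the recommended input
    for phenotypic tree building.
    """
    from .disparity_stats import (
        SubsetDistanceMatrix,
        pairwise_centroid_distances,
        subset_centroids,
    )

    if n_runs < 1:
        raise InvalidArgumentError("n_runs must be >= 1")
    mats = []
    for k in range(n_runs):
        run_cfg = replace(
            cfg,
            training_seed=cfg.training_seed + 100 * k,
            data_order_seed=cfg.data_order_seed + 100 * k,
            checkpoint_epochs=(cfg.epochs,),
        )
        checkpoints, _ = train(manifest, None, run_cfg)
        cents = subset_centroids(checkpoints[cfg.epochs], manifest,
                                 sex=sex, surface=surface)
        mats.append(pairwise_centroid_distances(cents))
    keys = mats[0].keys
    return SubsetDistanceMatrix(
        keys=keys, values=np.mean([m.values for m in mats], axis=0)
    )
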