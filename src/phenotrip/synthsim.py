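"""Synthetic specimen-image simulator.

Emulates a museum photograph collection of a sexually dimorphic butterfly
radiation: a species phylogeny is simulated under a pure-birth process,
latent phenotype parameters (wing shape, colour, pattern) evolve along it by
Brownian motion with sex-specific rates, and a parametric renderer turns each
species x sex phenotype into four-winged, bilaterally symmetric RGB images in
dorsal and ventral view.  Gene-tree samples are produced by jittering the
species tree (lognormal branch-length noise plus occasional
nearest-neighbour-interchange moves), standing in for a posterior sample of
coalescent species trees.

The two headline regimes are male-divergent evolution (male Brownian rate
greater than female) and its inversion; a null regime sets the rates equal.
Dimorphism is a constant offset between the sexes' latent traits, so all
species are dimorphic even at rate zero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd
import yaml

from .dataset_io import ImageRecord, DatasetManifest, save_dataset
from .errors import InvalidArgumentError

# Latent trait vector layout (all real-valued; clamped at render time only).
TRAIT_NAMES = (
    "forewing_aspect",
    "hindwing_aspect",
    "tail_length",
    "base_hue",
    "patch_hue",
    "patch_x",
    "patch_y",
    "patch_size",
    "spot_count",
    "saturation",
)
N_TRAITS = len(TRAIT_NAMES)

# Ancestral phenotype at the root of the tree.
BASE_TRAITS = np.array(
    [1.0, 1.0, 0.2, 0.08, 0.55, 0.5, 0.4, 0.4, 2.0, 0.85], dtype=float
)

# Direction of the constant male-minus-female dimorphism offset.  Kept to
# colour and spot-count components: these render with the same pixel
# sensitivity at both sexes' operating points, so the offset separates the
# sexes without inflating either sex's image variance (structural traits
# like tail length or patch size would).
DIMORPHISM_DIRECTION = np.array(
    [0.0, 0.0, 0.0, 0.12, 0.10, 0.0, 0.0, 0.0, 1.0, 0.08], dtype=float
)

BACKGROUND_RGB = (0.82, 0.82, 0.80)


@dataclass
class SpeciesPhylogeny:
    """Ground-truth species tree: rooted binary ultrametric, unit root depth.

    ``regime_map`` assigns each edge (keyed by the preorder index of its child
    node) to a named selective regime; the simulator starts every edge in
    ``"default"``.
    """

    tree: dendropy.Tree
    taxa: list[str]
    regime_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise InvalidArgumentError("taxa must be unique")
        if not self.regime_map:
            self.regime_map = {
                i: "default" for i, _ in enumerate(self.tree.preorder_node_iter())
            }

    @property
    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    def root_to_tip_depths(self) -> dict[str, float]:
        out = {}
        for leaf in self.tree.leaf_node_iter():
            out[leaf.taxon.label] = leaf.distance_from_root()
        return out

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = list(self.root_to_tip_depths().values())
        return max(depths) - min(depths) <= tol

    def patristic_matrix(self) -> pd.DataFrame:
        """Symmetric DataFrame of leaf-to-leaf path lengths."""
        pdm = self.tree.phylogenetic_distance_matrix()
        labels = sorted(t.label for t in self.tree.taxon_namespace)
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        n = len(labels)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
                m[i, j] = m[j, i] = d
        return pd.DataFrame(m, index=labels, columns=labels)


@dataclass
class SimScenario:
    """Full specification of one synthetic-collection run.

    Rates are Brownian-motion variances per unit tree depth (the tree is
    rescaled to unit root depth); ``dimorphism_offset`` scales the constant
    male-female latent offset; ``noise_sd`` is per-pixel Gaussian noise on the
    0..1 intensity scale; ``trait_jitter_sd`` is the per-specimen latent
    variation within a species x sex cell.
    """

    n_species: int = 8
    images_per_species_sex_surface: int = 12
    male_rate: float = 0.08
    female_rate: float = 0.02
    dimorphism_offset: float = 0.6
    render_size: int = 32
    noise_sd: float = 0.02
    seed: int = 0
    trait_jitter_sd: float = 0.02
    n_gene_trees: int = 100
    gene_tree_jitter: float = 0.1

    def __post_init__(self):
        if self.n_species < 2:
            raise InvalidArgumentError("n_species must be >= 2")
        if self.images_per_species_sex_surface < 1:
            raise InvalidArgumentError("need >= 1 image per cell")
        if self.male_rate < 0 or self.female_rate < 0:
            raise InvalidArgumentError("rates must be >= 0")

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimScenario":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class PhenotypeEntry:
    """Latent phenotype of one species x sex cell."""

    species: str
    sex: str
    traits: np.ndarray


@dataclass
class PhenotypeParams:
    """Latent phenotypes for every species x sex cell of a scenario."""

    entries: dict[tuple[str, str], PhenotypeEntry]

    def traits(self, species: str, sex: str) -> np.ndarray:
        return self.entries[(species, sex)].traits

    def latent_distance(self, sp1: str, sp2: str, sex: str) -> float:
        return float(
            np.linalg.norm(self.traits(sp1, sex) - self.traits(sp2, sex))
        )


def simulate_phylogeny(n_species: int, seed: int) -> SpeciesPhylogeny:
    """Pure-birth (Yule) tree with ``n_species`` leaves, unit root depth.

    Lineages split at rate 1 each; the simulation runs one further waiting
    time after the last split so pendant edges are positive, then all branch
    lengths are rescaled so every root-to-tip path equals 1.
    """
    if n_species < 2:
        raise InvalidArgumentError("n_species must be >= 2")
    rng = np.random.default_rng(seed)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    # birth time of each currently-active lineage's node
    active = []
    for _ in range(2):
        child = root.new_child()
        child.birth_time = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node.edge.length = t - node.birth_time
        for _ in range(2):
            child = node.new_child()
            child.birth_time = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / n_species)
    for node in active:
        node.edge.length = t_end - node.birth_time
    root.edge.length = 0.0

    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= t_end

    for i, leaf in enumerate(tree.leaf_node_iter()):
        label = f"sp{i + 1:02d}"
        leaf.taxon = tns.require_taxon(label=label)
    tree.is_rooted = True
    taxa = sorted(t_.label for t_ in tns)
    return SpeciesPhylogeny(tree=tree, taxa=taxa)


def evolve_phenotypes(
    phylogeny: SpeciesPhylogeny,
    scenario: SimScenario,
    regime_rates: dict[str, dict[str, float]] | None = None,
) -> PhenotypeParams:
    """Brownian-motion trait evolution with sex-specific rates.

    Both sexes evolve on the same tree with independent increments; each
    trait is independent with variance rate * branch length.  Males
    additionally receive the constant offset
    ``dimorphism_offset * DIMORPHISM_DIRECTION``.  ``regime_rates`` may map a
    regime name to ``{"female": rate, "male": rate}`` overriding the scenario
    rates on edges assigned to that regime.
    """
    rng = np.random.default_rng([scenario.seed, 1])
    entries: dict[tuple[str, str], PhenotypeEntry] = {}
    preorder = list(phylogeny.tree.preorder_node_iter())
    node_index = {id(n): i for i, n in enumerate(preorder)}

    for sex, base_rate in (("female", scenario.female_rate),
                           ("male", scenario.male_rate)):
        values = {id(phylogeny.tree.seed_node): BASE_TRAITS.copy()}
        for node in preorder:
            if node is phylogeny.tree.seed_node:
                continue
            regime = phylogeny.regime_map.get(node_index[id(node)], "default")
            rate = base_rate
            if regime_rates and regime in regime_rates:
                rate = regime_rates[regime].get(sex, base_rate)
            bl = node.edge.length or 0.0
            step = rng.normal(0.0, np.sqrt(max(rate * bl, 0.0)), N_TRAITS)
            values[id(node)] = values[id(node.parent_node)] + step
        for leaf in phylogeny.tree.leaf_node_iter():
            traits = values[id(leaf)].copy()
            if sex == "male":
                traits = traits + scenario.dimorphism_offset * DIMORPHISM_DIRECTION
            entries[(leaf.taxon.label, sex)] = PhenotypeEntry(
                species=leaf.taxon.label, sex=sex, traits=traits
            )
    return PhenotypeParams(entries=entries)


def _hsv_to_rgb(h: float, s: float, v: float) -> np.ndarray:
    h = h % 1.0
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    rgb = [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]
    return np.array(rgb)


def _soft_mask(dist: np.ndarray, width: float) -> np.ndarray:
    """1 inside (dist < 0), 0 outside, smooth over ``width``."""
    return 1.0 / (1.0 + np.exp(np.clip(dist / width, -40, 40)))


def _clamp(x, lo, hi):
    return float(np.clip(x, lo, hi))


def _squash(t: float, center: float, gain: float, spread: float = 1.0) -> float:
    """Smooth monotone map of a latent trait into a renderable range.

    Maps the real line into ``center +- gain`` with slope ``gain / spread``
    at the centre; ``spread`` (in latent units) sets where saturation begins,
    so per-trait render gain can be balanced without truncating the realistic
    range of trait excursions.  Never flattens, so pixel response stays
    monotone in the latent trait.
    """
    return center + gain * float(np.tanh((t - center) / spread))


def render_specimen(
    entry: PhenotypeEntry,
    surface: str,
    scenario: SimScenario,
    specimen_seed: int,
    image_id: str | None = None,
) -> ImageRecord:
    """Render one specimen image from a latent phenotype.

    The canvas is built from the absolute horizontal coordinate, so the image
    is exactly bilaterally symmetric before pixel noise is added.  The
    ventral surface is a deterministic muting of the dorsal parameters:
    reduced saturation, lighter wings, patch coordinates swapped and patch
    hue shifted.
    """
    if surface not in ("dorsal", "ventral"):
        raise InvalidArgumentError(f"unknown surface {surface!r}")
    if not np.all(np.isfinite(entry.traits)):
        raise InvalidArgumentError("phenotype traits must be finite")
    rng = np.random.default_rng(specimen_seed)
    tr = entry.traits + rng.normal(0.0, scenario.trait_jitter_sd, N_TRAITS)

    # gains are balanced so every trait moves the image by a comparable
    # amount per unit latent change (hue would otherwise dominate)
    fa = _squash(tr[0], 1.0, 0.80)
    ha = _squash(tr[1], 1.0, 0.70)
    tail = 0.5 * (1.0 + float(np.tanh(tr[2] - 0.2)))      # (0, 1), 0.5 at base
    base_hue = _squash(tr[3], 0.08, 0.04)
    patch_hue = _squash(tr[4], 0.55, 0.12)
    px = _squash(tr[5], 0.5, 0.13)
    py = _squash(tr[6], 0.4, 0.24)
    psize = _squash(tr[7], 0.4, 0.50)
    # (gains above are balanced for comparable pixel response per trait;
    # spread = 1 latent unit keeps the map near-linear over realistic
    # Brownian excursions)
    spots = 3.0 * (1.0 + float(np.tanh((tr[8] - 2.0) / 3.0)))   # continuous
    sat = _squash(tr[9], 0.8, 0.18)
    value = 0.75

    if surface == "ventral":
        sat *= 0.55
        value = 0.88
        base_hue = base_hue + 0.04
        patch_hue = patch_hue + 0.15
        px, py = py, px

    S = int(scenario.render_size)
    y = (np.arange(S) + 0.5)[:, None] / S          # 0 (top) .. 1 (bottom)
    x = ((np.arange(S) + 0.5) / S) * 2.0 - 1.0     # -1 .. 1, signed
    ax = np.abs(x)[None, :]                        # symmetric coordinate
    yy = np.broadcast_to(y, (S, S))
    w = 1.5 / S                                    # soft edge width

    canvas = np.empty((S, S, 3))
    canvas[:] = BACKGROUND_RGB

    def paint(mask, rgb):
        canvas[:] = canvas * (1 - mask[..., None]) + mask[..., None] * rgb

    wing_rgb = _hsv_to_rgb(base_hue, sat, value)
    hind_rgb = _hsv_to_rgb(base_hue + 0.03, sat, value * 0.85)
    patch_rgb = _hsv_to_rgb(patch_hue, min(1.0, sat + 0.1), 0.9)
    dark = np.array([0.12, 0.10, 0.08])

    # hindwing: lower ellipse, elongated by the tail parameter
    hb_a, hb_b = 0.32 * np.sqrt(ha), 0.20 / np.sqrt(ha)
    hcx, hcy = 0.30, 0.60
    d_hind = np.sqrt(((ax - hcx) / hb_a) ** 2 + ((yy - hcy) / hb_b) ** 2) - 1.0
    paint(_soft_mask(d_hind, w / hb_b), hind_rgb)
    # tail lobe below the hindwing
    t_len = 0.40 * tail
    if t_len > 0:
        d_tail = np.sqrt(((ax - 0.28) / 0.13) ** 2
                         + ((yy - (hcy + hb_b + t_len / 2)) / (t_len / 2 + 1e-9)) ** 2) - 1.0
        paint(_soft_mask(d_tail, w / max(t_len / 2, w)), hind_rgb)

    # forewing: upper ellipse
    fb_a, fb_b = 0.40 * np.sqrt(fa), 0.20 / np.sqrt(fa)
    fcx, fcy = 0.45, 0.30
    d_fore = np.sqrt(((ax - fcx) / fb_a) ** 2 + ((yy - fcy) / fb_b) ** 2) - 1.0
    fore_mask = _soft_mask(d_fore, w / fb_b)
    paint(fore_mask, wing_rgb)

    # forewing patch
    pr = 0.05 + 0.12 * psize
    pcx = 0.15 + 0.6 * px
    pcy = 0.12 + 0.4 * py
    d_patch = np.sqrt((ax - pcx) ** 2 + (yy - pcy) ** 2) - pr
    paint(_soft_mask(d_patch, w) * fore_mask, patch_rgb)

    # hindwing spots at fixed angular stations; the last spot fades in with
    # the fractional part so the map stays continuous in the latent trait
    spot_angles = np.linspace(-0.9, 0.9, 6)
    n_full = int(spots)
    for k in range(min(n_full + 1, 6)):
        alpha = 1.0 if k < n_full else spots - n_full
        if alpha <= 0:
            continue
        scx = hcx + 0.55 * hb_a * np.sin(spot_angles[k])
        scy = hcy + 0.55 * hb_b * np.cos(spot_angles[k])
        d_spot = np.sqrt((ax - scx) ** 2 + (yy - scy) ** 2) - 0.07
        paint(alpha * _soft_mask(d_spot, w), dark)

    # body: central dark lozenge
    d_body = np.sqrt((ax / 0.05) ** 2 + (((yy - 0.45) / 0.38) ** 2)) - 1.0
    paint(_soft_mask(d_body, w / 0.38), dark)

    if scenario.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, scenario.noise_sd, canvas.shape)
    pixels = np.clip(np.round(canvas * 255.0), 0, 255).astype(np.uint8)

    return ImageRecord(
        image_id=image_id or f"{entry.species}_{entry.sex}_{surface}_{specimen_seed}",
        pixels=pixels,
        species=entry.species,
        sex=entry.sex,
        surface=surface,
    )


def simulate_gene_trees(
    phylogeny: SpeciesPhylogeny, n_trees: int, jitter: float, seed: int
) -> dendropy.TreeList:
    """Sample of gene trees around the species tree.

    Each tree is a copy of the species tree with every branch length
    multiplied by exp(N(0, jitter)) and, independently per internal edge with
    probability 1 - exp(-jitter), one nearest-neighbour-interchange applied.
    ``jitter = 0`` returns exact copies.
    """
    if n_trees < 1:
        raise InvalidArgumentError("n_trees must be >= 1")
    if jitter < 0:
        raise InvalidArgumentError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    p_nni = 1.0 - np.exp(-jitter)
    out = dendropy.TreeList(taxon_namespace=phylogeny.tree.taxon_namespace)
    for _ in range(n_trees):
        t = phylogeny.tree.clone(depth=1)
        for edge in t.preorder_edge_iter():
            if edge.length:
                edge.length = float(edge.length * np.exp(rng.normal(0.0, jitter)))
        if p_nni > 0:
            for node in list(t.preorder_node_iter()):
                if node.parent_node is None or node.is_leaf():
                    continue
                parent = node.parent_node
                siblings = [c for c in parent.child_nodes() if c is not node]
                if not siblings or not node.child_nodes():
                    continue
                if rng.random() < p_nni:
                    sib = siblings[int(rng.integers(len(siblings)))]
                    child = node.child_nodes()[
                        int(rng.integers(len(node.child_nodes())))
                    ]
                    parent.remove_child(sib)
                    node.remove_child(child)
                    parent.add_child(child)
                    node.add_child(sib)
        out.append(t)
    return out


@dataclass
class GeneratedDataset:
    """Bundle returned by :func:`generate_dataset`."""

    manifest: DatasetManifest
    metadata: pd.DataFrame
    phylogeny: SpeciesPhylogeny
    genetic_distances: pd.DataFrame
    gene_trees: dendropy.TreeList
    phenotypes: PhenotypeParams


def generate_dataset(scenario: SimScenario, out_dir=None) -> GeneratedDataset:
    """Simulate a full synthetic collection under one scenario.

    Produces n_species x 2 sexes x 2 surfaces x images_per_cell images, a
    metadata table, the true species tree, the patristic genetic-distance
    matrix, and a jittered gene-tree sample.  When ``out_dir`` is given,
    writes PNGs, metadata.csv, species_tree.nwk, gene_trees.nwk (one per
    line), genetic_distances.csv and scenario.yaml.
    """
    phylogeny = simulate_phylogeny(scenario.n_species, scenario.seed)
    phenotypes = evolve_phenotypes(phylogeny, scenario)

    records = []
    idx = 0
    for species in phylogeny.taxa:
        for sex in ("female", "male"):
            entry = phenotypes.entries[(species, sex)]
            for surface in ("dorsal", "ventral"):
                for rep in range(scenario.images_per_species_sex_surface):
                    sseed = (scenario.seed * 1_000_003 + idx * 97 + 13) % (2**31)
                    rec = render_specimen(
                        entry, surface, scenario, sseed,
                        image_id=f"img{idx:05d}_{species}_{sex}_{surface}",
                    )
                    records.append(rec)
                    idx += 1

    gene_trees = simulate_gene_trees(
        phylogeny, scenario.n_gene_trees, scenario.gene_tree_jitter,
        seed=(scenario.seed * 7_919 + 5) % (2**31),
    )
    genetic = phylogeny.patristic_matrix()
    manifest = DatasetManifest(records)
    metadata = pd.DataFrame(
        [(r.image_id, r.species, r.sex, r.surface, f"images/{r.image_id}.png")
         for r in records],
        columns=["image_id", "species", "sex", "surface", "path"],
    )

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        save_dataset(records, out_dir)
        phylogeny.tree.write(path=os.path.join(out_dir, "species_tree.nwk"),
                             schema="newick")
        gene_trees.write(path=os.path.join(out_dir, "gene_trees.nwk"),
                         schema="newick")
        genetic.to_csv(os.path.join(out_dir, "genetic_distances.csv"))
        scenario.to_yaml(os.path.join(out_dir, "scenario.yaml"))

    return GeneratedDataset(
        manifest=manifest,
        metadata=metadata,
        phylogeny=phylogeny,
        genetic_distances=genetic,
        gene_trees=gene_trees,
        phenotypes=phenotypes,
    )
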