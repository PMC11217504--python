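import numpy as np
import pandas as pd
import pytest

import phenotrip as pt
from phenotrip._nn import Encoder, triplet_batch_loss
from phenotrip.errors import (
    InvalidArgumentError,
    InvalidDatasetError,
    UndefinedCorrelationError,
)
from phenotrip.triplet_embed import _stack_images


class TestTripletMarginLoss:
    @pytest.mark.parametrize(
        "a,p,n,margin,expected",
        [
            ((0, 0), (0, 0), (1, 0), 1.0, 0.0),       # a=p, ||a-n|| = margin
            ((0, 0), (3, 4), (6, 8), 1.0, 0.0),       # 5 - 10 + 1 < 0
            ((0, 0), (0, 2), (0, 1), 0.5, 1.5),       # 2 - 1 + 0.5
            ((1, 1), (1, 1), (1, 1), 0.25, 0.25),     # degenerate: margin
        ],
    )
    def test_closed_form(self, a, p, n, margin, expected):
        assert pt.triplet_margin_loss(a, p, n, margin) == expected

    def test_dimension_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            pt.triplet_margin_loss([0, 0], [1], [2, 2], 0.1)

    def test_nonnegative_random(self, rng):
        for _ in range(100):
            v = rng.normal(size=(3, 5))
            assert pt.triplet_margin_loss(v[0], v[1], v[2], 0.3) >= 0.0


class TestSampleTriplet:
    def test_species_uniform_despite_imbalance(self):
        """Two species with 10 vs 1000 images: each is the 'same' species in
        about half of the draws."""
        records = []
        for i in range(10):
            records.append(pt.ImageRecord(
                f"a{i}", np.zeros((4, 4, 3), np.uint8), "spA", "female",
                "dorsal"))
        for i in range(1000):
            records.append(pt.ImageRecord(
                f"b{i}", np.zeros((4, 4, 3), np.uint8), "spB", "female",
                "dorsal"))
        man = pt.DatasetManifest(records)
        rng = np.random.default_rng(0)
        n_a = sum(pt.sample_triplet(man, rng).anchor.species == "spA"
                  for _ in range(10_000))
        # 3 sigma of Binomial(10000, 0.5)
        assert abs(n_a - 5000) < 3 * np.sqrt(10_000 * 0.25)

    def test_single_species_rejected(self):
        records = [pt.ImageRecord(f"x{i}", np.zeros((4, 4, 3), np.uint8),
                                  "spA", "male", "dorsal") for i in range(5)]
        with pytest.raises(InvalidDatasetError):
            pt.sample_triplet(pt.DatasetManifest(records),
                              np.random.default_rng(0))

    def test_anchor_never_equals_positive(self):
        records = [pt.ImageRecord(f"a{i}", np.zeros((4, 4, 3), np.uint8),
                                  "spA", "male", "dorsal") for i in range(2)]
        records += [pt.ImageRecord("b0", np.zeros((4, 4, 3), np.uint8),
                                   "spB", "male", "dorsal")]
        man = pt.DatasetManifest(records)
        rng = np.random.default_rng(1)
        for _ in range(1000):
            t = pt.sample_triplet(man, rng)
            assert t.anchor.image_id != t.positive.image_id
            assert t.negative.species == "spB"


class TestAugment:
    def test_zero_limits_identity(self, small_dataset, rng):
        rec = small_dataset.manifest.records[0]
        limits = pt.AffineLimits(translate=0.0, scale=(1.0, 1.0), shear=0.0)
        out = pt.augment(rec, rng, limits)
        assert np.array_equal(out.pixels, rec.pixels)

    def test_deterministic_given_rng_state(self, small_dataset):
        rec = small_dataset.manifest.records[0]
        limits = pt.AffineLimits()
        a = pt.augment(rec, np.random.default_rng(7), limits)
        b = pt.augment(rec, np.random.default_rng(7), limits)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.pixels.shape == rec.pixels.shape

    def test_translation_bounds_centroid_shift(self, small_dataset):
        """With only translation allowed, the intensity centroid moves at
        most the translation limit plus interpolation tolerance."""
        rec = small_dataset.manifest.records[0]
        h, w = rec.pixels.shape[:2]
        limits = pt.AffineLimits(translate=0.1, scale=(1.0, 1.0), shear=0.0)
        rng = np.random.default_rng(3)

        def centroid(px):
            weight = 255.0 - px.astype(float).mean(axis=2)  # dark = specimen
            total = weight.sum()
            ys = (weight.sum(axis=1) * np.arange(h)).sum() / total
            xs = (weight.sum(axis=0) * np.arange(w)).sum() / total
            return np.array([ys, xs])

        base = centroid(rec.pixels)
        for _ in range(100):
            shifted = centroid(pt.augment(rec, rng, limits).pixels)
            assert np.all(np.abs(shifted - base) <= 0.1 * h + 2.0)


class TestEncoderGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Analytic gradients of the full encoder + triplet loss agree with
        central finite differences on a tiny double-precision net."""
        enc = Encoder((4, 6), 5, rng, input_hw=(8, 8), pool="flatten")
        for p, _ in enc.params():
            p[...] = p.astype(np.float64)
        x = rng.normal(size=(6, 3, 8, 8))

        def loss_of(x_):
            emb = enc.forward(x_, train=True)
            return triplet_batch_loss(emb, 0.4)[0]

        emb = enc.forward(x, train=True)
        loss, d_emb = triplet_batch_loss(emb, 0.4)
        enc.backward(d_emb)

        for p, g in enc.params():
            flat = p.ravel()
            idx = rng.choice(flat.size, size=min(5, flat.size), replace=False)
            for i in idx:
                eps = 1e-4
                orig = flat[i]
                flat[i] = orig + eps
                up = loss_of(x)
                flat[i] = orig - eps
                down = loss_of(x)
                flat[i] = orig
                num = (up - down) / (2 * eps)
                assert g.ravel()[i] == pytest.approx(num, abs=2e-4)


class TestTrainAndEmbed:
    def test_zero_epochs_returns_initial_embedding(self, small_dataset):
        cfg = pt.EncoderConfig(epochs=0, checkpoint_epochs=(0,),
                               training_seed=3)
        ck, log = pt.train(small_dataset.manifest, None, cfg)
        assert set(ck) == {0}
        assert len(ck[0]) == len(small_dataset.manifest)
        assert len(log.losses) == 0

    def test_training_reproducible(self, small_dataset):
        cfg = pt.EncoderConfig(epochs=2, training_seed=5, batch_size=8)
        a, _ = pt.train(small_dataset.manifest, None, cfg)
        b, _ = pt.train(small_dataset.manifest, None, cfg)
        pd.testing.assert_frame_equal(a[2].vectors, b[2].vectors)

    def test_loss_logged_every_epoch_and_correlation_every_interval(
            self, small_dataset):
        cfg = pt.EncoderConfig(epochs=4, report_interval=2, training_seed=1)
        _, log = pt.train(small_dataset.manifest,
                          small_dataset.genetic_distances, cfg)
        assert list(log.losses["epoch"]) == [1, 2, 3, 4]
        assert (log.losses["loss"] >= 0).all()
        assert list(log.correlations["epoch"]) == [2, 4]
        assert log.correlations["genetic_r"].between(-1, 1).all()

    def test_embedding_batch_order_invariant(self, small_dataset, rng):
        man = small_dataset.manifest
        x = _stack_images(man)
        enc = Encoder((4,), 8, rng, input_hw=x.shape[2:], pool="flatten")
        full = pt.embed_dataset(enc, man)
        # embed a permuted copy of the manifest
        perm = list(rng.permutation(len(man.records)))
        man2 = pt.DatasetManifest([man.records[i] for i in perm])
        shuffled = pt.embed_dataset(enc, man2)
        pd.testing.assert_frame_equal(
            full.vectors.sort_index(), shuffled.vectors.sort_index()
        )

    def test_training_reduces_loss_on_easy_data(self):
        """Final-epoch triplet loss falls below the first epoch's in at least
        9 of 10 seeds on a 6-species synthetic dataset."""
        wins = 0
        for seed in range(10):
            sc = pt.SimScenario(n_species=6,
                                images_per_species_sex_surface=20,
                                seed=100 + seed)
            ds = pt.generate_dataset(sc)
            cfg = pt.EncoderConfig(epochs=30, training_seed=seed,
                                   data_order_seed=12345 + seed)
            _, log = pt.train(ds.manifest, None, cfg)
            wins += log.losses["loss"].iloc[-1] < log.losses["loss"].iloc[0]
        assert wins >= 9


class TestGeneticCorrelation:
    def _dataset_tables(self, small_dataset, distances):
        man = small_dataset.manifest
        species = sorted(man.species_list)
        # place species centroids on a line so distances are controllable
        pos = {s: p for s, p in zip(species, distances)}
        vecs = []
        ids = []
        rng = np.random.default_rng(0)
        for r in man.records:
            ids.append(r.image_id)
            vecs.append([pos[r.species], 0.0])
        return pt.EmbeddingTable(vectors=pd.DataFrame(vecs, index=ids))

    def test_proportional_distances_give_r_one(self, small_dataset):
        emb = self._dataset_tables(small_dataset, [0.0, 1.0, 3.0, 6.0])
        gm = small_dataset.genetic_distances
        species = sorted(gm.index)
        from scipy.spatial.distance import pdist, squareform as sq
        coords = np.array([[0.0], [1.0], [3.0], [6.0]])
        gm2 = pd.DataFrame(sq(pdist(coords)) * 2.5, index=species,
                           columns=species)
        r, n_pairs = pt.genetic_correlation(emb, small_dataset.manifest, gm2)
        assert r == pytest.approx(1.0)
        assert n_pairs == 6

    def test_matrix_against_itself(self, small_dataset):
        """Using genetic distances to synthesise a perfectly matching
        embedding geometry recovers r = 1 via classical MDS coordinates."""
        gm = small_dataset.genetic_distances
        species = sorted(gm.index)
        d2 = gm.loc[species, species].to_numpy() ** 2
        j = np.eye(len(species)) - 1 / len(species)
        b = -0.5 * j @ d2 @ j
        w, v = np.linalg.eigh(b)
        coords = v[:, w > 1e-10] * np.sqrt(w[w > 1e-10])
        pos = {s: coords[i] for i, s in enumerate(species)}
        man = small_dataset.manifest
        emb = pt.EmbeddingTable(vectors=pd.DataFrame(
            [pos[r.species] for r in man.records],
            index=[r.image_id for r in man.records]))
        r, _ = pt.genetic_correlation(emb, man, gm)
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_three_species_reversed_ranks(self):
        records = []
        for sp, x in (("a", 0.0), ("b", 1.0), ("c", 3.0)):
            for i in range(2):
                records.append(pt.ImageRecord(
                    f"{sp}{i}", np.zeros((4, 4, 3), np.uint8), sp, "female",
                    "dorsal"))
        man = pt.DatasetManifest(records)
        emb = pt.EmbeddingTable(vectors=pd.DataFrame(
            [[0.0], [0.0], [1.0], [1.0], [3.0], [3.0]],
            index=[r.image_id for r in records]))
        gm = pd.DataFrame(
            [[0, 3, 2], [3, 0, 1], [2, 1, 0]],
            index=["a", "b", "c"], columns=["a", "b", "c"], dtype=float,
        )
        # embedding condensed (ab, ac, bc) = (1, 3, 2); genetic = (3, 2, 1)
        from scipy.stats import pearsonr
        expected = pearsonr([1, 3, 2], [3, 2, 1]).statistic
        r, _ = pt.genetic_correlation(emb, man, gm)
        assert r == pytest.approx(expected)

    def test_zero_variance_rejected(self, small_dataset):
        man = small_dataset.manifest
        emb = pt.EmbeddingTable(vectors=pd.DataFrame(
            np.zeros((len(man), 2)), index=[r.image_id for r in man.records]))
        with pytest.raises(UndefinedCorrelationError):
            pt.genetic_correlation(emb, man, small_dataset.genetic_distances)
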