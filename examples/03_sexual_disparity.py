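"""Quantify sexual disparity differences in the learnt morphospace.

For every species pair the statistic is (inter-male centroid distance) -
(inter-female centroid distance): positive means males of the two species
are more phenotypically disparate than their females.  A male-divergent
simulation (male Brownian rate 4x the female rate) should yield a positive
mean, a Kruskal-Wallis male > female location shift, and a positive Spearman
correlation of the difference with inter-male distance.
"""

import phenotrip as pt

scenario = pt.SimScenario(n_species=8, images_per_species_sex_surface=6,
                          male_rate=0.08, female_rate=0.02, seed=3)
ds = pt.generate_dataset(scenario)
cfg = pt.EncoderConfig(epochs=40, training_seed=3)
checkpoints, _ = pt.train(ds.manifest, None, cfg)
emb = checkpoints[40]

male, female = pt.sex_distance_matrices(emb, ds.manifest)
ddm = pt.sexual_disparity_difference(male, female)
print(f"mean sexual disparity difference: "
      f"{pt.mean_disparity_difference(ddm):+.3f}  (positive = males more "
      "disparate)")

test = pt.sex_distance_location_test(male.condensed(), female.condensed())
print(f"Kruskal-Wallis H = {test['H']:.2f}, p = {test['p']:.2e}; "
      f"male mean {test['male']['mean']:.2f} vs female mean "
      f"{test['female']['mean']:.2f} over {test['male']['n']} pairs")

rho, p = pt.disparity_distance_correlation(ddm, male)
print(f"Spearman rho (difference vs inter-male distance) = {rho:+.2f}, "
      f"p = {p:.2e}")

print("\nPhenotypic distinctiveness (mean criterion, most distinct first):")
for species, score in pt.phenotypic_distinctiveness(
        pt.pairwise_centroid_distances(
            pt.subset_centroids(emb, ds.manifest)), "mean")[:3]:
    print(f"  {species}: {score:.2f}")
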