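"""Simulate a synthetic specimen collection and write it to disk.

Builds a ground-truthed stand-in for a museum photograph collection:
a Yule species tree, sex-specific Brownian phenotype evolution, rendered
dorsal/ventral specimen images, a patristic genetic-distance matrix and a
jittered gene-tree sample.
"""

import phenotrip as pt

scenario = pt.SimScenario(n_species=6, images_per_species_sex_surface=4,
                          seed=7)
ds = pt.generate_dataset(scenario, out_dir="scratch/example_collection")

print(f"images rendered : {len(ds.manifest)}")
print(f"species         : {', '.join(ds.phylogeny.taxa)}")
print(f"gene trees      : {len(ds.gene_trees)}")
print("species tree    :", ds.phylogeny.newick)
print("\nPer-subset image counts (species x sex x surface):")
print(ds.manifest.counts.to_string(index=False))
print("\nEach species contributes 2 sexes x 2 surfaces x 4 specimens = 16 "
      "images; the genetic matrix holds patristic distances on the true "
      "tree, in units of tree depth (root depth = 1).")
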