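"""Reference PCA and least-squares projection of low-coverage genomes.

Fits a PCA space on clean diploid reference genomes from two drifted
populations (with iterative 6-SD outlier screening), then projects
pseudohaploid, missing-rich genomes into that space.  Projection uses only
each genome's observed sites, so heavy missingness shifts precision, not
placement.
"""

import numpy as np

from driftscape import pca_project as pp
from driftscape import synthdata as sd
from driftscape.genodata import GenotypeMatrix

rng = np.random.default_rng(7)
n_sites = 4_000

tree = sd.DriftTree({"P0": ("root", 0.05), "P1": ("root", 0.05)}, ("P0", "P1"), ())
freqs = sd.drift_along_tree(tree, sd.sample_ancestral_freqs(n_sites, rng), rng)
calls = np.hstack([sd.genotypes_from_freqs(freqs[p], 30, rng) for p in ("P0", "P1")])
ids = [f"{p}_{j}" for p in ("P0", "P1") for j in range(30)]
matrix = GenotypeMatrix(sd.make_site_table(n_sites), ids, calls.astype(np.int8),
                        "diploid")

model = pp.fit_reference_pca(matrix, pp.PcaConfig(n_pcs=5, min_projected_sites=200))
removed = sum(len(r) for r in model.removed_per_iteration)
print(f"reference space: {len(model.retained_ids)} genomes retained, "
      f"{removed} outliers removed, {len(model.site_ids)} sites")

for leaf, miss in (("P0", 0.3), ("P0", 0.7), ("P1", 0.5)):
    ph = sd.pseudohaploidize(sd.genotypes_from_freqs(freqs[leaf], 1, rng), miss, rng)
    coords, n_used = pp.lsq_project(ph[:, 0], matrix.sites["id"].tolist(), model,
                                    min_sites=200, sample_id=leaf)
    print(f"  {leaf} genome at {int(miss*100)}% missing: "
          f"PC1 = {coords[0]:+7.2f} using {n_used} sites")

c0 = model.scores[[i for i, s in enumerate(model.retained_ids) if s[1] == "0"], 0].mean()
c1 = model.scores[[i for i, s in enumerate(model.retained_ids) if s[1] == "1"], 0].mean()
print(f"reference centroids on PC1: P0 = {c0:+.2f}, P1 = {c1:+.2f}")
# each projected genome should land on its own population's side of PC1
# regardless of missingness level.
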