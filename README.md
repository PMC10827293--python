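# driftscape

Tools for studying **spatial population structure and individual mobility
from genome-wide genotype data**, built for the ancient-DNA setting:
pseudohaploid calls, heavy and uneven missingness, and sample sets organised
by region and archaeological period.

The package answers two complementary questions:

1. *Who moved?* — an f4-statistic workflow that clusters individuals within
   each region, flags ancestry outliers, and attributes each outlier to a
   source region elsewhere, yielding a directed migration network.
2. *What does mobility do to spatial structure?* — sliding-grid FST against
   geographic distance (isolation by distance), and a continuous-space
   Wright–Fisher simulator showing how quickly long-range dispersal erodes
   that structure.

## The statistics at the core

**Clade test (qpWave-style one-component model).** For two groups *A*, *B*
and a panel of reference ("right") populations *R₁ … R_k* chosen to be
differentially related to them, form the vector

&nbsp;&nbsp;&nbsp;&nbsp;*v_j* = f4(*A*, *B*; *R₁*, *R_j*) = mean over sites of (p_A − p_B)(p_{R₁} − p_{R_j}),&nbsp;&nbsp;*j* = 2 … *k*.

If *A* and *B* form a clade relative to the panel, E[*v*] = 0. With Σ the
weighted block-jackknife covariance of *v* (5 Mb blocks), the statistic
*T* = *v*ᵀ Σ⁻¹ *v* is approximately χ² with *k* − 1 degrees of freedom, and
*d* = −log₁₀(*p*) is the dissimilarity used for clustering — *d* > 1.3
corresponds to *p* < 0.05. A two-component extension fits a target as
α·*S₁* + (1 − α)·*S₂* by generalised least squares on the same vectors.

**Outlier workflow.** Within each region, all pairs of individuals
(Copper Age up to, excluding, the present day) are clade-tested; UPGMA on
the *d*-matrix is cut at 1.3; clusters with < 5% of the region's
individuals or ≤ 2 members are outlier candidates; candidates still forming
a clade (*p* > 0.01) with a home-region majority cluster are absorbed;
survivors are tested against majority clusters of all other regions, the
resulting sources pruned by model competition (each source re-tested with
its rivals moved into the reference set) and by period priority
(same period, else nearest earlier).

**Spatial FST.** Hudson's estimator with unequal-sample-size correction,
combined across sites as a ratio of sums, between 10°×10° grid cells slid
nine times by 1°; lowess smoothing of FST against mean inter-individual
distance; confidence bands from a spatial bootstrap that resamples
connected components of the cell-overlap graph so each individual is wholly
in or out of a replicate.

**Simulator.** A constant-size population on the unit square with Gaussian
mate-choice and competition kernels, local Gaussian dispersal (SD
σ_disp), and an optional fraction p_lr of long-range dispersers forced
beyond the 99th-percentile radius of the base kernel. Dispersal and
population size are calibrated by grid search so that far-distance FST
matches the ~0.03 observed at the start of the historical period; 120
generations × 25 years then span the historical era.

## Worked example

`examples/02_outlier_workflow.py` generates a synthetic six-region fixture
(240 study individuals, 8 reference populations, 50k sites, 7 planted
cross-region migrants) and runs the full workflow:

```
fixture: 288 samples x 50000 sites, 7 planted migrants

per-region outlier proportions (fraction of individuals in outlier clusters):
     region  total  outliers  outlier_proportion
   Anatolia     31         0            0.000000
    Balkans     31         1            0.032258
     Iberia     29         2            0.068966
      Italy     31         1            0.032258
     Levant     33         1            0.030303
NorthAfrica     31         1            0.032258

migration edges (attributed source region -> outlier's region):
source_region outlier_region  count
       Iberia       Anatolia      1
  NorthAfrica        Balkans      1
     Anatolia         Iberia      2
       Levant          Italy      1
        Italy         Levant      1
      Balkans    NorthAfrica      1

planted migrants recovered as outliers: 7/7
sex-bias chi-square p-value: 0.588 (should be non-significant: migrants were planted sex-blind)
```

Every planted migrant is recovered as an outlier, each edge points from the
migrant's true source region to the region it was planted in, and no
resident is falsely flagged. The other examples cover the clade test
itself (`01`), the FST–distance curve with bootstrap bands (`03`), PCA
projection of missing-rich genomes (`04`), and the dispersal simulation
(`05`). A thin CLI (`driftscape synth|outliers|ibd|pca|simulate|calibrate`)
wraps the same drivers for file-based runs.

## Layout

```
src/driftscape/
  genodata.py          EIGENSTRAT I/O, metadata, site filters, allele counts
  fstats.py            f4 statistics, block jackknife, clade test, 2-way fit
  outlier_pipeline.py  clustering -> outliers -> sources -> migration network
  spatial_fst.py       sliding-grid Hudson FST, lowess IBD, spatial bootstrap
  pca_project.py       reference PCA, least-squares projection, simulated PCA
  spacesim.py          continuous-space Wright-Fisher simulator + calibration
  synthdata.py         drift-tree fixture generator with ground truth
  studies.py           bundled calibration experiments
  cli.py               thin command-line wrapper
```
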