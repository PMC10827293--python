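"""Reproducible study drivers built from the library primitives.

These functions bundle the experiment loops used to check the method's
statistical behaviour -- e.g. the type-I error of the clade test under a
panmictic null -- so the same code path serves tests, examples and the
reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import fstats as fs
from . import synthdata as sd


def clade_null_type1_rate(
    n_reps: int = 1_000,
    n_sites: int = 20_000,
    missingness: float = 0.4,
    d_cutoff: float = 1.3,
    seed: int = 0,
    rights_per_leaf: int = 6,
) -> dict:
    """Empirical type-I error of the one-component clade test.

    Draws the standard drift tree's frequencies once, fixes a pseudohaploid
    right panel, then generates ``n_reps`` fresh pairs of pseudohaploid
    individuals from a single panmictic leaf (fixed per-individual
    missingness) and counts how often the dissimilarity d = -log10(p)
    exceeds ``d_cutoff``.  Conditional on the leaf frequencies the pair is
    an exact clade, so the exceedance rate estimates the nominal level of
    the d > 1.3 cutoff (0.05 when the chi-square approximation is
    calibrated).
    """
    rng = np.random.default_rng(seed)
    tree = sd.standard_tree()
    ancestral = sd.sample_ancestral_freqs(n_sites, rng)
    freqs = sd.drift_along_tree(tree, ancestral, rng)
    sites = sd.make_site_table(n_sites)
    blocks = fs.make_blocks(sites)
    rights = list(tree.right_leaves)

    counts: dict = {}
    for r in rights:
        dip = sd.genotypes_from_freqs(freqs[r], rights_per_leaf, rng)
        ph = sd.pseudohaploidize(dip, 0.05, rng)
        nonmissing = ph != -1
        counts[r] = ((ph == 2).sum(axis=1), nonmissing.sum(axis=1))

    leaf = tree.regional_leaves[0]
    n_exceed = 0
    for _ in range(n_reps):
        dip = sd.genotypes_from_freqs(freqs[leaf], 2, rng)
        ph = sd.pseudohaploidize(dip, missingness, rng)
        nonmissing = ph != -1
        counts["pair_a"] = ((ph[:, :1] == 2).sum(axis=1), nonmissing[:, :1].sum(axis=1))
        counts["pair_b"] = ((ph[:, 1:] == 2).sum(axis=1), nonmissing[:, 1:].sum(axis=1))
        res = fs.one_component_test("pair_a", "pair_b", rights, counts, blocks)
        n_exceed += res.d > d_cutoff
    return {
        "rate": n_exceed / n_reps,
        "n_reps": n_reps,
        "n_sites": n_sites,
        "missingness": missingness,
        "d_cutoff": d_cutoff,
    }


def alpha_recovery(
    alphas=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    n_reps: int = 10,
    n_sites: int = 20_000,
    group_size: int = 20,
    missingness: float = 0.2,
    seed: int = 0,
) -> dict:
    """Two-component mixture-weight recovery on drift-tree fixtures.

    Targets are constructed at the frequency level as
    alpha * p_s1 + (1 - alpha) * p_s2 from the two most backbone-distant
    regional leaves, then sampled as pseudohaploid groups.  Returns the
    mean estimated alpha per true alpha.
    """
    rng = np.random.default_rng(seed)
    tree = sd.standard_tree()
    sites = sd.make_site_table(n_sites)
    blocks = fs.make_blocks(sites)
    rights = list(tree.right_leaves)
    s1_leaf, s2_leaf = tree.regional_leaves[0], tree.regional_leaves[-1]

    def ph_counts(freq, n):
        dip = sd.genotypes_from_freqs(freq, n, rng)
        ph = sd.pseudohaploidize(dip, missingness, rng)
        nonmissing = ph != -1
        return (ph == 2).sum(axis=1), nonmissing.sum(axis=1)

    out = {}
    for alpha in alphas:
        estimates = []
        for _ in range(n_reps):
            ancestral = sd.sample_ancestral_freqs(n_sites, rng)
            freqs = sd.drift_along_tree(tree, ancestral, rng)
            counts = {r: ph_counts(freqs[r], 6) for r in rights}
            counts["s1"] = ph_counts(freqs[s1_leaf], group_size)
            counts["s2"] = ph_counts(freqs[s2_leaf], group_size)
            target = alpha * freqs[s1_leaf] + (1 - alpha) * freqs[s2_leaf]
            counts["t"] = ph_counts(target, group_size)
            fit = fs.two_component_fit("t", "s1", "s2", rights, counts, blocks)
            estimates.append(fit.alpha)
        out[float(alpha)] = float(np.mean(estimates))
    return out
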