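"""f4 statistics, jackknife covariance, clade test and admixture fit."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from driftscape import fstats as fs
from driftscape import synthdata as sd

from conftest import counts_from_calls


def _sites(physpos, chrom=None):
    n = len(physpos)
    return pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "chrom": chrom or ["1"] * n,
            "genpos": [p * 1e-8 for p in physpos],
            "physpos": physpos,
            "ref": "A",
            "alt": "C",
        }
    )


def _full_counts(freq_vectors, n_alleles=2):
    """Turn exact frequency vectors into (derived, called) count pairs."""
    return {
        k: (np.round(np.asarray(v) * n_alleles).astype(int),
            np.full(len(v), n_alleles))
        for k, v in freq_vectors.items()
    }


class TestMakeBlocks:
    def test_positions_split_at_block_boundaries(self):
        blocks = fs.make_blocks(_sites([1, 4_999_999, 5_000_001]), 5_000_000)
        assert blocks.block_ids.tolist() == [0, 0, 1]

    def test_blocks_never_span_chromosomes(self):
        sites = _sites([1, 2, 1, 2], chrom=["1", "1", "2", "2"])
        blocks = fs.make_blocks(sites, 5_000_000)
        assert blocks.block_ids.tolist() == [0, 0, 1, 1]

    def test_block_count_matches_span(self):
        positions = list(range(1, 20_000_001, 1_000_000))
        blocks = fs.make_blocks(_sites(positions), 5_000_000)
        assert blocks.n_blocks == 4

    def test_single_block_is_an_error(self):
        with pytest.raises(fs.FStatError, match="smaller"):
            fs.make_blocks(_sites([1, 2, 3]), 5_000_000)


class TestF4:
    def _blocks(self, n):
        return fs.make_blocks(_sites([1 + 6_000_000 * i for i in range(n)]))

    def test_identical_first_pair_gives_zero(self):
        counts = _full_counts(
            {"A": [0.5, 0.3], "B": [0.5, 0.3], "C": [1, 0], "D": [0, 1]}, 10
        )
        st_ = fs.f4("A", "B", "C", "D", counts, self._blocks(2))
        assert st_.estimate == 0.0

    def test_hand_evaluated_two_site_case(self):
        counts = _full_counts({"A": [1, 0], "B": [0, 0], "C": [1, 1], "D": [0, 1]}, 2)
        st_ = fs.f4("A", "B", "C", "D", counts, self._blocks(2))
        assert st_.estimate == pytest.approx(0.5, abs=1e-12)

    def test_antisymmetry_in_first_pair(self):
        rng = np.random.default_rng(3)
        counts = _full_counts(
            {k: rng.random(40) for k in "ABCD"}, 20
        )
        blocks = self._blocks(40)
        fwd = fs.f4("A", "B", "C", "D", counts, blocks)
        rev = fs.f4("B", "A", "C", "D", counts, blocks)
        assert fwd.estimate == pytest.approx(-rev.estimate, rel=1e-12)
        assert fwd.se == pytest.approx(rev.se, rel=1e-9)

    def test_no_usable_sites_is_an_error(self):
        counts = {
            "A": (np.array([0]), np.array([0])),
            "B": (np.array([1]), np.array([2])),
            "C": (np.array([1]), np.array([2])),
            "D": (np.array([1]), np.array([2])),
        }
        with pytest.raises(fs.FStatError, match="no usable sites"):
            fs.f4("A", "B", "C", "D", counts, self._blocks(2))


class TestF4Vector:
    def test_equal_pair_gives_zero_vector(self, standard_panel):
        p = standard_panel
        vec = fs.f4_vector("R2", "R2", p["rights"], p["counts"], p["blocks"])
        assert np.allclose(vec.values, 0.0)

    def test_two_rights_reduce_to_single_f4(self, standard_panel):
        p = standard_panel
        vec = fs.f4_vector("R2", "R3", ["R1", "R4"], p["counts"], p["blocks"])
        single = fs.f4("R2", "R3", "R1", "R4", p["counts"], p["blocks"])
        assert vec.values.shape == (1,)
        assert vec.values[0] == pytest.approx(single.estimate, rel=1e-9)

    def test_permuting_rights_permutes_values(self, standard_panel):
        p = standard_panel
        a = fs.f4_vector("R2", "R3", ["R1", "R4", "R5", "R6"], p["counts"], p["blocks"])
        b = fs.f4_vector("R2", "R3", ["R1", "R6", "R4", "R5"], p["counts"], p["blocks"])
        perm = [a.rights.index(r) for r in b.rights]
        assert np.allclose(b.values, a.values[perm])


class TestJackknifeCovariance:
    def test_matches_leave_one_block_out_oracle(self):
        """The incremental covariance equals literally re-running the full
        estimate with each block's sites deleted."""
        rng = np.random.default_rng(7)
        n_sites, n_blocks = 300, 12
        sites = _sites([1 + i * 200_000 for i in range(n_sites)])
        blocks = fs.make_blocks(sites, 5_000_000)
        assert blocks.n_blocks == n_blocks
        counts = _full_counts({k: rng.random(n_sites) for k in "ABCDE"}, 50)
        vec = fs.f4_vector("A", "B", ["C", "D", "E"], counts, blocks)
        cov = fs.jackknife_cov(vec)

        # oracle: recompute the whole vector without each block
        loo = []
        weights = []
        for b in range(n_blocks):
            keep = blocks.block_ids != b
            sub_counts = {
                k: (d[keep], c[keep]) for k, (d, c) in counts.items()
            }
            sub_sites = sites.loc[keep].reset_index(drop=True)
            sub_blocks = fs.make_blocks(sub_sites, 5_000_000)
            v = fs.f4_vector("A", "B", ["C", "D", "E"], sub_counts, sub_blocks)
            loo.append(v.values)
            weights.append((blocks.block_ids == b).sum())
        loo = np.array(loo)
        weights = np.array(weights, dtype=float)
        n = weights.sum()
        theta = vec.values
        h = n / weights
        tau = h[:, None] * theta - (h - 1)[:, None] * loo
        theta_tilde = n_blocks * theta - ((1 - weights / n)[:, None] * loo).sum(0)
        dev = tau - theta_tilde
        oracle = (dev.T * (1 / (h - 1))) @ dev / n_blocks
        np.testing.assert_allclose(cov, oracle, rtol=1e-10)

    def test_diagonal_matches_single_f4_se(self, standard_panel):
        p = standard_panel
        vec = fs.f4_vector("R2", "R3", p["rights"], p["counts"], p["blocks"])
        cov = fs.jackknife_cov(vec)
        for j, r in enumerate(vec.rights):
            single = fs.f4("R2", "R3", vec.base, r, p["counts"], p["blocks"])
            # shared complete-case mask makes the diagonal comparable only
            # when single-f4 masks coincide; with a low-missingness panel
            # they nearly do
            assert np.sqrt(cov[j, j]) == pytest.approx(single.se, rel=0.05)

    def test_identical_blocks_give_zero_covariance(self):
        pattern = np.tile(np.array([0.2, 0.8, 0.4, 0.6, 0.5]), 8)
        n = len(pattern)
        sites = _sites([1 + i * 1_000_000 for i in range(n)])
        blocks = fs.make_blocks(sites, 5_000_000)
        counts = _full_counts(
            {"A": pattern, "B": pattern[::-1], "C": np.roll(pattern, 1),
             "D": np.roll(pattern, 2)},
            1000,
        )
        vec = fs.f4_vector("A", "B", ["C", "D"], counts, blocks)
        cov = fs.jackknife_cov(vec)
        assert np.abs(cov).max() < 1e-12


class TestCladeTest:
    def test_dissimilarity_of_p_05(self):
        assert fs.dissimilarity(0.05) == pytest.approx(1.3010, abs=1e-4)
        assert fs.dissimilarity(1.0) == 0.0

    def test_dissimilarity_monotone_and_floored(self):
        ps = np.logspace(-8, 0, 30)
        ds = [fs.dissimilarity(p) for p in ps]
        assert all(a >= b for a, b in zip(ds, ds[1:]))
        assert np.isfinite(fs.dissimilarity(0.0))

    def test_null_p_values_approximately_uniform(self, standard_panel):
        """Pairs drawn from one panmictic leaf: p ~ Uniform(0,1)."""
        p = standard_panel
        rng = np.random.default_rng(99)
        counts = dict(p["counts"])
        pvals = []
        for _ in range(200):
            dip = sd.genotypes_from_freqs(p["freqs"]["L2"], 2, rng)
            ph = sd.pseudohaploidize(dip, 0.3, rng)
            counts["x"] = counts_from_calls(ph[:, :1])
            counts["y"] = counts_from_calls(ph[:, 1:])
            res = fs.one_component_test("x", "y", p["rights"], counts, p["blocks"])
            pvals.append(res.p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_strong_drift_rejected(self, standard_panel):
        """Individuals from backbone-separated leaves are detected."""
        p = standard_panel
        rng = np.random.default_rng(5)
        counts = dict(p["counts"])
        n_reject = 0
        for _ in range(20):
            for lbl, leaf in (("x", "L1"), ("y", "L5")):
                dip = sd.genotypes_from_freqs(p["freqs"][leaf], 1, rng)
                counts[lbl] = counts_from_calls(sd.pseudohaploidize(dip, 0.3, rng))
            res = fs.one_component_test("x", "y", p["rights"], counts, p["blocks"])
            n_reject += res.p < 1e-6
        assert n_reject >= 19

    def test_statistic_invariant_to_base_change(self, standard_panel):
        """T is the same linear test under any choice of base right."""
        p = standard_panel
        rng = np.random.default_rng(6)
        counts = dict(p["counts"])
        dip = sd.genotypes_from_freqs(p["freqs"]["L1"], 2, rng)
        ph = sd.pseudohaploidize(dip, 0.1, rng)
        counts["x"] = counts_from_calls(ph[:, :1])
        counts["y"] = counts_from_calls(ph[:, 1:])
        r1 = fs.one_component_test("x", "y", p["rights"], counts, p["blocks"])
        reordered = [p["rights"][3]] + [r for r in p["rights"] if r != p["rights"][3]]
        r2 = fs.one_component_test("x", "y", reordered, counts, p["blocks"])
        assert r1.T == pytest.approx(r2.T, rel=1e-6)


class TestTwoComponentFit:
    def test_exact_mixture_recovered(self, standard_panel):
        p = standard_panel
        rng = np.random.default_rng(8)
        counts = dict(p["counts"])
        target_freq = 0.3 * p["freqs"]["L1"] + 0.7 * p["freqs"]["L6"]
        for lbl, f in (("s1", p["freqs"]["L1"]), ("s2", p["freqs"]["L6"]),
                       ("t", target_freq)):
            dip = sd.genotypes_from_freqs(f, 20, rng)
            counts[lbl] = counts_from_calls(sd.pseudohaploidize(dip, 0.2, rng))
        fit = fs.two_component_fit("t", "s1", "s2", p["rights"], counts, p["blocks"])
        assert fit.alpha == pytest.approx(0.30, abs=0.02)
        assert fit.p > 0.05

    def test_degenerate_mixture_alpha_one(self, standard_panel):
        p = standard_panel
        rng = np.random.default_rng(9)
        counts = dict(p["counts"])
        for lbl, f in (("s1", p["freqs"]["L1"]), ("s2", p["freqs"]["L6"])):
            dip = sd.genotypes_from_freqs(f, 20, rng)
            counts[lbl] = counts_from_calls(sd.pseudohaploidize(dip, 0.2, rng))
        dip = sd.genotypes_from_freqs(p["freqs"]["L1"], 20, rng)
        counts["t"] = counts_from_calls(sd.pseudohaploidize(dip, 0.2, rng))
        fit = fs.two_component_fit("t", "s1", "s2", p["rights"], counts, p["blocks"])
        assert fit.alpha == pytest.approx(1.0, abs=0.05)

    def test_identical_sources_rejected(self, standard_panel):
        p = standard_panel
        rng = np.random.default_rng(10)
        counts = dict(p["counts"])
        exact = _full_counts({"s1": p["freqs"]["L1"], "s2": p["freqs"]["L1"],
                              "t": p["freqs"]["L2"]}, 10_000)
        counts.update(exact)
        with pytest.raises(fs.FStatError, match="indistinguishable"):
            fs.two_component_fit("t", "s1", "s2", p["rights"], counts, p["blocks"])
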