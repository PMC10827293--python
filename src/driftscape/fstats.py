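"""f4-statistics, weighted block jackknife, and qpWave-style model tests.

The central quantity is the f4-statistic

    f4(A, B; C, D) = mean over sites of (pA - pB)(pC - pD),

the average product of allele-frequency differences.  Its expectation is
zero when {A, B} form a clade relative to {C, D}: drift on the branch
separating A from B is then uncorrelated with drift separating C from D.

The one-component (clade) test evaluates a vector of f4-statistics

    v_j = f4(A, B; R_base, R_j)

over a panel of reference ("right") populations chosen to be differentially
related to the test pair.  Under the clade null v = 0, and the Hotelling-style
statistic T = v' Sigma^-1 v is approximately chi-square with k-1 degrees of
freedom, where Sigma is a weighted block-jackknife estimate of Cov(v) and k
the number of rights.  The dissimilarity d = -log10(p) feeds the clustering
step of the ancestry-outlier workflow.

The two-component fit models a target as a mixture alpha * S1 + (1-alpha) * S2
via generalised least squares on the same f4 vectors.

All frequency inputs arrive as per-group (derived_count, called_alleles)
arrays from :func:`driftscape.genodata.group_allele_counts`; a site enters a
statistic only if every participating group has at least one called allele
there (complete-case analysis, shared across vector components so that the
block bookkeeping is common to all of them).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Floor applied to p-values before taking -log10, keeping d finite.
P_FLOOR = 1e-320

#: Relative tolerance for the covariance pseudoinverse.
PINV_RTOL = 1e-8

DEFAULT_BLOCK_SIZE_BP = 5_000_000
MIN_SITES_WARN = 5_000
MIN_SITES_ERROR = 500


class FStatError(ValueError):
    """Raised on unusable inputs to an f-statistic computation."""


@dataclasses.dataclass(frozen=True)
class BlockSpec:
    """Assignment of every site to a contiguous jackknife block.

    Blocks are defined by physical position within chromosome
    (``floor((physpos - 1) / block_size_bp)``) and renumbered consecutively
    in site order, never crossing a chromosome boundary.
    """

    block_size_bp: int
    block_ids: np.ndarray  # int per site
    n_blocks: int


def make_blocks(sites: pd.DataFrame, block_size_bp: int = DEFAULT_BLOCK_SIZE_BP) -> BlockSpec:
    """Build jackknife blocks from a site table with ``chrom`` and ``physpos``.

    Requires at least two nonempty blocks; with a single block the jackknife
    variance is undefined, so a smaller ``block_size_bp`` is suggested.
    """
    chrom = sites["chrom"].to_numpy()
    physpos = sites["physpos"].to_numpy(dtype=np.int64)
    if np.any(physpos < 1):
        raise FStatError("physical positions must be 1-based (>= 1)")
    local = (physpos - 1) // int(block_size_bp)
    # renumber (chrom, local) pairs consecutively in order of appearance
    keys = pd.Series(list(zip(chrom, local)))
    codes = keys.astype("category").cat.codes.to_numpy()
    # preserve site order: map first-appearance order
    _, first_idx = np.unique(codes, return_index=True)
    order = {codes[i]: rank for rank, i in enumerate(np.sort(first_idx))}
    block_ids = np.array([order[c] for c in codes], dtype=np.int64)
    n_blocks = int(block_ids.max()) + 1 if len(block_ids) else 0
    if n_blocks < 2:
        raise FStatError(
            f"only {n_blocks} nonempty jackknife block(s); use a smaller "
            f"block_size_bp than {block_size_bp}"
        )
    return BlockSpec(int(block_size_bp), block_ids, n_blocks)


# ---------------------------------------------------------------------------
# Frequencies and masks
# ---------------------------------------------------------------------------

def _freq(counts: Mapping[str, tuple[np.ndarray, np.ndarray]], label: str) -> np.ndarray:
    try:
        derived, called = counts[label]
    except KeyError:
        raise FStatError(f"no allele counts for group {label!r}") from None
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, derived / np.maximum(called, 1), np.nan)


def _usable_mask(freqs: Sequence[np.ndarray]) -> np.ndarray:
    mask = np.isfinite(freqs[0])
    for f in freqs[1:]:
        mask &= np.isfinite(f)
    return mask


# ---------------------------------------------------------------------------
# Weighted block jackknife (delete-m, Busing-style)
# ---------------------------------------------------------------------------

def weighted_jackknife_cov(
    block_sums: np.ndarray, block_counts: np.ndarray
) -> np.ndarray:
    """Covariance of a ratio-of-sums vector estimate via weighted jackknife.

    ``block_sums`` is (B, m): per-block sums of the per-site terms for each
    of the m vector components; ``block_counts`` (B,) the per-block numbers
    of contributing sites.  Empty blocks are ignored.  The delete-one-block
    estimates are reweighted by block size (delete-m jackknife), which for
    equal blocks reduces to the classic (B-1)/B * scatter formula.
    """
    block_sums = np.atleast_2d(np.asarray(block_sums, dtype=float))
    block_counts = np.asarray(block_counts, dtype=float)
    nonempty = block_counts > 0
    bs = block_sums[nonempty]
    bc = block_counts[nonempty]
    B = len(bc)
    if B < 2:
        raise FStatError("jackknife requires at least 2 nonempty blocks")
    n = bc.sum()
    total = bs.sum(axis=0)
    theta = total / n  # (m,)
    loo = (total[None, :] - bs) / (n - bc)[:, None]  # (B, m)
    h = n / bc  # (B,)
    tau = h[:, None] * theta[None, :] - (h - 1.0)[:, None] * loo
    theta_tilde = B * theta - ((1.0 - bc / n)[:, None] * loo).sum(axis=0)
    dev = tau - theta_tilde[None, :]
    cov = (dev.T * (1.0 / (h - 1.0))) @ dev / B
    cov = 0.5 * (cov + cov.T)
    if not np.all(np.isfinite(cov)):
        raise FStatError("non-finite jackknife covariance")
    return cov


# ---------------------------------------------------------------------------
# f4 statistics
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class F4Stat:
    """Single f4 estimate with jackknife standard error."""

    labels: tuple[str, str, str, str]
    estimate: float
    se: float
    n_snps_used: int
    block_sums: np.ndarray
    block_counts: np.ndarray


@dataclasses.dataclass(frozen=True)
class F4Vector:
    """Vector of f4(a, b; base, r_j) over the non-base rights.

    ``block_sums`` (B, k-1) and ``block_counts`` (B,) carry the shared
    per-block bookkeeping needed for the jackknife covariance.
    """

    a: str
    b: str
    base: str
    rights: tuple[str, ...]  # non-base rights, order matches values
    values: np.ndarray  # (k-1,)
    block_sums: np.ndarray
    block_counts: np.ndarray
    n_snps_used: int


@dataclasses.dataclass(frozen=True)
class CladeTestResult:
    """Outcome of the one-component (clade) test for a pair of groups."""

    a: str
    b: str
    T: float
    df: int
    p: float
    d: float
    n_snps_used: int

    def to_record(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class AdmixtureFit:
    """Two-component admixture fit target ~ alpha * s1 + (1 - alpha) * s2."""

    target: str
    s1: str
    s2: str
    alpha: float
    se_alpha: float
    T_resid: float
    df: int
    p: float
    n_snps_used: int


def _block_accumulate(
    prods: np.ndarray, block_ids_used: np.ndarray, n_blocks: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block sums (B, m) and site counts (B,) of per-site terms."""
    if prods.ndim == 1:
        prods = prods[:, None]
    m = prods.shape[1]
    sums = np.zeros((n_blocks, m))
    np.add.at(sums, block_ids_used, prods)
    counts = np.bincount(block_ids_used, minlength=n_blocks).astype(np.int64)
    return sums, counts


def f4(
    a: str,
    b: str,
    c: str,
    d: str,
    counts: Mapping[str, tuple[np.ndarray, np.ndarray]],
    blocks: BlockSpec,
) -> F4Stat:
    """f4(a, b; c, d) with weighted block-jackknife standard error.

    Sites missing in any of the four groups are skipped.
    """
    fa, fb, fc, fd = (_freq(counts, g) for g in (a, b, c, d))
    mask = _usable_mask([fa, fb, fc, fd])
    n_used = int(mask.sum())
    if n_used == 0:
        raise FStatError(f"no usable sites for f4({a},{b};{c},{d})")
    prods = (fa[mask] - fb[mask]) * (fc[mask] - fd[mask])
    bs, bc = _block_accumulate(prods, blocks.block_ids[mask], blocks.n_blocks)
    estimate = float(bs.sum() / n_used)
    cov = weighted_jackknife_cov(bs, bc)
    return F4Stat((a, b, c, d), estimate, float(np.sqrt(cov[0, 0])), n_used, bs, bc)


def f4_vector(
    a: str,
    b: str,
    rights: Sequence[str],
    counts: Mapping[str, tuple[np.ndarray, np.ndarray]],
    blocks: BlockSpec,
) -> F4Vector:
    """All f4(a, b; base, r_j) with the first right as the base.

    A single complete-case site mask is shared across components so that the
    per-block bookkeeping (and hence the covariance) is coherent.
    """
    if len(rights) < 2:
        raise FStatError("need at least 2 right groups (base + 1)")
    base, others = rights[0], list(rights[1:])
    fa = _freq(counts, a)
    fb = _freq(counts, b)
    fbase = _freq(counts, base)
    fr = np.column_stack([_freq(counts, r) for r in others])  # (S, k-1)
    mask = _usable_mask([fa, fb, fbase]) & np.all(np.isfinite(fr), axis=1)
    n_used = int(mask.sum())
    if n_used == 0:
        empty = [r for r in rights if not np.isfinite(_freq(counts, r)).any()]
        detail = f"; right group(s) with no usable sites: {empty}" if empty else ""
        raise FStatError(f"no usable sites for f4 vector ({a},{b}){detail}")
    prods = (fa[mask] - fb[mask])[:, None] * (fbase[mask][:, None] - fr[mask])
    bs, bc = _block_accumulate(prods, blocks.block_ids[mask], blocks.n_blocks)
    values = bs.sum(axis=0) / n_used
    return F4Vector(a, b, base, tuple(others), values, bs, bc, n_used)


def jackknife_cov(vec: F4Vector) -> np.ndarray:
    """Weighted block-jackknife covariance of an f4 vector (symmetric PSD)."""
    return weighted_jackknife_cov(vec.block_sums, vec.block_counts)


def _check_site_count(n_used: int, context: str) -> None:
    if n_used < MIN_SITES_ERROR:
        raise FStatError(
            f"{context}: only {n_used} usable sites (< {MIN_SITES_ERROR})"
        )
    if n_used < MIN_SITES_WARN:
        warnings.warn(
            f"{context}: only {n_used} usable sites (< {MIN_SITES_WARN}); "
            "covariance may be unstable",
            stacklevel=3,
        )


def dissimilarity(p: float) -> float:
    """d = -log10(p), floored so that it stays finite."""
    return float(-np.log10(max(p, P_FLOOR)))


def one_component_test(
    a: str,
    b: str,
    rights: Sequence[str],
    counts: Mapping[str, tuple[np.ndarray, np.ndarray]],
    blocks: BlockSpec,
) -> CladeTestResult:
    """Test the null that groups ``a`` and ``b`` form a clade w.r.t. ``rights``.

    T = v' Sigma^+ v with v the f4 vector and Sigma its jackknife covariance;
    p is the upper chi-square tail at df = rank(Sigma).  A numerically
    singular covariance falls back to the pseudoinverse, reducing the
    effective degrees of freedom.
    """
    vec = f4_vector(a, b, rights, counts, blocks)
    _check_site_count(vec.n_snps_used, f"clade test ({a}, {b})")
    cov = jackknife_cov(vec)
    cov_inv = np.linalg.pinv(cov, rcond=PINV_RTOL, hermitian=True)
    rank = int(np.linalg.matrix_rank(cov, tol=PINV_RTOL * float(np.abs(cov).max() or 1.0),
                                     hermitian=True))
    rank = max(rank, 1)
    T = float(vec.values @ cov_inv @ vec.values)
    T = max(T, 0.0)
    p = float(stats.chi2.sf(T, df=rank))
    p = max(p, P_FLOOR)
    return CladeTestResult(a, b, T, rank, p, dissimilarity(p), vec.n_snps_used)


def two_component_fit(
    target: str,
    s1: str,
    s2: str,
    rights: Sequence[str],
    counts: Mapping[str, tuple[np.ndarray, np.ndarray]],
    blocks: BlockSpec,
) -> AdmixtureFit:
    """GLS fit of target as a two-way mixture of s1 and s2.

    With y_j = f4(target, s2; base, r_j) and X_j = f4(s1, s2; base, r_j),
    a perfect mixture target = alpha*s1 + (1-alpha)*s2 implies y = alpha X.
    alpha is estimated by generalised least squares under the jackknife
    covariance of y; the residual statistic is chi-square with k-2 df when
    the two-component model holds.
    """
    if len(rights) < 3:
        raise FStatError("two-component fit needs k >= 3 right groups")
    y_vec = f4_vector(target, s2, rights, counts, blocks)
    x_vec = f4_vector(s1, s2, rights, counts, blocks)
    _check_site_count(min(y_vec.n_snps_used, x_vec.n_snps_used),
                      f"two-component fit ({target} ~ {s1} + {s2})")
    y = y_vec.values
    X = x_vec.values
    cov = jackknife_cov(y_vec)
    cov_inv = np.linalg.pinv(cov, rcond=PINV_RTOL, hermitian=True)
    xtx = float(X @ cov_inv @ X)
    if not np.isfinite(xtx) or xtx < 1e-10:
        raise FStatError(
            f"sources indistinguishable: f4 contrast between {s1!r} and {s2!r} "
            "is numerically zero against the rights"
        )
    alpha = float(X @ cov_inv @ y) / xtx
    se_alpha = float(1.0 / np.sqrt(xtx))
    resid = y - alpha * X
    T_resid = max(float(resid @ cov_inv @ resid), 0.0)
    df = len(rights) - 2
    p = max(float(stats.chi2.sf(T_resid, df=df)), P_FLOOR)
    return AdmixtureFit(target, s1, s2, alpha, se_alpha, T_resid, df, p,
                        min(y_vec.n_snps_used, x_vec.n_snps_used))
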