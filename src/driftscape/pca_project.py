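"""Reference-space PCA and least-squares projection of incomplete genomes.

The reference space is computed from high-quality (typically present-day)
genotypes: each site is centred by its reference mean genotype mu and scaled
by sqrt((mu/2)(1 - mu/2)) (unit drift variance), then principal components
are extracted, with iterative removal of reference individuals lying more
than ``outlier_sigma`` standard deviations out along any of the leading PCs.

Low-coverage (pseudohaploid, missing-rich) genomes are then placed into
that space by least squares: the projection coordinates minimise the squared
error between the sample's normalised non-missing entries and their
loadings-restricted reconstruction.  With no missingness this reduces
exactly to the direct score projection.

``pca_simulated`` is the plain-PCA variant used for simulated cohorts:
no projection step, same 6-SD / 5-iteration outlier screen.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _procrustes
from sklearn.decomposition import PCA as _SkPCA

from .genodata import MISSING, GenotypeMatrix

MODEL_FORMAT_VERSION = 1


class PcaError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class PcaConfig:
    n_pcs: int = 10
    n_outlier_iter: int = 5
    outlier_sigma: float = 6.0
    min_projected_sites: int = 1_000

    def __post_init__(self) -> None:
        if min(self.n_pcs, self.n_outlier_iter, self.min_projected_sites) <= 0 \
                or self.outlier_sigma <= 0:
            raise PcaError("all PcaConfig fields must be positive")


@dataclasses.dataclass
class PcaModel:
    """Fitted reference PCA space.

    ``loadings`` is sites x n_pcs with orthonormal columns; ``means`` and
    ``norms`` are the per-site centring/scaling constants; ``site_ids``
    identifies the retained (polymorphic) sites in order.
    """

    site_ids: np.ndarray
    means: np.ndarray
    norms: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    retained_ids: list[str]
    removed_per_iteration: list[list[str]]
    scores: np.ndarray  # retained references x n_pcs

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            format_version=MODEL_FORMAT_VERSION,
            site_ids=np.asarray(self.site_ids, dtype=str),
            means=self.means,
            norms=self.norms,
            loadings=self.loadings,
            eigenvalues=self.eigenvalues,
            retained_ids=np.asarray(self.retained_ids, dtype=str),
            removed_flat=np.asarray(
                [x for it in self.removed_per_iteration for x in it], dtype=str
            ),
            removed_counts=np.asarray(
                [len(it) for it in self.removed_per_iteration], dtype=int
            ),
            scores=self.scores,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PcaModel":
        with np.load(path, allow_pickle=False) as z:
            if int(z["format_version"]) != MODEL_FORMAT_VERSION:
                raise PcaError(
                    f"unsupported model format version {int(z['format_version'])}"
                )
            removed, i = [], 0
            flat = z["removed_flat"].tolist()
            for c in z["removed_counts"].tolist():
                removed.append([str(x) for x in flat[i:i + c]])
                i += c
            return cls(
                site_ids=z["site_ids"],
                means=z["means"],
                norms=z["norms"],
                loadings=z["loadings"],
                eigenvalues=z["eigenvalues"],
                retained_ids=[str(x) for x in z["retained_ids"].tolist()],
                removed_per_iteration=removed,
                scores=z["scores"],
            )


def _normalised_reference(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mean-impute, drop monomorphic sites, centre and scale.

    Returns (Z, keep_mask, means, norms) with Z individuals x sites.
    """
    calls = calls.astype(float)
    calls[calls == MISSING] = np.nan
    mu = np.nanmean(calls, axis=1)
    callable_ = np.isfinite(mu)
    poly = callable_ & (mu > 0) & (mu < 2)
    mu_p = mu[poly]
    norms = np.sqrt((mu_p / 2.0) * (1.0 - mu_p / 2.0))
    sub = calls[poly]
    sub = np.where(np.isnan(sub), mu_p[:, None], sub)
    Z = ((sub - mu_p[:, None]) / norms[:, None]).T
    return Z, poly, mu_p, norms


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make each loading column's largest-magnitude entry positive."""
    idx = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[idx, np.arange(loadings.shape[1])])
    signs[signs == 0] = 1.0
    return loadings * signs, scores * signs


def _svd_fit(Z: np.ndarray, n_pcs: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(loadings, scores, eigenvalues) from the normalised matrix."""
    Zc = Z - Z.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    loadings = Vt[:n_pcs].T
    scores = Zc @ loadings
    eigenvalues = (s[:n_pcs] ** 2) / max(Z.shape[0] - 1, 1)
    return loadings, scores, eigenvalues


def fit_reference_pca(matrix: GenotypeMatrix, config: PcaConfig = PcaConfig()) -> PcaModel:
    """Fit the reference PCA space with iterative outlier removal.

    Each round removes every reference whose score exceeds
    ``outlier_sigma`` standard deviations (per-PC SD over currently retained
    references) on any of the first ``n_pcs`` PCs, then refits from scratch
    on the survivors.  Missing reference entries are mean-imputed.
    """
    retained = list(matrix.samples)
    removed_log: list[list[str]] = []
    for _ in range(config.n_outlier_iter + 1):
        if len(retained) < config.n_pcs:
            raise PcaError(
                f"only {len(retained)} references retained; need >= "
                f"{config.n_pcs} for {config.n_pcs} PCs"
            )
        sub = matrix.take_samples(retained)
        Z, keep, mu, norms = _normalised_reference(sub.calls.copy())
        n_pcs = min(config.n_pcs, Z.shape[0] - 1, Z.shape[1])
        loadings, scores, eig = _svd_fit(Z, n_pcs)
        if len(removed_log) >= config.n_outlier_iter:
            break
        sd = scores.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        is_out = (np.abs(scores) > config.outlier_sigma * sd).any(axis=1)
        if not is_out.any():
            break
        removed_log.append([retained[i] for i in np.nonzero(is_out)[0]])
        retained = [s for s, o in zip(retained, is_out) if not o]
    loadings, scores = _fix_signs(loadings, scores)
    return PcaModel(
        site_ids=sub.sites["id"].to_numpy()[keep],
        means=mu,
        norms=norms,
        loadings=loadings,
        eigenvalues=eig,
        retained_ids=retained,
        removed_per_iteration=removed_log,
        scores=scores,
    )


def lsq_project(
    calls: np.ndarray, site_ids: Sequence[str], model: PcaModel,
    min_sites: int = 1_000, sample_id: str = "?",
) -> tuple[np.ndarray, int]:
    """Least-squares projection of one (possibly missing-rich) genome.

    ``calls`` are genotype values aligned to ``site_ids``; only sites shared
    with the model and non-missing are used.  Returns (coordinates,
    n_sites_used).
    """
    id_to_row = {sid: i for i, sid in enumerate(model.site_ids)}
    rows, vals = [], []
    for sid, call in zip(site_ids, np.asarray(calls)):
        r = id_to_row.get(sid)
        if r is not None and call != MISSING:
            rows.append(r)
            vals.append(call)
    if len(rows) < min_sites:
        raise PcaError(
            f"sample {sample_id!r}: only {len(rows)} usable sites "
            f"(< {min_sites}) for projection"
        )
    rows = np.asarray(rows, dtype=np.intp)
    z = (np.asarray(vals, dtype=float) - model.means[rows]) / model.norms[rows]
    L = model.loadings[rows]
    coords, *_ = np.linalg.lstsq(L, z, rcond=None)
    return coords, len(rows)


def project_samples(
    matrix: GenotypeMatrix, model: PcaModel, config: PcaConfig = PcaConfig()
) -> pd.DataFrame:
    """Project every sample of a matrix; one row per sample with PC columns."""
    rows = []
    for i, sid in enumerate(matrix.samples):
        coords, n_used = lsq_project(
            matrix.calls[:, i], matrix.sites["id"].tolist(), model,
            min_sites=config.min_projected_sites, sample_id=sid,
        )
        rows.append({"id": sid, "n_sites_used": n_used,
                     **{f"PC{j + 1}": c for j, c in enumerate(coords)}})
    return pd.DataFrame(rows)


def pca_simulated(
    genotypes: np.ndarray,
    sample_ids: Sequence[str] | None = None,
    config: PcaConfig = PcaConfig(),
    min_maf: float = 0.01,
) -> tuple[pd.DataFrame, list[list[str]]]:
    """Plain PCA of simulated diploid genotypes with 6-SD outlier screening.

    ``genotypes`` is sites x individuals in {0,1,2} (no missingness in
    simulated data).  Sites below ``min_maf`` are dropped first.  Returns
    the coordinates of all retained individuals plus the per-iteration
    removal log.
    """
    G = np.asarray(genotypes, dtype=float)
    n_ind = G.shape[1]
    ids = list(sample_ids) if sample_ids is not None else [f"ind{i}" for i in range(n_ind)]
    freq = G.mean(axis=1) / 2.0
    maf = np.minimum(freq, 1 - freq)
    G = G[maf >= min_maf]
    if G.shape[0] < config.n_pcs:
        raise PcaError("too few polymorphic sites for PCA")

    retained = list(range(n_ind))
    removed_log: list[list[str]] = []
    for _ in range(config.n_outlier_iter + 1):
        if len(retained) < config.n_pcs + 1:
            raise PcaError("outlier removal left too few individuals")
        X = G[:, retained].T
        n_pcs = min(config.n_pcs, len(retained) - 1)
        pca = _SkPCA(n_components=n_pcs, svd_solver="arpack", random_state=0)
        scores = pca.fit_transform(X)
        if len(removed_log) >= config.n_outlier_iter:
            break
        sd = scores.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        is_out = (np.abs(scores) > config.outlier_sigma * sd).any(axis=1)
        if not is_out.any():
            break
        removed_log.append([ids[retained[i]] for i in np.nonzero(is_out)[0]])
        retained = [r for r, o in zip(retained, is_out) if not o]
    out = pd.DataFrame(
        {"id": [ids[r] for r in retained],
         **{f"PC{j + 1}": scores[:, j] for j in range(scores.shape[1])}}
    )
    return out, removed_log


def procrustes_correlation(coords: np.ndarray, reference: np.ndarray) -> float:
    """Procrustes similarity between two point configurations.

    Computed as sqrt(1 - M2) where M2 is the standardised Procrustes
    disparity after optimal translation, scaling and rotation; 1 means the
    configurations match exactly, 0 means no correspondence.
    """
    _, _, disparity = _procrustes(np.asarray(reference, float), np.asarray(coords, float))
    return float(np.sqrt(max(0.0, 1.0 - disparity)))
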