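"""Ancestry-outlier detection and source attribution across regions.

The workflow, region by region:

1. **Pairwise dissimilarity** -- one-component clade tests between all
   pairs of individuals sampled in the region (Copper Age up to, but
   excluding, the present day), converted to d = -log10(p).
2. **Clustering** -- UPGMA (average linkage) on the dissimilarity matrix,
   cut into flat clusters at d = 1.3 (a nominal p = 0.05).
3. **Classification** -- clusters holding fewer than 5% of the region's
   individuals, or at most two individuals, are outlier *candidates*;
   the rest are majority clusters.  Clusters are then split by time period
   into region_period clusters, the unit of all downstream steps.
4. **Within-region absorption** -- a candidate that still forms a clade
   (p > 0.01) with any majority cluster of its own region is not an
   outlier; it is absorbed.
5. **Cross-region sources** -- surviving candidates are clade-tested
   against majority clusters of all other regions; those that pass are
   potential sources.  An outlier with no valid source is reported as
   "outlier without source".
6. **Model competition** -- each potential source is re-tested with every
   rival source added to the reference set; a source whose model is then
   rejected is pruned (the scheme eliminates sub-optimal sources, it does
   not pick a single best one).
7. **Period prioritisation** -- among surviving sources, same-period
   sources are preferred, then the nearest earlier period; remaining ties
   are all kept.
8. **Network summary** -- per-region outlier proportions, directed
   source-region -> outlier-region edges, and a chi-square check that
   outlier status is not associated with genetic sex.

Cluster-level tests pool member allele counts into one pseudo-population,
which gains power relative to individual-level tests.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency

from .genodata import PERIOD_NAMES, GenotypeMatrix, group_allele_counts, period_rank
from .fstats import BlockSpec, FStatError, CladeTestResult, make_blocks, one_component_test

#: Clustering considers these periods (Copper Age inclusive up to
#: present-day exclusive).
CLUSTERING_PERIODS: tuple[str, ...] = PERIOD_NAMES[1:6]

#: Periods counted in outlier-proportion denominators (Bronze Age up to
#: present-day).
TIME_WINDOW: tuple[str, ...] = PERIOD_NAMES[2:6]


class WorkflowError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class WorkflowConfig:
    cluster_cutoff_d: float = 1.3
    clade_p_threshold: float = 0.01
    minority_fraction: float = 0.05
    minority_max_n: int = 2
    clustering_periods: tuple[str, ...] = CLUSTERING_PERIODS
    time_window: tuple[str, ...] = TIME_WINDOW

    def __post_init__(self) -> None:
        if self.cluster_cutoff_d <= 0:
            raise WorkflowError("cluster_cutoff_d must be positive")
        if not 0.0 < self.minority_fraction < 1.0:
            raise WorkflowError("minority_fraction must be in (0, 1)")


@dataclasses.dataclass
class RegionPeriodCluster:
    """A within-region cluster restricted to one time period."""

    region: str
    period: str
    cluster_id: int  # parent (region-level) cluster
    members: list[str]
    classification: str = "unclassified"  # majority | outlier_candidate | ...
    sources: list["RegionPeriodCluster"] = dataclasses.field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def label(self) -> str:
        return f"{self.region}|c{self.cluster_id}|{self.period}"


@dataclasses.dataclass
class MigrationNetwork:
    """Regions as nodes, source -> outlier relations as directed edges."""

    nodes: list[str]
    edges: pd.DataFrame  # source_region, outlier_region, count, clusters
    proportions: pd.DataFrame  # region, total, outliers, outliers_with_source, ...
    sex_bias: dict


# ---------------------------------------------------------------------------
# Step 1-2: pairwise tests and clustering
# ---------------------------------------------------------------------------

def pairwise_dissimilarity(
    ids: Sequence[str],
    rights: Sequence[str],
    counts: Mapping[str, tuple[np.ndarray, np.ndarray]],
    blocks: BlockSpec,
) -> tuple[np.ndarray, list[CladeTestResult]]:
    """Symmetric matrix of d = -log10(p) from all pairwise clade tests.

    Pairs that fall below the usable-site minimum get NaN and are later
    imputed for clustering.  The diagonal is zero; each unordered pair is
    tested once.  Also returns the full test log.
    """
    n = len(ids)
    if n < 2:
        raise WorkflowError("pairwise dissimilarity needs >= 2 individuals")
    dmat = np.zeros((n, n))
    log: list[CladeTestResult] = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                res = one_component_test(ids[i], ids[j], rights, counts, blocks)
                dmat[i, j] = dmat[j, i] = res.d
                log.append(res)
            except FStatError as err:
                warnings.warn(
                    f"pair ({ids[i]}, {ids[j]}) excluded from clustering: {err}",
                    stacklevel=2,
                )
                dmat[i, j] = dmat[j, i] = np.nan
    return dmat, log


def upgma_flat_clusters(dmat: np.ndarray, cutoff: float = 1.3) -> np.ndarray:
    """Flat clusters from UPGMA at the given dissimilarity cutoff.

    NaN entries (pairs that could not be tested) are imputed as the maximum
    observed dissimilarity plus one, keeping such pairs apart unless linked
    through other members.  Returns integer labels starting at 1.
    """
    dmat = np.asarray(dmat, dtype=float)
    n = dmat.shape[0]
    if n == 1:
        return np.array([1])
    if np.isnan(dmat).any():
        finite = dmat[np.isfinite(dmat)]
        fill = (finite.max() if finite.size else 0.0) + 1.0
        dmat = np.where(np.isnan(dmat), fill, dmat)
        warnings.warn("untestable pairs imputed as max observed d + 1", stacklevel=2)
    condensed = squareform(dmat, checks=False)
    Z = linkage(condensed, method="average")
    return fcluster(Z, t=cutoff, criterion="distance")


# ---------------------------------------------------------------------------
# Step 3: classification and period split
# ---------------------------------------------------------------------------

def classify_clusters(
    labels: np.ndarray,
    periods: Sequence[str],
    config: WorkflowConfig,
) -> dict[int, str]:
    """Majority vs outlier-candidate per region-level cluster.

    A cluster is a candidate when its size (across time) is strictly below
    ``minority_fraction`` of the region total, or at most
    ``minority_max_n`` members.  The region total counts clustered
    individuals whose period falls in the configured time window.
    """
    labels = np.asarray(labels)
    in_window = np.array([p in config.time_window for p in periods])
    total = int(in_window.sum())
    out = {}
    for lab in np.unique(labels):
        size = int((labels == lab).sum())
        candidate = size <= config.minority_max_n or (
            total > 0 and size < config.minority_fraction * total
        )
        out[int(lab)] = "outlier_candidate" if candidate else "majority"
    return out


def split_by_period(
    ids: Sequence[str],
    labels: np.ndarray,
    periods: Sequence[str],
    region: str,
    classifications: Mapping[int, str],
) -> list[RegionPeriodCluster]:
    """Split each region-level cluster into (region, period) clusters,
    keeping the parent linkage and classification."""
    by_key: dict[tuple[int, str], list[str]] = {}
    for sid, lab, period in zip(ids, labels, periods):
        by_key.setdefault((int(lab), period), []).append(sid)
    clusters = [
        RegionPeriodCluster(region, period, lab, members,
                            classification=classifications[lab])
        for (lab, period), members in sorted(by_key.items())
    ]
    assert sum(c.size for c in clusters) == len(ids)
    return clusters


# ---------------------------------------------------------------------------
# Steps 4-7: absorption, sources, competition, prioritisation
# ---------------------------------------------------------------------------

def _cluster_test(
    cand: RegionPeriodCluster,
    other: RegionPeriodCluster,
    rights: Sequence[str],
    counts: Mapping[str, tuple[np.ndarray, np.ndarray]],
    blocks: BlockSpec,
) -> CladeTestResult:
    return one_component_test(cand.label, other.label, rights, counts, blocks)


def absorb_candidates_within_region(
    candidates: Sequence[RegionPeriodCluster],
    majorities: Sequence[RegionPeriodCluster],
    rights: Sequence[str],
    counts: Mapping[str, tuple[np.ndarray, np.ndarray]],
    blocks: BlockSpec,
    config: WorkflowConfig,
    log: list | None = None,
) -> list[RegionPeriodCluster]:
    """Drop candidates that form a clade with a majority of their region."""
    survivors = []
    for cand in candidates:
        absorbed = False
        for maj in majorities:
            if maj.region != cand.region:
                continue
            try:
                res = _cluster_test(cand, maj, rights, counts, blocks)
            except FStatError:
                continue
            if log is not None:
                log.append(res)
            if res.p > config.clade_p_threshold:
                absorbed = True
                cand.classification = "absorbed"
                break
        if not absorbed:
            survivors.append(cand)
    return survivors


def find_cross_region_sources(
    candidate: RegionPeriodCluster,
    other_majorities: Sequence[RegionPeriodCluster],
    rights: Sequence[str],
    counts: Mapping[str, tuple[np.ndarray, np.ndarray]],
    blocks: BlockSpec,
    config: WorkflowConfig,
    log: list | None = None,
) -> list[RegionPeriodCluster]:
    """Majority clusters of other regions forming a valid clade with the
    candidate (p above the threshold); empty = outlier without source."""
    sources = []
    for maj in other_majorities:
        if maj.region == candidate.region:
            continue
        try:
            res = _cluster_test(candidate, maj, rights, counts, blocks)
        except FStatError:
            continue
        if log is not None:
            log.append(res)
        if res.p > config.clade_p_threshold:
            sources.append(maj)
    return sources


def compete_sources(
    candidate: RegionPeriodCluster,
    sources: Sequence[RegionPeriodCluster],
    rights: Sequence[str],
    counts: Mapping[str, tuple[np.ndarray, np.ndarray]],
    blocks: BlockSpec,
    config: WorkflowConfig,
) -> list[RegionPeriodCluster]:
    """Prune sub-optimal sources by rotation through the reference set.

    Source x is dropped when adding any rival source y to the rights makes
    the one-component model (candidate, x) rejected: y then shares more
    drift with the candidate than x does.  If every source is eliminated
    the candidate is demoted to outlier-without-source with a warning.
    """
    sources = list(sources)
    if len(sources) < 2:
        return sources
    keep = []
    for x in sources:
        rejected = False
        for y in sources:
            if y is x:
                continue
            aug = list(rights) + [y.label]
            try:
                res = one_component_test(candidate.label, x.label, aug, counts, blocks)
            except FStatError:
                continue
            if res.p < config.clade_p_threshold:
                rejected = True
                break
        if not rejected:
            keep.append(x)
    if not keep:
        warnings.warn(
            f"model competition eliminated all sources of {candidate.label}; "
            "demoted to outlier without source",
            stacklevel=2,
        )
    return keep


def prioritize_sources_by_period(
    sources: Sequence[RegionPeriodCluster], target_period: str
) -> list[RegionPeriodCluster]:
    """Prefer same-period sources, then the nearest earlier period.

    Remaining ties are considered equivalent and all kept.  Sources only
    from later periods are kept unfiltered (no prioritisation applies).
    """
    if not sources:
        return []
    t = period_rank(target_period)
    ranks = np.array([period_rank(s.period) for s in sources])
    if (ranks == t).any():
        return [s for s, r in zip(sources, ranks) if r == t]
    earlier = ranks[ranks < t]
    if earlier.size:
        best = earlier.max()
        return [s for s, r in zip(sources, ranks) if r == best]
    return list(sources)


# ---------------------------------------------------------------------------
# Step 8: summary
# ---------------------------------------------------------------------------

def summarize_network(
    clusters: Sequence[RegionPeriodCluster],
    metadata: pd.DataFrame,
    config: WorkflowConfig,
) -> MigrationNetwork:
    """Outlier proportions, migration edges, and the sex-bias check.

    Proportions count individuals in region_period clusters whose period
    lies in the configured time window.  An edge source_region ->
    outlier_region is drawn once per outlier cluster per attributed source
    region; the chi-square test (df = 2) checks sex against {non-outlier,
    outlier with source, outlier without source}.
    """
    meta = metadata.set_index("id")
    regions = sorted({c.region for c in clusters})
    edge_rows: dict[tuple[str, str], dict] = {}
    prop = {
        r: {"total": 0, "outliers": 0, "outliers_with_source": 0} for r in regions
    }
    status_of: dict[str, str] = {}
    for c in clusters:
        in_window = c.period in config.time_window
        is_outlier = c.classification in ("outlier_with_source", "outlier_without_source")
        if in_window:
            prop[c.region]["total"] += c.size
            if is_outlier:
                prop[c.region]["outliers"] += c.size
                if c.classification == "outlier_with_source":
                    prop[c.region]["outliers_with_source"] += c.size
        for sid in c.members:
            status_of[sid] = (
                c.classification
                if is_outlier
                else "non_outlier"
            )
        if c.classification == "outlier_with_source":
            for s in c.sources:
                key = (s.region, c.region)
                rec = edge_rows.setdefault(
                    key, {"source_region": s.region, "outlier_region": c.region,
                          "count": 0, "clusters": []}
                )
                if c.label not in rec["clusters"]:
                    rec["count"] += 1
                    rec["clusters"].append(c.label)
    edges = pd.DataFrame(
        list(edge_rows.values()),
        columns=["source_region", "outlier_region", "count", "clusters"],
    )
    prop_df = pd.DataFrame(
        [
            {
                "region": r,
                **v,
                "outlier_proportion": v["outliers"] / v["total"] if v["total"] else np.nan,
                "outlier_with_source_proportion":
                    v["outliers_with_source"] / v["total"] if v["total"] else np.nan,
            }
            for r, v in prop.items()
        ]
    )

    sex_bias = _sex_bias_test(status_of, meta)
    return MigrationNetwork(regions, edges, prop_df, sex_bias)


def _sex_bias_test(status_of: Mapping[str, str], meta: pd.DataFrame) -> dict:
    """Chi-square of sex x outlier status over clustered individuals."""
    cats = ("non_outlier", "outlier_with_source", "outlier_without_source")
    table = np.zeros((len(cats), 2), dtype=int)
    for sid, status in status_of.items():
        sex = meta.loc[sid, "sex"] if sid in meta.index else "U"
        if sex not in ("M", "F"):
            continue
        table[cats.index(status), 0 if sex == "M" else 1] += 1
    used = table[table.sum(axis=1) > 0]
    if used.shape[0] < 2 or (used.sum(axis=0) == 0).any():
        return {"table": table.tolist(), "chi2": None, "p": None, "df": None}
    chi2, p, df, _ = chi2_contingency(used, correction=False)
    return {"table": table.tolist(), "chi2": float(chi2), "p": float(p), "df": int(df)}


def sex_outlier_chi2(table: np.ndarray) -> tuple[float, float, int]:
    """Plain chi-square of an outlier-status x sex contingency table."""
    chi2, p, df, _ = chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p), int(df)


# ---------------------------------------------------------------------------
# End-to-end driver
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class WorkflowResult:
    clusters: list[RegionPeriodCluster]
    assignments: pd.DataFrame  # individual, region, period, cluster, classification
    network: MigrationNetwork
    test_log: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.assignments.to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
        edges = self.network.edges.copy()
        if len(edges):
            edges["clusters"] = edges["clusters"].map(",".join)
        edges.to_csv(out_dir / "edges.tsv", sep="\t", index=False)
        payload = {
            "nodes": self.network.nodes,
            "edges": edges.to_dict(orient="records"),
            "proportions": self.network.proportions.to_dict(orient="records"),
            "sex_bias": self.network.sex_bias,
        }
        with open(out_dir / "network.json", "w") as fh:
            json.dump(payload, fh, indent=1)
        self.test_log.to_csv(out_dir / "clade_tests.tsv", sep="\t", index=False)


def run_outlier_workflow(
    matrix: GenotypeMatrix,
    metadata: pd.DataFrame,
    right_groups: Mapping[str, str],
    config: WorkflowConfig = WorkflowConfig(),
    block_size_bp: int | None = None,
) -> WorkflowResult:
    """The full pipeline: pairwise tests -> clusters -> outliers -> network.

    ``right_groups`` maps reference sample ids to their right-population
    label; every other sample with a clustering-window period is analysed
    within its metadata region.
    """
    blocks = make_blocks(matrix.sites, block_size_bp) if block_size_bp \
        else make_blocks(matrix.sites)
    # right labels in insertion order; the first is the f4 base reference
    rights: list[str] = []
    for lab in right_groups.values():
        if lab not in rights:
            rights.append(lab)

    meta = metadata.set_index("id")
    study_ids = [
        s for s in matrix.samples
        if s not in right_groups
        and s in meta.index
        and meta.loc[s, "period"] in config.clustering_periods
    ]
    groups: dict[str, str] = dict(right_groups)
    for s in study_ids:
        groups[s] = s
    counts = group_allele_counts(matrix, groups)

    all_clusters: list[RegionPeriodCluster] = []
    log_records: list[dict] = []
    by_region: dict[str, list[str]] = {}
    for s in study_ids:
        by_region.setdefault(str(meta.loc[s, "region"]), []).append(s)

    for region in sorted(by_region):
        ids = by_region[region]
        periods = [str(meta.loc[s, "period"]) for s in ids]
        if len(ids) == 1:
            labels = np.array([1])
        else:
            dmat, pair_log = pairwise_dissimilarity(ids, rights, counts, blocks)
            log_records.extend(
                {**r.to_record(), "stage": "pairwise", "region": region}
                for r in pair_log
            )
            labels = upgma_flat_clusters(dmat, config.cluster_cutoff_d)
        classifications = classify_clusters(labels, periods, config)
        all_clusters.extend(
            split_by_period(ids, labels, periods, region, classifications)
        )

    # pooled counts for every region_period cluster
    pooled: dict[str, str] = {}
    for c in all_clusters:
        for sid in c.members:
            pooled[sid] = c.label
    counts.update(group_allele_counts(matrix, pooled))

    majorities = [c for c in all_clusters if c.classification == "majority"]
    candidates = [c for c in all_clusters if c.classification == "outlier_candidate"]

    cluster_log: list[CladeTestResult] = []
    survivors = absorb_candidates_within_region(
        candidates, majorities, rights, counts, blocks, config, cluster_log
    )
    for cand in survivors:
        sources = find_cross_region_sources(
            cand, majorities, rights, counts, blocks, config, cluster_log
        )
        sources = compete_sources(cand, sources, rights, counts, blocks, config)
        sources = prioritize_sources_by_period(sources, cand.period)
        cand.sources = sources
        cand.classification = (
            "outlier_with_source" if sources else "outlier_without_source"
        )
    log_records.extend(
        {**r.to_record(), "stage": "cluster", "region": ""} for r in cluster_log
    )

    assignments = pd.DataFrame(
        [
            {
                "individual": sid,
                "region": c.region,
                "period": c.period,
                "cluster": c.label,
                "classification": c.classification,
                "sources": ";".join(s.label for s in c.sources),
            }
            for c in all_clusters
            for sid in c.members
        ]
    )
    network = summarize_network(all_clusters, metadata, config)
    return WorkflowResult(all_clusters, assignments, network, pd.DataFrame(log_records))
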