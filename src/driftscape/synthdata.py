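"""Synthetic ancient-DNA-like data with known ground truth.

Allele frequencies are generated by Balding-Nichols drift along a rooted
tree: along a branch with drift parameter F, the child frequency is drawn
from Beta(p(1-F)/F, (1-p)(1-F)/F) given the parent frequency p, so that
E[child] = p and Var(child) = F p (1-p).  The closed-form moments make the
generator self-checking: Hudson FST between two leaves is approximately the
summed drift along their connecting path (for small F), and expectations of
f4-statistics follow from shared branch overlaps.

The standard workflow fixture emulates the statistical structure of a
historical-period ancient-DNA compendium:

* six regional leaves hanging off a drifted backbone, each sampled as
  pseudohaploid individuals with wide per-individual missingness;
* eight deeply diverged reference ("right") populations attached at
  *different* backbone depths, so that they are differentially related to
  the regional leaves -- the property that gives f4 clade tests power.  A
  panel of pure outgroups would make every pair of regional leaves a formal
  clade and the outlier workflow blind by construction;
* planted cross-region migrants: individuals whose genotypes are drawn from
  one leaf but whose metadata (region, coordinates, period) place them in
  another region, with the truth recorded for recovery scoring.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genodata import (
    MISSING,
    GenotypeMatrix,
    validate_metadata,
    write_eigenstrat,
)

__all__ = [
    "DriftTree",
    "FixtureSpec",
    "Fixture",
    "sample_ancestral_freqs",
    "drift_along_tree",
    "genotypes_from_freqs",
    "pseudohaploidize",
    "standard_tree",
    "standard_fixture_spec",
    "build_fixture",
    "make_site_table",
]


class SynthError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class DriftTree:
    """Rooted drift tree as a child -> (parent, F) map.

    ``branches`` maps every non-root node name to its parent and branch
    drift parameter F in (0, 0.5].  ``regional_leaves`` and ``right_leaves``
    name the two kinds of tips; the first right leaf is the base (outgroup)
    reference of f4 vectors.
    """

    branches: Mapping[str, tuple[str, float]]
    regional_leaves: tuple[str, ...]
    right_leaves: tuple[str, ...]
    root: str = "root"

    def __post_init__(self) -> None:
        for child, (parent, F) in self.branches.items():
            if not 0.0 < F <= 0.5:
                raise SynthError(f"branch {parent}->{child}: F={F} outside (0, 0.5]")
        for leaf in (*self.regional_leaves, *self.right_leaves):
            if leaf not in self.branches:
                raise SynthError(f"leaf {leaf!r} has no branch to the tree")

    def topological_order(self) -> list[str]:
        """Nodes ordered root-first so parents precede children."""
        children: dict[str, list[str]] = {}
        for child, (parent, _) in self.branches.items():
            children.setdefault(parent, []).append(child)
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(sorted(children.get(node, []), reverse=True))
        return order

    def path_to_root(self, node: str) -> list[str]:
        path = []
        while node != self.root:
            path.append(node)
            node = self.branches[node][0]
        return path

    def path_drift(self, leaf_a: str, leaf_b: str) -> float:
        """Summed F along the path connecting two leaves (small-F FST oracle)."""
        pa = self.path_to_root(leaf_a)
        pb = self.path_to_root(leaf_b)
        shared = set(pa) & set(pb)
        return sum(self.branches[n][1] for n in pa if n not in shared) + sum(
            self.branches[n][1] for n in pb if n not in shared
        )


def sample_ancestral_freqs(n_sites: int, rng: np.random.Generator) -> np.ndarray:
    """Root allele frequencies ~ Uniform(0.05, 0.95), keeping sites informative."""
    if n_sites < 1:
        raise SynthError("n_sites must be >= 1")
    return rng.uniform(0.05, 0.95, size=n_sites)


def _drift_once(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols step; frequencies at 0/1 stay fixed."""
    scale = (1.0 - F) / F
    interior = (p > 0.0) & (p < 1.0)
    out = p.copy()
    if interior.any():
        a = np.maximum(p[interior] * scale, 1e-12)
        b = np.maximum((1.0 - p[interior]) * scale, 1e-12)
        out[interior] = rng.beta(a, b)
    return out


def drift_along_tree(
    tree: DriftTree, ancestral: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-node allele frequencies after drifting root-to-leaf.

    Returns frequencies for every node, keyed by name; leaves are what
    callers usually want.
    """
    freqs = {tree.root: np.asarray(ancestral, dtype=float)}
    for node in tree.topological_order():
        if node == tree.root:
            continue
        parent, F = tree.branches[node]
        freqs[node] = _drift_once(freqs[parent], F, rng)
    return freqs


def genotypes_from_freqs(
    freqs: np.ndarray, n_individuals: int, rng: np.random.Generator
) -> np.ndarray:
    """Diploid genotypes ~ Binomial(2, p), sites x individuals, int8."""
    p = np.asarray(freqs, dtype=float)
    return rng.binomial(2, p[:, None], size=(len(p), n_individuals)).astype(np.int8)


def pseudohaploidize(
    calls: np.ndarray,
    missingness: Sequence[float] | float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random-allele pseudohaploid calls with per-individual missingness.

    Heterozygotes become 0 or 2 with probability 1/2 each; homozygotes keep
    their value class.  Each individual's sites are then masked MISSING
    independently at that individual's missingness rate.
    """
    calls = np.asarray(calls)
    n_sites, n_ind = calls.shape
    miss = np.broadcast_to(np.asarray(missingness, dtype=float), (n_ind,))
    out = calls.astype(np.int8).copy()
    hets = out == 1
    out[hets] = rng.choice(np.array([0, 2], dtype=np.int8), size=int(hets.sum()))
    mask = rng.random((n_sites, n_ind)) < miss[None, :]
    out[mask] = MISSING
    return out


# ---------------------------------------------------------------------------
# Standard fixture
# ---------------------------------------------------------------------------

#: Backbone drift between consecutive internal nodes of the standard tree.
BACKBONE_F = 0.03

#: Pendant drift of the six regional leaves (range [0.01, 0.05]).
REGIONAL_F = (0.02, 0.03, 0.01, 0.04, 0.02, 0.05)

#: Drift of the eight right branches (range [0.1, 0.3]); index 0 is the
#: deep outgroup used as the f4 base.
RIGHT_F = (0.30, 0.25, 0.20, 0.15, 0.20, 0.25, 0.10, 0.30)

#: Backbone node each right attaches to (0 = root); spreading the
#: attachment points is what makes rights differentially related to the
#: regional leaves.
RIGHT_ATTACH = (0, 1, 2, 3, 4, 5, 6, 2)

REGION_NAMES = ("Iberia", "Italy", "Balkans", "Anatolia", "Levant", "NorthAfrica")
REGION_CENTROIDS = {
    "Iberia": (40.0, -4.0),
    "Italy": (42.5, 12.5),
    "Balkans": (43.0, 21.0),
    "Anatolia": (39.0, 33.0),
    "Levant": (33.0, 36.0),
    "NorthAfrica": (34.0, 9.0),
}

STUDY_PERIODS = (
    "Copper Age",
    "Bronze Age",
    "Iron Age",
    "Imperial Rome & Late Antiquity",
    "Medieval Ages & Early Modern",
)


def standard_tree(
    n_regions: int = 6,
    backbone_f: float = BACKBONE_F,
    regional_f: Sequence[float] = REGIONAL_F,
    right_f: Sequence[float] = RIGHT_F,
    right_attach: Sequence[int] = RIGHT_ATTACH,
) -> DriftTree:
    """The standard drift tree: a drifted backbone with interleaved tips.

    Backbone nodes B1..Bn carry the regional leaves L1..Ln on shallow
    pendant branches; right leaves R1..R8 hang on long branches attached at
    staggered backbone depths (R1 at the root is the outgroup base).
    """
    branches: dict[str, tuple[str, float]] = {}
    prev = "root"
    for i in range(1, n_regions + 1):
        node = f"B{i}"
        branches[node] = (prev, backbone_f)
        prev = node
    regional = []
    for i in range(1, n_regions + 1):
        leaf = f"L{i}"
        branches[leaf] = (f"B{i}", float(regional_f[(i - 1) % len(regional_f)]))
        regional.append(leaf)
    rights = []
    for j, (F, at) in enumerate(zip(right_f, right_attach), start=1):
        leaf = f"R{j}"
        parent = "root" if at == 0 else f"B{min(at, n_regions)}"
        branches[leaf] = (parent, float(F))
        rights.append(leaf)
    return DriftTree(branches, tuple(regional), tuple(rights))


def make_site_table(
    n_sites: int, n_chrom: int = 22, chrom_span_bp: int = 135_000_000
) -> pd.DataFrame:
    """Evenly spaced site annotations across ``n_chrom`` chromosomes.

    Spacing is chosen so each chromosome spans ~``chrom_span_bp``, giving a
    realistic number of 5 Mb jackknife blocks (~27 per chromosome).
    """
    per_chrom = int(np.ceil(n_sites / n_chrom))
    spacing = max(chrom_span_bp // per_chrom, 1)
    chroms, positions = [], []
    for c in range(1, n_chrom + 1):
        k = min(per_chrom, n_sites - len(chroms))
        if k <= 0:
            break
        chroms.extend([str(c)] * k)
        positions.extend((np.arange(k, dtype=np.int64) * spacing + 1).tolist())
    return pd.DataFrame(
        {
            "id": [f"snp{i}" for i in range(len(chroms))],
            "chrom": chroms,
            "genpos": [p * 1e-8 for p in positions],
            "physpos": positions,
            "ref": "A",
            "alt": "C",
        }
    )


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic workflow fixture.

    ``missing_range`` spans the wide per-individual missingness observed in
    pseudohaploid ancient genomes; ``migrant_plan`` lists planted migrants
    as (source_leaf, sink_region, count, period) with genotypes from the
    source leaf and metadata from the sink region.
    """

    n_sites: int = 50_000
    individuals_per_leaf: int = 40
    rights_per_leaf: int = 6
    missing_range: tuple[float, float] = (0.15, 0.85)
    right_missingness: float = 0.05
    migrant_plan: tuple[tuple[str, str, int, str], ...] = ()
    seed: int = 0
    tree: DriftTree = dataclasses.field(default_factory=standard_tree)
    regions: tuple[str, ...] = REGION_NAMES
    coord_jitter_deg: float = 1.5

    def __post_init__(self) -> None:
        leaf_of_region = dict(zip(self.regions, self.tree.regional_leaves))
        for source_leaf, sink_region, count, period in self.migrant_plan:
            if sink_region not in leaf_of_region:
                raise SynthError(f"unknown sink region {sink_region!r}")
            if leaf_of_region[sink_region] == source_leaf:
                raise SynthError(
                    f"migrant source leaf {source_leaf!r} equals the sink "
                    f"region's own leaf"
                )
            if count < 1:
                raise SynthError("migrant count must be >= 1")


def standard_fixture_spec(
    n_sites: int = 50_000,
    individuals_per_leaf: int = 40,
    migrant_fraction: float = 0.03,
    seed: int = 0,
) -> FixtureSpec:
    """The standard fixture: 6 regions x 40 individuals, 8 rights x 6,
    ~3% planted migrants from backbone-distant source leaves."""
    tree = standard_tree()
    regions = REGION_NAMES
    n_total = individuals_per_leaf * len(regions)
    n_migrants = int(round(migrant_fraction * n_total))
    plan = []
    rng = np.random.default_rng(seed + 901)
    for k in range(n_migrants):
        sink_i = k % len(regions)
        source_i = (sink_i + 3) % len(regions)  # 3 backbone segments away
        period = STUDY_PERIODS[rng.integers(len(STUDY_PERIODS))]
        plan.append((tree.regional_leaves[source_i], regions[sink_i], 1, period))
    return FixtureSpec(
        n_sites=n_sites,
        individuals_per_leaf=individuals_per_leaf,
        migrant_plan=tuple(plan),
        seed=seed,
        tree=tree,
        regions=regions,
    )


@dataclasses.dataclass
class Fixture:
    """A generated fixture: genotypes, metadata, truth, and leaf frequencies."""

    matrix: GenotypeMatrix
    metadata: pd.DataFrame
    truth: pd.DataFrame
    leaf_freqs: dict[str, np.ndarray]
    right_groups: dict[str, str]  # sample id -> right label
    spec: FixtureSpec

    def right_labels(self) -> list[str]:
        return list(self.spec.tree.right_leaves)


def build_fixture(spec: FixtureSpec, out_dir: str | Path | None = None) -> Fixture:
    """Generate a complete fixture; optionally write EIGENSTRAT + TSV + JSON.

    Deterministic under ``spec.seed``.  Study individuals are pseudohaploid
    with per-individual missingness ~ Uniform(missing_range); right-panel
    individuals are pseudohaploid with low, fixed missingness.
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree
    ancestral = sample_ancestral_freqs(spec.n_sites, rng)
    freqs = drift_along_tree(tree, ancestral, rng)

    leaf_of_region = dict(zip(spec.regions, tree.regional_leaves))
    sites = make_site_table(spec.n_sites)

    sample_ids: list[str] = []
    call_blocks: list[np.ndarray] = []
    meta_rows: list[dict] = []
    truth_rows: list[dict] = []
    right_groups: dict[str, str] = {}

    # planted migrants per sink region
    migrants_by_region: dict[str, list[tuple[str, str]]] = {}
    for source_leaf, sink_region, count, period in spec.migrant_plan:
        migrants_by_region.setdefault(sink_region, []).extend(
            [(source_leaf, period)] * count
        )

    periods = list(STUDY_PERIODS)
    for region in spec.regions:
        leaf = leaf_of_region[region]
        migrants = migrants_by_region.get(region, [])
        n_local = spec.individuals_per_leaf - len(migrants)
        if n_local < 0:
            raise SynthError(f"migrant plan overfills region {region!r}")
        lat0, lon0 = REGION_CENTROIDS.get(region, (45.0, 10.0))
        plan = [(leaf, None)] * n_local + list(migrants)
        dip = np.empty((spec.n_sites, len(plan)), dtype=np.int8)
        for j, (src_leaf, _) in enumerate(plan):
            dip[:, j] = genotypes_from_freqs(freqs[src_leaf], 1, rng)[:, 0]
        miss = rng.uniform(*spec.missing_range, size=len(plan))
        ph = pseudohaploidize(dip, miss, rng)
        call_blocks.append(ph)
        for j, (src_leaf, mig_period) in enumerate(plan):
            sid = f"{region}_{j:03d}"
            sample_ids.append(sid)
            is_migrant = src_leaf != leaf
            period = mig_period if is_migrant else periods[int(rng.integers(len(periods)))]
            meta_rows.append(
                {
                    "id": sid,
                    "sex": "M" if rng.random() < 0.55 else "F",
                    "group_label": region,
                    "lat": lat0 + rng.normal(0, spec.coord_jitter_deg / 2),
                    "lon": lon0 + rng.normal(0, spec.coord_jitter_deg / 2),
                    "region": region,
                    "period": period,
                    "role": "study",
                }
            )
            truth_rows.append(
                {
                    "id": sid,
                    "true_leaf": src_leaf,
                    "migrant": bool(is_migrant),
                    "true_source_region": next(
                        (r for r, lf in leaf_of_region.items() if lf == src_leaf), None
                    )
                    if is_migrant
                    else None,
                }
            )

    # right panels: low-missingness pseudohaploid reference individuals
    for right in tree.right_leaves:
        dip = genotypes_from_freqs(freqs[right], spec.rights_per_leaf, rng)
        ph = pseudohaploidize(dip, spec.right_missingness, rng)
        call_blocks.append(ph)
        for j in range(spec.rights_per_leaf):
            sid = f"{right}_{j:02d}"
            sample_ids.append(sid)
            right_groups[sid] = right
            meta_rows.append(
                {
                    "id": sid,
                    "sex": "U",
                    "group_label": right,
                    "lat": 0.0,
                    "lon": 0.0,
                    "region": right,
                    "period": "Present-day",
                    "role": "reference",
                }
            )
            truth_rows.append(
                {"id": sid, "true_leaf": right, "migrant": False,
                 "true_source_region": None}
            )

    calls = np.hstack(call_blocks)
    matrix = GenotypeMatrix(sites, sample_ids, calls, "pseudohaploid")
    metadata = validate_metadata(pd.DataFrame(meta_rows))
    truth = pd.DataFrame(truth_rows)
    fixture = Fixture(matrix, metadata, truth, freqs, right_groups, spec)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ind = pd.DataFrame(
            {"id": sample_ids,
             "sex": metadata.set_index("id").loc[sample_ids, "sex"].tolist(),
             "group": metadata.set_index("id").loc[sample_ids, "group_label"].tolist()}
        )
        write_eigenstrat(matrix, ind, out_dir / "fixture")
        metadata.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
        truth_out = truth.copy()
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(truth_out.to_dict(orient="records"), fh, indent=1)
    return fixture
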