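"""Genotype data model and I/O.

Genotypes are held as a sites x samples matrix of small integers:
``0``, ``1``, ``2`` count copies of the alternate (derived) allele and
``MISSING`` (-1 internally, ``9`` on disk) marks no-call sites.  Two ploidy
modes are supported: ``diploid`` (calls in {0,1,2}) and ``pseudohaploid``,
the standard representation for low-coverage ancient genomes where a single
randomly drawn allele is recorded as a homozygous call, so only {0,2} occur
and each non-missing call carries one observed allele rather than two.

The on-disk format is plain-text EIGENSTRAT (.geno/.snp/.ind).  Sample
metadata (coordinates, region, archaeological period) travels in a separate
tab-separated table.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing call in the in-memory matrix.
MISSING: int = -1

#: Character used for a missing call in .geno files.
GENO_MISSING_CHAR = "9"

#: Ordered archaeological period bins (name, start year, end year; years CE,
#: negative = BCE).  The upper bound is exclusive; the last bin is open-ended.
PERIODS: tuple[tuple[str, float, float], ...] = (
    ("Mesolithic and Neolithic", -10000, -3500),
    ("Copper Age", -3500, -2300),
    ("Bronze Age", -2300, -1000),
    ("Iron Age", -1000, 1),
    ("Imperial Rome & Late Antiquity", 1, 700),
    ("Medieval Ages & Early Modern", 700, 1900),
    ("Present-day", 1900, float("inf")),
)

PERIOD_NAMES: tuple[str, ...] = tuple(p[0] for p in PERIODS)
PERIOD_INDEX: dict[str, int] = {name: i for i, (name, _, _) in enumerate(PERIODS)}

_TRANSITION_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

METADATA_REQUIRED_COLUMNS = ("id", "lat", "lon", "region", "period")


class GenodataError(ValueError):
    """Raised on malformed genotype or metadata input."""


@dataclasses.dataclass(frozen=True)
class Variant:
    """A single biallelic site.

    Attributes
    ----------
    id : str
        Site identifier.
    chrom : str
        Chromosome label.
    genpos : float
        Genetic position in Morgans.
    physpos : int
        Physical position in bp (1-based).
    allele_ref, allele_alt : str
        Reference and alternate allele (single characters).
    """

    id: str
    chrom: str
    genpos: float
    physpos: int
    allele_ref: str
    allele_alt: str

    def is_transition(self) -> bool:
        return (self.allele_ref.upper(), self.allele_alt.upper()) in _TRANSITION_PAIRS


@dataclasses.dataclass(frozen=True)
class SiteFilterSpec:
    """Shared site-level filters.

    ``min_maf`` is a dataset-wide minor-allele-frequency floor computed on
    non-missing calls; ``exclusion_list`` holds precomputed site ids to drop
    (e.g. transitions at CpG sites, which cannot be recognised without
    flanking sequence); ``drop_transitions`` removes every A<->G / C<->T site.
    """

    min_maf: float = 0.0
    exclusion_list: frozenset[str] = frozenset()
    drop_transitions: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf <= 0.5:
            raise GenodataError(f"min_maf must be in [0, 0.5], got {self.min_maf}")


class GenotypeMatrix:
    """Sites x samples genotype calls with site annotations.

    Parameters
    ----------
    sites : pandas.DataFrame
        One row per site with columns ``id, chrom, genpos, physpos, ref, alt``.
    samples : sequence of str
        Sample identifiers, one per matrix column.
    calls : ndarray of int8, shape (n_sites, n_samples)
        Values in {0, 1, 2, MISSING}; pseudohaploid mode admits only
        {0, 2, MISSING}.
    ploidy_mode : {"diploid", "pseudohaploid"}
    """

    SITE_COLUMNS = ("id", "chrom", "genpos", "physpos", "ref", "alt")

    def __init__(
        self,
        sites: pd.DataFrame,
        samples: Sequence[str],
        calls: np.ndarray,
        ploidy_mode: str = "diploid",
    ) -> None:
        sites = sites.reset_index(drop=True)
        missing_cols = set(self.SITE_COLUMNS) - set(sites.columns)
        if missing_cols:
            raise GenodataError(f"site table lacks columns: {sorted(missing_cols)}")
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(sites), len(samples)):
            raise GenodataError(
                f"calls shape {calls.shape} does not match "
                f"{len(sites)} sites x {len(samples)} samples"
            )
        if ploidy_mode not in ("diploid", "pseudohaploid"):
            raise GenodataError(f"unknown ploidy_mode {ploidy_mode!r}")
        allowed = {0, 2, MISSING} if ploidy_mode == "pseudohaploid" else {0, 1, 2, MISSING}
        observed = set(np.unique(calls).tolist())
        if not observed <= allowed:
            raise GenodataError(
                f"calls contain values {sorted(observed - allowed)} invalid for "
                f"{ploidy_mode} mode"
            )
        if len(set(samples)) != len(samples):
            raise GenodataError("duplicate sample ids in matrix")
        self.sites = sites
        self.samples = list(samples)
        self.calls = calls
        self.ploidy_mode = ploidy_mode
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    # -- basic introspection -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    @property
    def alleles_per_call(self) -> int:
        """Observed alleles carried by one non-missing call (1 or 2)."""
        return 1 if self.ploidy_mode == "pseudohaploid" else 2

    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        idx = []
        for s in ids:
            if s not in self._sample_index:
                raise GenodataError(f"sample {s!r} not present in matrix")
            idx.append(self._sample_index[s])
        return np.asarray(idx, dtype=np.intp)

    def variants(self) -> list[Variant]:
        return [
            Variant(str(r.id), str(r.chrom), float(r.genpos), int(r.physpos),
                    str(r.ref), str(r.alt))
            for r in self.sites.itertuples(index=False)
        ]

    # -- subsetting ----------------------------------------------------------

    def take_sites(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        sites = self.sites.loc[np.asarray(mask_or_index)].reset_index(drop=True) \
            if np.asarray(mask_or_index).dtype == bool else \
            self.sites.iloc[np.asarray(mask_or_index)].reset_index(drop=True)
        return GenotypeMatrix(
            sites, self.samples, self.calls[mask_or_index], self.ploidy_mode
        )

    def take_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix(self.sites, list(ids), self.calls[:, idx], self.ploidy_mode)

    # -- frequencies ---------------------------------------------------------

    def dataset_allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Dataset-wide (derived, called) allele counts per site."""
        nonmissing = self.calls != MISSING
        if self.ploidy_mode == "pseudohaploid":
            derived = (self.calls == 2).sum(axis=1)
            called = nonmissing.sum(axis=1)
        else:
            derived = np.where(nonmissing, self.calls, 0).sum(axis=1)
            called = 2 * nonmissing.sum(axis=1)
        return derived.astype(np.int64), called.astype(np.int64)


# ---------------------------------------------------------------------------
# EIGENSTRAT I/O
# ---------------------------------------------------------------------------

_GENO_DECODE = np.full(256, -2, dtype=np.int8)
for _ch, _val in (("0", 0), ("1", 1), ("2", 2), (GENO_MISSING_CHAR, MISSING)):
    _GENO_DECODE[ord(_ch)] = _val


def read_eigenstrat(
    geno_path: str | Path, snp_path: str | Path, ind_path: str | Path
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a plain-text EIGENSTRAT triple.

    Returns the genotype matrix plus the .ind table as a DataFrame with
    columns ``id, sex, group``.  The ploidy mode is inferred: a matrix with
    no heterozygous (``1``) call is flagged pseudohaploid.
    """
    ind = pd.read_csv(
        ind_path, sep=r"\s+", header=None, names=["id", "sex", "group"], dtype=str
    )
    if ind["id"].duplicated().any():
        dup = ind["id"][ind["id"].duplicated()].iloc[0]
        raise GenodataError(f"duplicate sample id {dup!r} in {ind_path}")
    n_samples = len(ind)

    snp = pd.read_csv(
        snp_path,
        sep=r"\s+",
        header=None,
        names=["id", "chrom", "genpos", "physpos", "ref", "alt"],
        dtype={"id": str, "chrom": str, "ref": str, "alt": str},
    )
    snp["genpos"] = snp["genpos"].astype(float)
    snp["physpos"] = snp["physpos"].astype(np.int64)

    rows = []
    with open(geno_path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if len(line) != n_samples:
                raise GenodataError(
                    f"row {i + 1}: {len(line)} genotypes for {n_samples} samples"
                )
            decoded = _GENO_DECODE[np.frombuffer(line.encode("ascii"), dtype=np.uint8)]
            bad = np.nonzero(decoded == -2)[0]
            if bad.size:
                raise GenodataError(
                    f"row {i + 1}, column {bad[0] + 1}: invalid genotype "
                    f"character {line[bad[0]]!r}"
                )
            rows.append(decoded)
    calls = np.vstack(rows) if rows else np.empty((0, n_samples), dtype=np.int8)
    if len(calls) != len(snp):
        raise GenodataError(
            f"{len(calls)} genotype rows but {len(snp)} sites in {snp_path}"
        )
    mode = "diploid" if (calls == 1).any() else "pseudohaploid"
    return GenotypeMatrix(snp, ind["id"].tolist(), calls, mode), ind


def write_eigenstrat(
    matrix: GenotypeMatrix, ind_table: pd.DataFrame | None, out_prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Write .geno/.snp/.ind files readable by :func:`read_eigenstrat`.

    ``ind_table`` may be None, in which case sex ``U`` and group ``Ignore``
    are written for every sample.  Missing calls are written as ``9``.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    geno_path = out_prefix.with_suffix(".geno")
    snp_path = out_prefix.with_suffix(".snp")
    ind_path = out_prefix.with_suffix(".ind")

    encode = np.array(["0", "1", "2"], dtype="U1")
    with open(geno_path, "w") as fh:
        for row in matrix.calls:
            chars = np.where(row == MISSING, GENO_MISSING_CHAR, encode[np.where(row == MISSING, 0, row)])
            fh.write("".join(chars) + "\n")

    with open(snp_path, "w") as fh:
        for r in matrix.sites.itertuples(index=False):
            fh.write(
                f"{r.id}\t{r.chrom}\t{r.genpos:.6f}\t{int(r.physpos)}\t{r.ref}\t{r.alt}\n"
            )

    if ind_table is None:
        ind_table = pd.DataFrame(
            {"id": matrix.samples, "sex": "U", "group": "Ignore"}
        )
    with open(ind_path, "w") as fh:
        for r in ind_table.itertuples(index=False):
            fh.write(f"{r.id}\t{r.sex}\t{r.group}\n")
    return geno_path, snp_path, ind_path


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def read_metadata(tsv_path: str | Path, period_names: Sequence[str] = PERIOD_NAMES) -> pd.DataFrame:
    """Read and validate the sample-metadata table.

    Required columns: ``id, lat, lon, region, period``.  Optional columns
    ``sex``, ``group_label``, ``date_mid`` and ``role`` are passed through
    (defaults: U / region / NaN / study).
    """
    meta = pd.read_csv(tsv_path, sep="\t", dtype={"id": str})
    return validate_metadata(meta, period_names)


def validate_metadata(
    meta: pd.DataFrame, period_names: Sequence[str] = PERIOD_NAMES
) -> pd.DataFrame:
    missing = [c for c in METADATA_REQUIRED_COLUMNS if c not in meta.columns]
    if missing:
        raise GenodataError(f"metadata lacks required column(s): {missing}")
    meta = meta.copy()
    if meta["id"].duplicated().any():
        dup = meta["id"][meta["id"].duplicated()].iloc[0]
        raise GenodataError(f"duplicate sample id {dup!r} in metadata")
    for col, lo, hi in (("lat", -90.0, 90.0), ("lon", -180.0, 180.0)):
        vals = meta[col].astype(float)
        bad = meta.loc[(vals < lo) | (vals > hi) | ((col == "lon") & (vals >= 180.0)), "id"]
        if len(bad):
            raise GenodataError(
                f"sample {bad.iloc[0]!r}: {col} out of range "
                f"[{lo}, {hi}{')' if col == 'lon' else ']'}"
            )
        meta[col] = vals
    valid = set(period_names)
    unknown = meta.loc[~meta["period"].isin(valid), "period"]
    if len(unknown):
        raise GenodataError(
            f"unknown period {unknown.iloc[0]!r}; valid bins: {list(period_names)}"
        )
    if "sex" not in meta.columns:
        meta["sex"] = "U"
    if "group_label" not in meta.columns:
        meta["group_label"] = meta["region"]
    if "role" not in meta.columns:
        meta["role"] = "study"
    return meta


# ---------------------------------------------------------------------------
# Filters and group counting
# ---------------------------------------------------------------------------

def apply_site_filters(matrix: GenotypeMatrix, spec: SiteFilterSpec) -> GenotypeMatrix:
    """Apply dataset-wide MAF, exclusion-list and transition filters.

    The MAF is computed on non-missing calls only (one allele per
    pseudohaploid call, two per diploid call).  Sites with no called allele
    fail any positive MAF threshold.  Raises if nothing survives.
    """
    derived, called = matrix.dataset_allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(called > 0, derived / np.maximum(called, 1), np.nan)
    maf = np.fmin(freq, 1.0 - freq)
    keep = np.ones(matrix.n_sites, dtype=bool)
    if spec.min_maf > 0:
        keep &= np.nan_to_num(maf, nan=-1.0) >= spec.min_maf
    if spec.exclusion_list:
        keep &= ~matrix.sites["id"].isin(spec.exclusion_list).to_numpy()
    if spec.drop_transitions:
        ra = matrix.sites["ref"].str.upper()
        aa = matrix.sites["alt"].str.upper()
        transition = ((ra == "A") & (aa == "G")) | ((ra == "G") & (aa == "A")) | \
                     ((ra == "C") & (aa == "T")) | ((ra == "T") & (aa == "C"))
        keep &= ~transition.to_numpy()
    if not keep.any():
        raise GenodataError("site filters removed every site")
    return matrix.take_sites(keep)


def group_allele_counts(
    matrix: GenotypeMatrix, groups: Mapping[str, str]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-site (derived_count, called_alleles) for each group label.

    ``groups`` maps sample id -> group label.  A pseudohaploid call
    contributes one observed allele, a diploid call two.  Sites where a group
    has zero called alleles are left at (0, 0); downstream consumers treat
    them as uninformative for that group.
    """
    if not groups:
        raise GenodataError("empty group map")
    by_label: dict[str, list[str]] = {}
    for sid, label in groups.items():
        by_label.setdefault(label, []).append(sid)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for label, ids in by_label.items():
        if not ids:
            raise GenodataError(f"group {label!r} has no members")
        idx = matrix.sample_index(ids)
        sub = matrix.calls[:, idx]
        nonmissing = sub != MISSING
        if matrix.ploidy_mode == "pseudohaploid":
            derived = (sub == 2).sum(axis=1)
            called = nonmissing.sum(axis=1)
        else:
            derived = np.where(nonmissing, sub, 0).sum(axis=1)
            called = 2 * nonmissing.sum(axis=1)
        out[label] = (derived.astype(np.int64), called.astype(np.int64))
    return out


def group_freqs(
    counts: Mapping[str, tuple[np.ndarray, np.ndarray]]
) -> dict[str, np.ndarray]:
    """Frequencies derived/called per group; NaN where a group is uncalled."""
    out = {}
    for label, (derived, called) in counts.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            out[label] = np.where(called > 0, derived / np.maximum(called, 1), np.nan)
    return out


def period_rank(period: str) -> int:
    """Ordinal index of a period bin (0 = oldest)."""
    try:
        return PERIOD_INDEX[period]
    except KeyError:
        raise GenodataError(
            f"unknown period {period!r}; valid bins: {list(PERIOD_NAMES)}"
        ) from None
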