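"""Sliding-grid Hudson FST and the isolation-by-distance curve.

Samples are binned into 10-degree x 10-degree cells on a grid anchored at
(-180, -90); the grid is slid by 1 degree north and east nine times, giving
ten overlapping grids.  For every pair of populated cells (within each
grid), FST is computed with Hudson's estimator with unequal-sample-size
correction, combined across sites as a ratio of sums:

    N_s = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D_s = p1(1-p2) + p2(1-p1)
    FST = sum_s N_s / sum_s D_s

together with the mean pairwise great-circle distance between the
individuals of the two cells.  A lowess fit of FST against distance gives
the isolation-by-distance curve; confidence bands come from a spatial
bootstrap that resamples connected components of the cell-overlap graph, so
that an individual (who appears in up to ten overlapping cells) is either
fully in a bootstrap replicate or fully out.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
import statsmodels.api as sm

from .genodata import MISSING, GenotypeMatrix

EARTH_RADIUS_KM = 6371.0088

DEFAULT_LOWESS_FRAC = 0.67
DEFAULT_LOWESS_IT = 3
N_EVAL_POINTS = 100


class SpatialFstError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Sliding-grid geometry; offsets shift the anchor north and east."""

    cell_deg: float = 10.0
    step_deg: float = 1.0
    n_offsets: int = 10
    anchor: tuple[float, float] = (-180.0, -90.0)  # (lon0, lat0)
    min_cell_n: int = 2

    def __post_init__(self) -> None:
        if self.n_offsets * self.step_deg > self.cell_deg:
            raise SpatialFstError("n_offsets * step_deg must not exceed cell_deg")


@dataclasses.dataclass(frozen=True)
class IbdCurve:
    """Lowess isolation-by-distance curve with bootstrap percentile bands."""

    distances: np.ndarray
    fit: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_points: int
    n_bootstrap: int


# ---------------------------------------------------------------------------
# Estimator and geometry
# ---------------------------------------------------------------------------

def hudson_fst(
    counts_a: tuple[np.ndarray, np.ndarray], counts_b: tuple[np.ndarray, np.ndarray]
) -> float:
    """Multi-site Hudson FST (ratio of sums) between two allele-count sets.

    ``counts_*`` are per-site (derived, called) arrays; a site is used only
    when both sides have at least two called alleles (the n-1 correction
    needs n >= 2).  Returns NaN (with a warning) when the denominator sum is
    zero.  Negative values are legitimate (the estimator is unbiased around
    zero differentiation) and returned as-is.
    """
    d1, n1 = (np.asarray(x, dtype=float) for x in counts_a)
    d2, n2 = (np.asarray(x, dtype=float) for x in counts_b)
    use = (n1 >= 2) & (n2 >= 2)
    if not use.any():
        warnings.warn("hudson_fst: no jointly called sites", stacklevel=2)
        return float("nan")
    p1 = d1[use] / n1[use]
    p2 = d2[use] / n2[use]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1[use] - 1) - p2 * (1 - p2) / (n2[use] - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    dsum = den.sum()
    if dsum == 0:
        warnings.warn("hudson_fst: zero denominator (no segregating sites)", stacklevel=2)
        return float("nan")
    return float(num.sum() / dsum)


def haversine_km(
    lat1: np.ndarray, lon1: np.ndarray, lat2: np.ndarray, lon2: np.ndarray
) -> np.ndarray:
    """Great-circle distance in km (Earth radius 6371.0088 km)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def geographic_distance(
    point_a: tuple[float, float],
    point_b: tuple[float, float],
    mode: str = "haversine",
) -> float:
    """Distance between (lat, lon) points: km (haversine) or unitless
    (euclidean, for simulated habitats)."""
    if mode == "haversine":
        return float(haversine_km(point_a[0], point_a[1], point_b[0], point_b[1]))
    if mode == "euclidean":
        return float(np.hypot(point_a[0] - point_b[0], point_a[1] - point_b[1]))
    raise SpatialFstError(f"unknown distance mode {mode!r}")


def assign_cells(
    lats: np.ndarray, lons: np.ndarray, spec: GridSpec, offset_idx: int
) -> dict[tuple[int, int], np.ndarray]:
    """Cell membership for one offset grid.

    Cell index = (floor((lon - lon0 - g)/cell), floor((lat - lat0 - g)/cell))
    with g = offset_idx * step_deg.  Cells with fewer than ``min_cell_n``
    samples are dropped.
    """
    g = offset_idx * spec.step_deg
    lon0, lat0 = spec.anchor
    ix = np.floor((np.asarray(lons) - lon0 - g) / spec.cell_deg).astype(int)
    iy = np.floor((np.asarray(lats) - lat0 - g) / spec.cell_deg).astype(int)
    cells: dict[tuple[int, int], list[int]] = {}
    for i, key in enumerate(zip(ix, iy)):
        cells.setdefault(key, []).append(i)
    return {
        key: np.asarray(members, dtype=np.intp)
        for key, members in cells.items()
        if len(members) >= spec.min_cell_n
    }


def _cell_counts(matrix: GenotypeMatrix, members: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sub = matrix.calls[:, members]
    nonmissing = sub != MISSING
    if matrix.ploidy_mode == "pseudohaploid":
        return (sub == 2).sum(axis=1), nonmissing.sum(axis=1)
    return np.where(nonmissing, sub, 0).sum(axis=1), 2 * nonmissing.sum(axis=1)


def grid_fst_distance_table(
    matrix: GenotypeMatrix,
    metadata: pd.DataFrame,
    spec: GridSpec = GridSpec(),
    mode: str = "haversine",
) -> pd.DataFrame:
    """(FST, mean distance) for every populated-cell pair of every offset grid.

    Returns one row per pair with the cell identities and their lon/lat
    extents (needed by the spatial bootstrap).  Samples within half a cell
    width of the antimeridian are rejected: the grid does not wrap.
    """
    meta = metadata.set_index("id").loc[matrix.samples]
    lats = meta["lat"].to_numpy(dtype=float)
    lons = meta["lon"].to_numpy(dtype=float)
    near_wrap = np.abs(np.abs(lons) - 180.0) < spec.cell_deg / 2
    if near_wrap.any():
        warnings.warn(
            f"{int(near_wrap.sum())} sample(s) near the antimeridian excluded "
            "(grid does not wrap)",
            stacklevel=2,
        )
        keep = ~near_wrap
        lats, lons = lats[keep], lons[keep]
        matrix = matrix.take_samples([s for s, k in zip(matrix.samples, keep) if k])

    lon0, lat0 = spec.anchor
    rows = []
    any_pair = False
    for g in range(spec.n_offsets):
        cells = assign_cells(lats, lons, spec, g)
        keys = sorted(cells)
        counts = {k: _cell_counts(matrix, cells[k]) for k in keys}
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                ka, kb = keys[i], keys[j]
                fst = hudson_fst(counts[ka], counts[kb])
                if not np.isfinite(fst):
                    continue
                ia, ib = cells[ka], cells[kb]
                if mode == "haversine":
                    dmat = haversine_km(
                        lats[ia][:, None], lons[ia][:, None],
                        lats[ib][None, :], lons[ib][None, :],
                    )
                else:
                    dmat = np.hypot(
                        lats[ia][:, None] - lats[ib][None, :],
                        lons[ia][:, None] - lons[ib][None, :],
                    )
                off = g * spec.step_deg
                rows.append(
                    {
                        "offset": g,
                        "cellA": f"g{g}:{ka[0]},{ka[1]}",
                        "cellB": f"g{g}:{kb[0]},{kb[1]}",
                        "nA": len(ia),
                        "nB": len(ib),
                        "fst": fst,
                        "mean_km": float(dmat.mean()),
                        "lonA0": lon0 + off + ka[0] * spec.cell_deg,
                        "latA0": lat0 + off + ka[1] * spec.cell_deg,
                        "lonB0": lon0 + off + kb[0] * spec.cell_deg,
                        "latB0": lat0 + off + kb[1] * spec.cell_deg,
                    }
                )
                any_pair = True
    if not any_pair:
        raise SpatialFstError("no offset grid contains two populated cells")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Lowess curve and spatial bootstrap
# ---------------------------------------------------------------------------

def lowess_fit(
    x: np.ndarray,
    y: np.ndarray,
    frac: float = DEFAULT_LOWESS_FRAC,
    eval_x: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Lowess curve of y on x evaluated on a regular grid.

    Uses statsmodels' lowess (``frac`` span, 3 robustifying iterations) and
    linearly interpolates the fitted values onto ``eval_x`` (default: 100
    equally spaced distances spanning the data).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise SpatialFstError(f"lowess needs >= 10 points, got {len(x)}")
    fitted = sm.nonparametric.lowess(y, x, frac=frac, it=DEFAULT_LOWESS_IT)
    if eval_x is None:
        eval_x = np.linspace(x.min(), x.max(), N_EVAL_POINTS)
    fit = np.interp(eval_x, fitted[:, 0], fitted[:, 1])
    return eval_x, fit


def _cell_extents(points: pd.DataFrame, cell_deg: float) -> pd.DataFrame:
    """Unique cells referenced by the points, with lon/lat intervals."""
    recs = {}
    for _, r in points.iterrows():
        for side in ("A", "B"):
            key = r[f"cell{side}"]
            if key not in recs:
                recs[key] = (
                    r[f"lon{side}0"], r[f"lon{side}0"] + cell_deg,
                    r[f"lat{side}0"], r[f"lat{side}0"] + cell_deg,
                )
    return pd.DataFrame.from_dict(
        recs, orient="index", columns=["lon0", "lon1", "lat0", "lat1"]
    )


def overlap_components(points: pd.DataFrame, cell_deg: float) -> pd.Series:
    """Connected components of the cell-overlap graph.

    Two cells overlap when both their longitude and latitude intervals
    intersect with positive length; individuals shared between overlapping
    cells are then resampled jointly.
    """
    cells = _cell_extents(points, cell_deg)
    n = len(cells)
    lon0 = cells["lon0"].to_numpy()
    lon1 = cells["lon1"].to_numpy()
    lat0 = cells["lat0"].to_numpy()
    lat1 = cells["lat1"].to_numpy()
    rows_i, rows_j = [], []
    for i in range(n):
        lon_ov = (np.minimum(lon1[i], lon1) - np.maximum(lon0[i], lon0)) > 0
        lat_ov = (np.minimum(lat1[i], lat1) - np.maximum(lat0[i], lat0)) > 0
        for j in np.nonzero(lon_ov & lat_ov)[0]:
            if j != i:
                rows_i.append(i)
                rows_j.append(j)
    graph = csr_matrix(
        (np.ones(len(rows_i)), (rows_i, rows_j)), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    return pd.Series(labels, index=cells.index)


def spatial_bootstrap_ci(
    points: pd.DataFrame,
    n_bootstrap: int = 200,
    frac: float = DEFAULT_LOWESS_FRAC,
    cell_deg: float = 10.0,
    rng: np.random.Generator | None = None,
) -> IbdCurve:
    """Overlap-aware bootstrap bands for the isolation-by-distance curve.

    Populated cells are grouped into connected components of the overlap
    graph; each replicate resamples components with replacement, and a point
    (pair of cells) enters a replicate once per joint inclusion of its two
    components.  Bands are pointwise 2.5/97.5 percentiles of the replicate
    lowess curves.
    """
    rng = np.random.default_rng() if rng is None else rng
    comp = overlap_components(points, cell_deg)
    comp_a = comp.loc[points["cellA"]].to_numpy()
    comp_b = comp.loc[points["cellB"]].to_numpy()
    n_comp = int(comp.max()) + 1
    if n_comp < 2:
        warnings.warn(
            "all populated cells form one overlap component; the spatial "
            "bootstrap is degenerate (bands may be too narrow)",
            stacklevel=2,
        )
    x = points["mean_km"].to_numpy(dtype=float)
    y = points["fst"].to_numpy(dtype=float)
    eval_x, fit = lowess_fit(x, y, frac=frac)

    curves = np.full((n_bootstrap, len(eval_x)), np.nan)
    for b in range(n_bootstrap):
        draws = rng.integers(0, n_comp, size=n_comp)
        times = np.bincount(draws, minlength=n_comp)
        weight = np.where(
            comp_a == comp_b, times[comp_a], times[comp_a] * times[comp_b]
        )
        if (weight > 0).sum() < 10:
            continue
        xb = np.repeat(x, weight)
        yb = np.repeat(y, weight)
        try:
            _, curves[b] = lowess_fit(xb, yb, frac=frac, eval_x=eval_x)
        except SpatialFstError:
            continue
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lower = np.nanpercentile(curves, 2.5, axis=0)
        upper = np.nanpercentile(curves, 97.5, axis=0)
    return IbdCurve(eval_x, fit, lower, upper, len(points), n_bootstrap)
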