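"""Spatial statistics on phenotype-labeled segmented-cell tables.

All statistics operate on cell centroids in micrometres and are computed
per sample: radius-based neighborhood proportions (what fraction of the
cells surrounding a reference population belongs to a target population),
mean nearest-neighbor distances, "touching" cell pairs approximated by a
center-distance threshold, and rosette calls (a malignant HRS cell
surrounded by at least ``rosette_min_cells`` cells of a ring phenotype
within the neighborhood radius).

Distances are Euclidean with an inclusive boundary (``<=``).  Neighbor
queries use a k-d tree; all results are exactly equal to a brute-force
all-pairs scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class SpatialConfig:
    """Distance and count parameters for the spatial statistics.

    Parameters
    ----------
    neighborhood_radius_um
        Radius of the disk around each reference cell defining its
        "surrounding region" (default 75 um).
    touching_distance_um
        Center-to-center distance below which two cells are considered
        touching (default 10 um, about one lymphocyte diameter; membrane
        outlines are not available on centroid data).
    rosette_min_cells
        Minimum number of ring-phenotype cells within the neighborhood
        radius of an HRS cell for it to be called a rosette.
    min_rosette_fraction
        A case is called rosette-positive when the fraction of its HRS
        cells with a rosette exceeds this value (default 0: any rosette).
    """

    neighborhood_radius_um: float = 75.0
    touching_distance_um: float = 10.0
    rosette_min_cells: int = 5
    min_rosette_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.neighborhood_radius_um <= 0 or self.touching_distance_um <= 0:
            raise ValueError("distances must be positive")
        if self.rosette_min_cells < 1:
            raise ValueError("rosette_min_cells must be >= 1")

    def to_dict(self) -> dict:
        return {
            "neighborhood_radius_um": self.neighborhood_radius_um,
            "touching_distance_um": self.touching_distance_um,
            "rosette_min_cells": self.rosette_min_cells,
            "min_rosette_fraction": self.min_rosette_fraction,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SpatialConfig":
        return cls(**dict(d))


def _require_phenotype(cells: pd.DataFrame) -> None:
    if "phenotype" not in cells.columns:
        raise ValueError("cells have no 'phenotype' column; assign phenotypes first")


def _xy(df: pd.DataFrame) -> np.ndarray:
    return np.column_stack(
        [np.asarray(df["x_um"], float), np.asarray(df["y_um"], float)]
    )


def neighborhood_proportion(
    cells: pd.DataFrame,
    reference: str,
    target: str,
    config: SpatialConfig | None = None,
) -> pd.DataFrame:
    """Proportion of target cells among all cells surrounding a reference
    population, per sample.

    The surrounding region is the union of disks of radius
    ``neighborhood_radius_um`` centered on each reference cell; cells in
    overlapping disks are counted once.  The denominator is every
    non-reference cell in the region; the numerator is the target cells in
    the region.  Samples with no reference cells, or with an empty region,
    carry ``proportion = NaN`` and ``defined = False`` (undefined, not
    zero).
    """
    config = config or SpatialConfig()
    _require_phenotype(cells)
    r = config.neighborhood_radius_um
    rows = []
    for sample_id, sdf in cells.groupby("sample_id", sort=True):
        refs = sdf[sdf["phenotype"] == reference]
        others = sdf[sdf["phenotype"] != reference]
        n_ref = len(refs)
        if n_ref == 0 or len(others) == 0:
            rows.append(
                dict(
                    sample_id=sample_id,
                    reference_phenotype=reference,
                    target_phenotype=target,
                    n_reference=n_ref,
                    n_in_region=0,
                    n_target_in_region=0,
                    proportion=np.nan,
                    defined=False,
                )
            )
            continue
        tree = cKDTree(_xy(refs))
        dist, _ = tree.query(_xy(others), k=1)
        in_region = dist <= r
        n_in = int(in_region.sum())
        n_target = int(
            ((others["phenotype"] == target).to_numpy() & in_region).sum()
        )
        rows.append(
            dict(
                sample_id=sample_id,
                reference_phenotype=reference,
                target_phenotype=target,
                n_reference=n_ref,
                n_in_region=n_in,
                n_target_in_region=n_target,
                proportion=(n_target / n_in) if n_in else np.nan,
                defined=n_in > 0,
            )
        )
    return pd.DataFrame(rows)


def mean_nn_distance(
    cells: pd.DataFrame,
    reference: str,
    target: str,
    config: SpatialConfig | None = None,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Average distance from each reference cell to its nearest target cell.

    Computed per sample as the arithmetic mean (or median, via
    ``statistic='median'``) over reference cells of the Euclidean distance
    to the closest target cell.  Undefined (NaN, flagged) when either
    phenotype is absent from a sample.
    """
    del config  # distances are unbounded; config kept for interface symmetry
    _require_phenotype(cells)
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    agg = np.mean if statistic == "mean" else np.median
    rows = []
    for sample_id, sdf in cells.groupby("sample_id", sort=True):
        refs = sdf[sdf["phenotype"] == reference]
        targets = sdf[sdf["phenotype"] == target]
        if len(refs) == 0 or len(targets) == 0:
            rows.append(
                dict(
                    sample_id=sample_id,
                    reference_phenotype=reference,
                    target_phenotype=target,
                    n_reference=len(refs),
                    mean_nn_um=np.nan,
                    defined=False,
                )
            )
            continue
        tree = cKDTree(_xy(targets))
        dist, _ = tree.query(_xy(refs), k=1)
        rows.append(
            dict(
                sample_id=sample_id,
                reference_phenotype=reference,
                target_phenotype=target,
                n_reference=len(refs),
                mean_nn_um=float(agg(dist)),
                defined=True,
            )
        )
    return pd.DataFrame(rows)


def call_rosettes(
    cells: pd.DataFrame,
    hrs_phenotype: str = "HRS",
    ring_phenotype: str = "TFH_CXCL13",
    config: SpatialConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call rosettes: HRS cells ringed by >= ``rosette_min_cells`` cells of
    the ring phenotype within the neighborhood radius.

    Returns
    -------
    calls
        One row per HRS cell: ``sample_id, hrs_cell_id,
        n_phenotype_within_radius, is_rosette``.
    per_sample
        One row per sample: ``sample_id, n_hrs, n_rosette,
        rosette_fraction, case_positive, evaluable``.  Samples without HRS
        cells are flagged not evaluable.
    """
    config = config or SpatialConfig()
    _require_phenotype(cells)
    r = config.neighborhood_radius_um
    call_rows = []
    sample_rows = []
    for sample_id, sdf in cells.groupby("sample_id", sort=True):
        hrs = sdf[sdf["phenotype"] == hrs_phenotype]
        ring = sdf[sdf["phenotype"] == ring_phenotype]
        if len(hrs) == 0:
            sample_rows.append(
                dict(
                    sample_id=sample_id,
                    n_hrs=0,
                    n_rosette=0,
                    rosette_fraction=np.nan,
                    case_positive=False,
                    evaluable=False,
                )
            )
            continue
        if len(ring) == 0:
            counts = np.zeros(len(hrs), dtype=int)
        else:
            tree = cKDTree(_xy(ring))
            counts = np.array(
                [len(ix) for ix in tree.query_ball_point(_xy(hrs), r)], int
            )
        is_rosette = counts >= config.rosette_min_cells
        for cid, n, flag in zip(hrs["cell_id"], counts, is_rosette):
            call_rows.append(
                dict(
                    sample_id=sample_id,
                    hrs_cell_id=cid,
                    n_phenotype_within_radius=int(n),
                    is_rosette=bool(flag),
                )
            )
        frac = float(is_rosette.mean())
        sample_rows.append(
            dict(
                sample_id=sample_id,
                n_hrs=len(hrs),
                n_rosette=int(is_rosette.sum()),
                rosette_fraction=frac,
                case_positive=frac > config.min_rosette_fraction,
                evaluable=True,
            )
        )
    calls = pd.DataFrame(
        call_rows,
        columns=[
            "sample_id",
            "hrs_cell_id",
            "n_phenotype_within_radius",
            "is_rosette",
        ],
    )
    return calls, pd.DataFrame(sample_rows)


def touching_pairs(
    cells: pd.DataFrame,
    phenotype_a: str,
    phenotype_b: str,
    config: SpatialConfig | None = None,
) -> pd.DataFrame:
    """All unordered cross-phenotype cell pairs with center distance at most
    ``touching_distance_um``, per sample."""
    config = config or SpatialConfig()
    _require_phenotype(cells)
    if phenotype_a == phenotype_b:
        raise ValueError("touching_pairs expects two distinct phenotypes")
    d = config.touching_distance_um
    rows = []
    for sample_id, sdf in cells.groupby("sample_id", sort=True):
        ca = sdf[sdf["phenotype"] == phenotype_a]
        cb = sdf[sdf["phenotype"] == phenotype_b]
        if len(ca) == 0 or len(cb) == 0:
            continue
        xa, xb = _xy(ca), _xy(cb)
        tree_b = cKDTree(xb)
        ids_a = ca["cell_id"].to_numpy()
        ids_b = cb["cell_id"].to_numpy()
        for i, neighbors in enumerate(cKDTree(xa).query_ball_tree(tree_b, d)):
            for j in neighbors:
                rows.append(
                    dict(
                        sample_id=sample_id,
                        cell_id_a=ids_a[i],
                        cell_id_b=ids_b[j],
                        distance_um=float(np.linalg.norm(xa[i] - xb[j])),
                    )
                )
    return pd.DataFrame(
        rows, columns=["sample_id", "cell_id_a", "cell_id_b", "distance_um"]
    )


@dataclass
class GroupComparison:
    """Result of comparing a per-sample statistic between groups."""

    test: str  # "welch_t" or "anova"
    statistic: float
    p_value: float
    group_means: dict
    n_excluded: int


def compare_between_groups(
    values: Mapping[str, float] | pd.Series,
    groups: Mapping[str, str],
) -> GroupComparison:
    """Compare a per-sample statistic between groups.

    Welch's t-test for two groups, one-way ANOVA for more.  Samples whose
    statistic is undefined (NaN) are excluded and counted; a group left
    with no defined values is an error.
    """
    values = pd.Series(dict(values), dtype=float)
    by_group: dict[str, list[float]] = {}
    n_excluded = 0
    for sample, value in values.items():
        g = groups[sample]
        if np.isnan(value):
            n_excluded += 1
            continue
        by_group.setdefault(g, []).append(float(value))
    for g in set(groups.values()):
        if not by_group.get(g):
            raise ValueError(f"group {g!r} has no samples with a defined statistic")
    if len(by_group) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(v) for v in by_group.values()]
    if len(arrays) == 2:
        stat, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
        test = "welch_t"
    else:
        stat, p = stats.f_oneway(*arrays)
        test = "anova"
    return GroupComparison(
        test=test,
        statistic=float(stat),
        p_value=float(p),
        group_means={g: float(np.mean(v)) for g, v in by_group.items()},
        n_excluded=n_excluded,
    )
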