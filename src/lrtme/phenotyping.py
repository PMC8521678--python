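"""Marker gating, phenotype assignment, and exclusive coexpression patterns.

Cells arrive as a table of per-cell marker intensities (one row per
segmented cell).  Gating converts each intensity to a positive/negative
call by thresholding; phenotype assignment maps the call pattern to a
named population (e.g. ``CD4+PD1+CXCL13+CXCR5-``); coexpression-pattern
counting enumerates the *exact* positive marker subset of every cell over
a chosen panel, the quantity displayed by UpSet plots.

Cell tables are plain :class:`pandas.DataFrame` objects with columns
``sample_id``, ``cell_id``, ``x_um``, ``y_um``, one column per marker
intensity, boolean call columns named ``<marker>_pos`` after gating, and a
``phenotype`` column after assignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Reserved (non-marker) column names in a spatial cell table.
CELL_TABLE_COLUMNS = ("sample_id", "cell_id", "x_um", "y_um")

CALL_SUFFIX = "_pos"


class ConfigurationError(ValueError):
    """A gating or phenotype configuration refers to data that is absent."""


def marker_columns(cells: pd.DataFrame) -> list[str]:
    """Names of marker-intensity columns in a cell table."""
    reserved = set(CELL_TABLE_COLUMNS) | {"phenotype"}
    return [
        c
        for c in cells.columns
        if c not in reserved and not c.endswith(CALL_SUFFIX)
    ]


@dataclass(frozen=True)
class PhenotypeDef:
    """A named sign pattern over markers.

    A cell matches when every marker in ``required_pos`` was called
    positive and every marker in ``required_neg`` was called negative;
    markers not listed are unconstrained.
    """

    name: str
    required_pos: tuple[str, ...] = ()
    required_neg: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "required_pos", tuple(self.required_pos))
        object.__setattr__(self, "required_neg", tuple(self.required_neg))
        overlap = set(self.required_pos) & set(self.required_neg)
        if overlap:
            raise ConfigurationError(
                f"phenotype {self.name!r}: markers {sorted(overlap)} listed "
                "as both required-positive and required-negative"
            )

    @property
    def markers(self) -> set[str]:
        return set(self.required_pos) | set(self.required_neg)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "required_pos": list(self.required_pos),
            "required_neg": list(self.required_neg),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhenotypeDef":
        return cls(
            d["name"],
            tuple(d.get("required_pos", ())),
            tuple(d.get("required_neg", ())),
        )


@dataclass(frozen=True)
class GatingConfig:
    """Per-marker intensity cutoffs.

    Positivity is strict: a cell is positive for a marker iff its intensity
    is strictly greater than the cutoff, so a cell sitting exactly at the
    threshold is negative.
    """

    thresholds: Mapping[str, float]

    def to_dict(self) -> dict:
        return {"thresholds": dict(self.thresholds)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "GatingConfig":
        return cls(thresholds=dict(d["thresholds"]))


def _otsu_split(values: np.ndarray) -> float:
    """Exact Otsu cut on the empirical distribution.

    Evaluates the between-class variance at every cut between consecutive
    sorted observations (no histogram binning, so a wide empty gap between
    populations cannot be mislocated) and returns the midpoint of the
    optimal gap.
    """
    x = np.sort(np.asarray(values, float))
    n = x.size
    csum = np.cumsum(x)
    k = np.arange(1, n)
    w0 = k / n
    w1 = 1.0 - w0
    m0 = csum[:-1] / k
    m1 = (csum[-1] - csum[:-1]) / (n - k)
    objective = w0 * w1 * (m0 - m1) ** 2
    best = int(np.argmax(objective))
    return float((x[best] + x[best + 1]) / 2.0)


def otsu_thresholds(
    cells: pd.DataFrame, markers: Sequence[str] | None = None
) -> GatingConfig:
    """Parameter-free default gates: per-marker Otsu split of log intensities.

    Intended for intensity distributions that are mixtures of a negative and
    a positive population (approximately bimodal on the log scale).  The
    Otsu cut is computed on ``log(intensity)`` and mapped back to the
    intensity scale.
    """
    if markers is None:
        markers = marker_columns(cells)
    thresholds: dict[str, float] = {}
    for m in markers:
        values = np.asarray(cells[m], dtype=float)
        if np.any(values < 0):
            raise ConfigurationError(f"marker {m!r} has negative intensities")
        logv = np.log(values + 1e-12)
        if np.ptp(logv) == 0:
            # Degenerate single-valued marker: gate everything negative.
            thresholds[m] = float(values[0])
            continue
        thresholds[m] = float(np.exp(_otsu_split(logv)))
    return GatingConfig(thresholds=thresholds)


def gate_cells(
    cells: pd.DataFrame, config: GatingConfig | None = None
) -> pd.DataFrame:
    """Fill boolean ``<marker>_pos`` call columns from intensities.

    When ``config`` is ``None``, thresholds default to a per-marker Otsu
    split of log intensities (:func:`otsu_thresholds`).  Gating is
    idempotent: re-running with the same config rewrites identical calls.

    Raises
    ------
    ConfigurationError
        If a configured marker has no intensity column.
    """
    if config is None:
        config = otsu_thresholds(cells)
    out = cells.copy()
    for m, thr in config.thresholds.items():
        if m not in cells.columns:
            raise ConfigurationError(
                f"gating threshold for marker {m!r} but no such intensity "
                "column in the cell table"
            )
        out[m + CALL_SUFFIX] = np.asarray(cells[m], dtype=float) > float(thr)
    return out


def _call_matrix(cells: pd.DataFrame, markers: Sequence[str]) -> np.ndarray:
    cols = []
    for m in markers:
        col = m + CALL_SUFFIX
        if col not in cells.columns:
            raise ConfigurationError(
                f"no positivity calls for marker {m!r}; run gate_cells first"
            )
        cols.append(np.asarray(cells[col], dtype=bool))
    return np.column_stack(cols) if cols else np.empty((len(cells), 0), bool)


def assign_phenotypes(
    cells: pd.DataFrame, defs: Sequence[PhenotypeDef], other_label: str = "other"
) -> pd.DataFrame:
    """Assign each cell the first matching phenotype definition.

    Definitions are evaluated in list order (priority); a cell matching no
    definition receives ``other_label``.  One label per cell keeps the
    spatial statistics unambiguous.
    """
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigurationError(f"duplicate phenotype names: {dupes}")

    all_markers = sorted(set().union(*(d.markers for d in defs))) if defs else []
    calls = _call_matrix(cells, all_markers)
    idx = {m: i for i, m in enumerate(all_markers)}

    phenotype = np.full(len(cells), other_label, dtype=object)
    unassigned = np.ones(len(cells), dtype=bool)
    for d in defs:
        match = unassigned.copy()
        for m in d.required_pos:
            match &= calls[:, idx[m]]
        for m in d.required_neg:
            match &= ~calls[:, idx[m]]
        phenotype[match] = d.name
        unassigned &= ~match

    out = cells.copy()
    out["phenotype"] = phenotype
    return out


@dataclass
class CoexpressionPatternCounts:
    """Exclusive marker-combination counts over a panel (UpSet-style).

    Each cell is counted exactly once, under the exact subset of panel
    markers it is positive for; the counts therefore always sum to
    ``denominator``.
    """

    marker_panel: tuple[str, ...]
    counts: dict[frozenset, int] = field(default_factory=dict)
    denominator: int = 0

    def to_frame(self) -> pd.DataFrame:
        """One row per observed subset, encoded as '+'-joined sorted names."""
        rows = [
            {
                "pattern": "+".join(sorted(s)) if s else "none",
                "n_markers": len(s),
                "count": c,
            }
            for s, c in self.counts.items()
        ]
        df = pd.DataFrame(rows, columns=["pattern", "n_markers", "count"])
        df = df.sort_values(
            ["count", "pattern"], ascending=[False, True], ignore_index=True
        )
        return df


def coexpression_patterns(
    positivity, panel: Sequence[str]
) -> CoexpressionPatternCounts:
    """Count exact positive marker subsets over ``panel``.

    Parameters
    ----------
    positivity
        Either a gated spatial cell table (boolean ``<marker>_pos``
        columns), or a cells x markers DataFrame of booleans / expression
        values; expression values are treated as positive when > 0, the
        conventional nonzero-detection rule for log-normalized single-cell
        data.
    panel
        Ordered marker set to restrict the patterns to.
    """
    panel = tuple(panel)
    if not panel:
        raise ConfigurationError("empty marker panel")

    df = positivity
    if all(m + CALL_SUFFIX in df.columns for m in panel):
        mat = _call_matrix(df, panel)
    else:
        missing = [m for m in panel if m not in df.columns]
        if missing:
            raise ConfigurationError(
                f"panel markers missing from input: {missing}"
            )
        mat = np.asarray(df[list(panel)])
        if mat.dtype != bool:
            mat = mat.astype(float) > 0

    counts: dict[frozenset, int] = {}
    # Encode each row's positive set as a bit pattern, then tally.
    weights = 1 << np.arange(len(panel))
    codes = mat @ weights
    for code, n in zip(*np.unique(codes, return_counts=True)):
        members = frozenset(
            m for i, m in enumerate(panel) if (int(code) >> i) & 1
        )
        counts[members] = int(n)
    return CoexpressionPatternCounts(
        marker_panel=panel, counts=counts, denominator=int(mat.shape[0])
    )


def enumerate_patterns(panel: Sequence[str]) -> Iterable[frozenset]:
    """All 2^k subsets of a panel, in size-then-lexicographic order."""
    for r in range(len(panel) + 1):
        for combo in itertools.combinations(sorted(panel), r):
            yield frozenset(combo)
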