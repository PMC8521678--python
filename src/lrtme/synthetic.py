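"""Synthetic spatial maps, expression matrices, and survival cohorts.

The generators emulate the statistical structure of a lymphocyte-rich
classic Hodgkin lymphoma (LR-CHL) study cohort so the downstream analyses
can be exercised and property-tested against known ground truth:

* **Spatial maps** -- per-sample fields of segmented-cell centroids with
  per-marker intensities.  Rare CD30+ HRS cells are scattered with a
  minimum spacing; a configurable fraction of them receives a planted
  "rosette", a ring of CD4+PD1+CXCL13+CXCR5- T cells at a fixed radius;
  the remaining cells are a background mixture of phenotypes.  Marker
  intensities follow a two-component log-normal model (positive vs
  negative population per marker), which makes threshold gating
  well-posed.
* **Expression matrices** -- cells x genes negative-binomial counts around
  per-cluster mean profiles, with per-sample cluster composition drawn
  from subtype-specific proportion vectors and optional per-(subtype,
  cluster) mean shifts for individual genes (e.g. CXCL13 up and CXCR5
  down in the LR-CHL TFH cluster).  Counts are library-normalized to a
  fixed size and log2(x+1)-transformed.
* **Survival cohorts** -- exponential event times with a group-specific
  hazard (phenotype-high vs -low) under administrative censoring.

Every generator is deterministic given its spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from . import panels
from .phenotyping import PhenotypeDef
from .sc import lognormalize

__all__ = [
    "SyntheticSpatialSpec",
    "SyntheticExpressionSpec",
    "SyntheticSurvivalSpec",
    "PlacementError",
    "generate_spatial",
    "generate_expression",
    "generate_survival",
    "default_spatial_spec",
    "default_expression_spec",
    "default_survival_spec",
]


class PlacementError(RuntimeError):
    """A spatial field is too dense to place the requested cells."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticSpatialSpec:
    """Parameters of the spatial-map generator.

    ``phenotype_mixture`` maps each subtype label to the background
    phenotype proportions (summing to 1); ``background_density`` is the
    total background density in cells per mm^2.  ``intensity_model`` maps
    each marker to ``(mu_pos, sigma_pos, mu_neg, sigma_neg)`` on the
    natural-log intensity scale.  ``min_hrs_spacing_um`` keeps planted
    rings from contaminating the neighborhood of another HRS cell, so the
    planted ground truth stays unambiguous under the default 75-um
    detection radius.
    """

    n_samples: int = 6
    subtype_labels: tuple[str, ...] = ()  # per sample; default set in factory
    field_size_um: tuple[float, float] = (1000.0, 1000.0)
    n_hrs_per_sample: int = 10
    rosette_fraction: float = 0.5
    ring_count: int = 6
    ring_radius_um: float = 20.0
    ring_jitter_um: float = 2.0
    min_hrs_spacing_um: float = 160.0
    background_density_per_mm2: float = 800.0
    phenotype_mixture: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )
    intensity_model: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rosette_fraction <= 1:
            raise ValueError("rosette_fraction must be in [0, 1]")
        if self.ring_radius_um >= 75:
            raise ValueError(
                "ring_radius_um must stay below the 75-um neighborhood radius"
            )
        if self.ring_radius_um <= 0 or self.ring_jitter_um < 0:
            raise ValueError("ring geometry must be positive")
        for subtype, mix in self.phenotype_mixture.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"phenotype mixture for {subtype!r} sums to {total}, not 1"
                )

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "subtype_labels": list(self.subtype_labels),
            "field_size_um": list(self.field_size_um),
            "n_hrs_per_sample": self.n_hrs_per_sample,
            "rosette_fraction": self.rosette_fraction,
            "ring_count": self.ring_count,
            "ring_radius_um": self.ring_radius_um,
            "ring_jitter_um": self.ring_jitter_um,
            "min_hrs_spacing_um": self.min_hrs_spacing_um,
            "background_density_per_mm2": self.background_density_per_mm2,
            "phenotype_mixture": {
                k: dict(v) for k, v in self.phenotype_mixture.items()
            },
            "intensity_model": {
                k: list(v) for k, v in self.intensity_model.items()
            },
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticSpatialSpec":
        d = dict(d)
        d["subtype_labels"] = tuple(d.get("subtype_labels", ()))
        d["field_size_um"] = tuple(d.get("field_size_um", (1000.0, 1000.0)))
        if "intensity_model" in d:
            d["intensity_model"] = {
                k: tuple(v) for k, v in d["intensity_model"].items()
            }
        return cls(**d)


@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Parameters of the expression-matrix generator.

    ``cluster_means`` is a clusters x genes DataFrame of mean log2
    expression; realized counts for a cell in cluster ``c`` are negative
    binomial with mean ``2**cluster_means[c, g] - 1`` and size
    ``dispersion`` (Poisson in the infinite-dispersion limit).
    ``coexpression_overrides`` maps ``(subtype, cluster)`` to per-gene
    replacement log2 means, the device used to plant subtype-dependent
    coexpression such as CXCL13+CXCR5- TFH cells in LR-CHL.
    """

    n_cells_per_sample: int = 400
    subtype_labels: tuple[str, ...] = ("LR", "otherCHL")
    cluster_means: pd.DataFrame = None  # type: ignore[assignment]
    composition_by_subtype: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )
    coexpression_overrides: Mapping[tuple, Mapping[str, float]] = field(
        default_factory=dict
    )
    dispersion: float = 2.0
    library_size: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_means is None:
            raise ValueError("cluster_means is required")
        if (np.asarray(self.cluster_means) < 0).any():
            raise ValueError("cluster_means must be nonnegative (log2 scale)")
        if not self.composition_by_subtype:
            raise ValueError("composition_by_subtype is empty")
        genes = set(self.cluster_means.columns)
        clusters = set(self.cluster_means.index)
        for subtype in self.subtype_labels:
            if subtype not in self.composition_by_subtype:
                raise ValueError(f"no composition for subtype {subtype!r}")
        for subtype, comp in self.composition_by_subtype.items():
            if not comp:
                raise ValueError(f"empty composition vector for {subtype!r}")
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError(
                    f"composition for {subtype!r} does not sum to 1"
                )
            unknown = set(comp) - clusters
            if unknown:
                raise ValueError(
                    f"composition for {subtype!r} names unknown clusters "
                    f"{sorted(unknown)}"
                )
        for (subtype, cluster), shifts in self.coexpression_overrides.items():
            missing = set(shifts) - genes
            if missing:
                raise ValueError(
                    f"override for ({subtype!r}, {cluster!r}) names genes "
                    f"absent from cluster_means: {sorted(missing)}"
                )
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive (np.inf for Poisson)")


@dataclass(frozen=True)
class SyntheticSurvivalSpec:
    """Parameters of the survival-cohort generator.

    Event times are exponential: hazard ``hazard_low`` per year in the
    phenotype-low group and ``hazard_low * hazard_ratio`` in the high
    group; follow-up is administratively censored at
    ``censor_time_years``.
    """

    n_cases: int = 60
    group_fraction_high: float = 0.5
    hazard_low: float = 0.05
    hazard_ratio: float = 4.0
    censor_time_years: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hazard_low <= 0 or self.hazard_ratio <= 0:
            raise ValueError("hazards must be positive")
        if not 0 < self.group_fraction_high < 1:
            raise ValueError("group_fraction_high must be in (0, 1)")
        if self.censor_time_years < 0:
            raise ValueError("censor_time_years must be nonnegative")


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: Two-component log-normal intensity model per marker: (mu_pos, sigma_pos,
#: mu_neg, sigma_neg) on the natural-log scale.  The positive and negative
#: populations are separated by 3 log units with sigma 0.25 (a 6-sigma gap
#: on each side), wide enough that Otsu gating on log intensities stays
#: near-exact even for markers whose positive population is rare (CD30+
#: HRS cells are ~1% of all cells).
DEFAULT_INTENSITY_MODEL = {
    m: (3.0, 0.25, 0.0, 0.25) for m in panels.DEFAULT_MARKERS
}

#: Background phenotype mixtures by subtype.  LR-CHL fields carry more
#: CXCL13+ TFH-like cells and CXCR5+ B cells than other subtypes; the
#: absolute background level of the ring phenotype is kept low relative to
#: the planted rings (a 75-um disk holds ~0.4 background ring cells in
#: expectation) so rosette calls reflect planted structure.
DEFAULT_PHENOTYPE_MIXTURE = {
    "LR": {
        "TFH_CXCL13": 0.03,
        "B_CXCR5": 0.17,
        "T_CD4": 0.40,
        "B": 0.30,
        "other": 0.10,
    },
    "otherCHL": {
        "TFH_CXCL13": 0.01,
        "B_CXCR5": 0.06,
        "T_CD4": 0.55,
        "B": 0.23,
        "other": 0.15,
    },
}

#: Marker sign patterns implied by each ground-truth phenotype; markers not
#: listed are negative.
PHENOTYPE_MARKER_SIGNS = {
    "HRS": {"CD30": True},
    "TFH_CXCL13": {"CD4": True, "PD1": True, "CXCL13": True, "CXCR5": False},
    "B_CXCR5": {"CD20": True, "CXCR5": True},
    "T_CD4": {"CD4": True},
    "B": {"CD20": True},
    "other": {},
}


def default_spatial_spec(
    n_samples: int = 6, seed: int = 0, **overrides
) -> SyntheticSpatialSpec:
    """Spatial spec with the default study conditions.

    Samples alternate LR / otherCHL subtype labels unless
    ``subtype_labels`` is supplied.
    """
    labels = overrides.pop(
        "subtype_labels",
        tuple("LR" if i % 2 == 0 else "otherCHL" for i in range(n_samples)),
    )
    kwargs = dict(
        n_samples=n_samples,
        subtype_labels=labels,
        phenotype_mixture=DEFAULT_PHENOTYPE_MIXTURE,
        intensity_model=DEFAULT_INTENSITY_MODEL,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticSpatialSpec(**kwargs)


# Gene panel for the expression generator: canonical cluster markers plus
# every gene named by the built-in ligand-receptor panel.
_CLUSTER_MARKER_GENES = [
    "CD3D", "CD4", "CD8A", "FOXP3", "IL2RA", "LAG3", "PDCD1", "ICOS",
    "BCL6", "CXCL13", "CXCR5", "MS4A1", "CD19", "IGHD", "CD27", "CD38",
    "CCR7", "SELL", "GNLY", "NKG7", "CD14", "LYZ", "HLA-DRA", "TGFB1",
]


def _default_cluster_means() -> pd.DataFrame:
    genes = sorted(
        set(_CLUSTER_MARKER_GENES)
        | {g for pair in panels.DEFAULT_LR_PAIRS for g in pair}
    )
    clusters = [
        "Treg", "TFH", "CD4_helper", "CD8_T", "NaiveB", "GCB", "MemB",
        "Macrophage",
    ]
    means = pd.DataFrame(0.5, index=clusters, columns=genes)

    def bump(cluster: str, gene_levels: Mapping[str, float]) -> None:
        for g, v in gene_levels.items():
            means.loc[cluster, g] = v

    bump("Treg", {"CD3D": 4, "CD4": 3, "FOXP3": 4, "IL2RA": 3.5, "LAG3": 3,
                  "CTLA4": 3})
    bump("TFH", {"CD3D": 4, "CD4": 3, "PDCD1": 3.5, "ICOS": 3, "BCL6": 2.5,
                 "CXCR5": 3, "CXCL13": 1.0, "HLA-DRA": 2})
    bump("CD4_helper", {"CD3D": 4, "CD4": 3, "CCR7": 2.5, "SELL": 2.5,
                        "IL7R": 3})
    bump("CD8_T", {"CD3D": 4, "CD8A": 4, "GNLY": 3, "NKG7": 3})
    bump("NaiveB", {"MS4A1": 4, "CD19": 3.5, "IGHD": 3.5, "SELL": 2.5,
                    "CXCR5": 3.5, "CCR7": 2})
    bump("GCB", {"MS4A1": 4, "CD19": 3.5, "BCL6": 3.5, "CD38": 3,
                 "CXCR5": 3})
    bump("MemB", {"MS4A1": 4, "CD19": 3.5, "CD27": 3.5, "CXCR5": 2.5})
    bump("Macrophage", {"CD14": 4, "LYZ": 4.5, "HLA-DRA": 3.5, "CD86": 2.5,
                        "IL6": 2, "TNF": 2, "CD274": 2.5})
    return means


#: Per-subtype cluster composition.  LR-CHL: Treg depletion (0.02 vs 0.15)
#: and naive-B enrichment; RLN: germinal-center-dominated B compartment.
DEFAULT_COMPOSITION = {
    "LR": {
        "Treg": 0.02, "TFH": 0.14, "CD4_helper": 0.26, "CD8_T": 0.10,
        "NaiveB": 0.28, "GCB": 0.04, "MemB": 0.12, "Macrophage": 0.04,
    },
    "otherCHL": {
        "Treg": 0.15, "TFH": 0.07, "CD4_helper": 0.34, "CD8_T": 0.14,
        "NaiveB": 0.10, "GCB": 0.05, "MemB": 0.11, "Macrophage": 0.04,
    },
    "RLN": {
        "Treg": 0.06, "TFH": 0.08, "CD4_helper": 0.26, "CD8_T": 0.14,
        "NaiveB": 0.18, "GCB": 0.16, "MemB": 0.09, "Macrophage": 0.03,
    },
}

#: Subtype-dependent TFH coexpression: in LR-CHL the TFH cluster expresses
#: CXCL13 without CXCR5; in RLN (and, attenuated, other CHL) the classical
#: CXCR5+PD-1+CXCL13- profile dominates.
DEFAULT_COEXPRESSION_OVERRIDES = {
    ("LR", "TFH"): {"CXCL13": 4.0, "CXCR5": 0.1, "PDCD1": 3.5,
                    "HLA-DRA": 3.0},
    ("RLN", "TFH"): {"CXCL13": 0.1, "CXCR5": 3.5, "PDCD1": 3.0},
    ("otherCHL", "TFH"): {"CXCL13": 0.5, "CXCR5": 2.5, "PDCD1": 2.5},
}


def default_expression_spec(
    n_samples_per_subtype: int = 8,
    subtypes: Sequence[str] = ("LR", "otherCHL"),
    n_cells_per_sample: int = 400,
    seed: int = 0,
    **overrides,
) -> SyntheticExpressionSpec:
    """Expression spec with the default study conditions."""
    labels = tuple(s for s in subtypes for _ in range(n_samples_per_subtype))
    kwargs = dict(
        n_cells_per_sample=n_cells_per_sample,
        subtype_labels=labels,
        cluster_means=_default_cluster_means(),
        composition_by_subtype={
            s: DEFAULT_COMPOSITION[s] for s in set(subtypes)
        },
        coexpression_overrides={
            k: v
            for k, v in DEFAULT_COEXPRESSION_OVERRIDES.items()
            if k[0] in set(subtypes)
        },
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticExpressionSpec(**kwargs)


def default_survival_spec(seed: int = 0, **overrides) -> SyntheticSurvivalSpec:
    kwargs = dict(seed=seed)
    kwargs.update(overrides)
    return SyntheticSurvivalSpec(**kwargs)


# ---------------------------------------------------------------------------
# Spatial generator
# ---------------------------------------------------------------------------


def _place_with_spacing(
    rng: np.random.Generator,
    n: int,
    width: float,
    height: float,
    min_spacing: float,
    sample_id: str,
    margin: float = 0.0,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Dart-throwing placement with a minimum pairwise spacing.

    ``margin`` keeps points away from the field boundary so structures
    planted around them stay inside the field.
    """
    if 2 * margin >= min(width, height):
        raise PlacementError(
            f"sample {sample_id!r}: margin {margin} um leaves no interior "
            f"in a {width}x{height} um field"
        )
    points: list[np.ndarray] = []
    tries = 0
    while len(points) < n:
        if tries >= max_tries:
            raise PlacementError(
                f"sample {sample_id!r}: could not place {n} HRS cells with "
                f"{min_spacing} um spacing in a {width}x{height} um field"
            )
        candidate = rng.uniform(
            (margin, margin), (width - margin, height - margin)
        )
        if all(
            np.linalg.norm(candidate - p) >= min_spacing for p in points
        ):
            points.append(candidate)
        tries += 1
    return np.asarray(points)


def _intensities(
    rng: np.random.Generator,
    phenotypes: Sequence[str],
    model: Mapping[str, tuple[float, float, float, float]],
) -> pd.DataFrame:
    """Draw per-marker intensities from the two-component log-normal model."""
    n = len(phenotypes)
    out = {}
    for marker, (mu_pos, sig_pos, mu_neg, sig_neg) in model.items():
        positive = np.array(
            [PHENOTYPE_MARKER_SIGNS[p].get(marker, False) for p in phenotypes]
        )
        mu = np.where(positive, mu_pos, mu_neg)
        sigma = np.where(positive, sig_pos, sig_neg)
        out[marker] = np.exp(rng.normal(mu, sigma, size=n))
    return pd.DataFrame(out)


def generate_spatial(
    spec: SyntheticSpatialSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort of spatial cell maps with planted rosettes.

    Returns
    -------
    cells
        Spatial cell table: ``sample_id, cell_id, x_um, y_um`` plus one
        intensity column per marker.
    truth
        Ground truth, one row per cell: ``sample_id, cell_id,
        true_phenotype, is_ring_member, parent_hrs_id, hrs_is_rosette``
        (the last two are only set for HRS cells and ring members), plus a
        ``subtype`` column per sample.
    """
    root = np.random.SeedSequence(spec.seed)
    sample_seeds = root.spawn(spec.n_samples)
    width, height = spec.field_size_um
    labels = spec.subtype_labels or tuple(
        "LR" for _ in range(spec.n_samples)
    )
    if len(labels) != spec.n_samples:
        raise ValueError("subtype_labels length must equal n_samples")
    mixture = spec.phenotype_mixture or DEFAULT_PHENOTYPE_MIXTURE
    model = spec.intensity_model or DEFAULT_INTENSITY_MODEL

    cell_frames = []
    truth_frames = []
    for s_idx, (s_seed, subtype) in enumerate(zip(sample_seeds, labels)):
        rng = np.random.default_rng(s_seed)
        sample_id = f"S{s_idx:03d}"
        phenos: list[str] = []
        xy: list[np.ndarray] = []
        ring_member: list[bool] = []
        parent: list[object] = []
        hrs_flags: list[object] = []

        # HRS cells with exclusion-zone placement.
        hrs_xy = _place_with_spacing(
            rng,
            spec.n_hrs_per_sample,
            width,
            height,
            spec.min_hrs_spacing_um,
            sample_id,
            margin=spec.ring_radius_um + 3 * spec.ring_jitter_um,
        )
        n_rosette = int(round(spec.rosette_fraction * spec.n_hrs_per_sample))
        rosette_flags = np.zeros(spec.n_hrs_per_sample, bool)
        rosette_flags[
            rng.choice(spec.n_hrs_per_sample, size=n_rosette, replace=False)
        ] = True
        hrs_ids = [f"{sample_id}_hrs{i}" for i in range(len(hrs_xy))]
        for i, p in enumerate(hrs_xy):
            phenos.append("HRS")
            xy.append(p)
            ring_member.append(False)
            parent.append(None)
            hrs_flags.append(bool(rosette_flags[i]))

        # Planted rings: ring_count cells at radius ~ N(r, jitter) truncated
        # at +-3 jitter, evenly spaced base angles with angular jitter.
        for i, p in enumerate(hrs_xy):
            if not rosette_flags[i]:
                continue
            k = spec.ring_count
            base = np.linspace(0, 2 * np.pi, k, endpoint=False)
            base = base + rng.uniform(0, 2 * np.pi)
            if spec.ring_jitter_um > 0:
                radial = np.clip(
                    rng.normal(0, spec.ring_jitter_um, k),
                    -3 * spec.ring_jitter_um,
                    3 * spec.ring_jitter_um,
                )
                angular = rng.normal(
                    0, spec.ring_jitter_um / spec.ring_radius_um, k
                )
            else:
                radial = np.zeros(k)
                angular = np.zeros(k)
            radii = spec.ring_radius_um + radial
            angles = base + angular
            ring_xy = p + np.column_stack(
                [radii * np.cos(angles), radii * np.sin(angles)]
            )
            for q in ring_xy:
                phenos.append("TFH_CXCL13")
                xy.append(q)
                ring_member.append(True)
                parent.append(hrs_ids[i])
                hrs_flags.append(None)

        # Background mixture.
        area_mm2 = (width / 1000.0) * (height / 1000.0)
        n_background = int(round(spec.background_density_per_mm2 * area_mm2))
        mix = mixture[subtype]
        names = sorted(mix)
        draws = rng.choice(
            len(names), size=n_background, p=[mix[n] for n in names]
        )
        bg_xy = rng.uniform((0, 0), (width, height), size=(n_background, 2))
        for j in range(n_background):
            phenos.append(names[draws[j]])
            xy.append(bg_xy[j])
            ring_member.append(False)
            parent.append(None)
            hrs_flags.append(None)

        coords = np.asarray(xy)
        # Coincident coordinates would make neighbor structure ambiguous.
        if len(np.unique(coords.round(9), axis=0)) != len(coords):
            raise PlacementError(
                f"sample {sample_id!r}: coincident cell coordinates"
            )

        n_cells = len(phenos)
        cell_ids = [
            hrs_ids[i] if i < len(hrs_ids) else f"{sample_id}_c{i}"
            for i in range(n_cells)
        ]
        cells = pd.DataFrame(
            {
                "sample_id": sample_id,
                "cell_id": cell_ids,
                "x_um": coords[:, 0],
                "y_um": coords[:, 1],
            }
        )
        cells = pd.concat(
            [cells, _intensities(rng, phenos, model)], axis=1
        )
        truth = pd.DataFrame(
            {
                "sample_id": sample_id,
                "cell_id": cell_ids,
                "subtype": subtype,
                "true_phenotype": phenos,
                "is_ring_member": ring_member,
                "parent_hrs_id": parent,
                "hrs_is_rosette": hrs_flags,
            }
        )
        cell_frames.append(cells)
        truth_frames.append(truth)

    return (
        pd.concat(cell_frames, ignore_index=True),
        pd.concat(truth_frames, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# Expression generator
# ---------------------------------------------------------------------------


def generate_expression(
    spec: SyntheticExpressionSpec,
) -> ad.AnnData:
    """Generate a cluster-labeled, log-normalized expression dataset.

    Cluster labels in ``.obs['cluster']`` are the generating (ground-truth)
    labels; clustering itself is outside this package's scope and labels
    are treated as inputs downstream.  Raw counts are kept in
    ``.layers['counts']``.
    """
    root = np.random.SeedSequence(spec.seed)
    sample_seeds = root.spawn(len(spec.subtype_labels))
    genes = list(spec.cluster_means.columns)
    clusters = list(spec.cluster_means.index)

    X_blocks = []
    obs_rows = []
    for s_idx, (s_seed, subtype) in enumerate(
        zip(sample_seeds, spec.subtype_labels)
    ):
        rng = np.random.default_rng(s_seed)
        sample_id = f"P{s_idx:03d}"
        comp = spec.composition_by_subtype[subtype]
        comp_clusters = sorted(comp)
        assignment = rng.choice(
            len(comp_clusters),
            size=spec.n_cells_per_sample,
            p=[comp[c] for c in comp_clusters],
        )
        counts = np.empty((spec.n_cells_per_sample, len(genes)))
        for ci, cluster in enumerate(comp_clusters):
            mask = assignment == ci
            if not mask.any():
                continue
            log2_mean = spec.cluster_means.loc[cluster].to_numpy(float).copy()
            override = spec.coexpression_overrides.get((subtype, cluster))
            if override:
                for g, v in override.items():
                    log2_mean[genes.index(g)] = v
            mu = np.maximum(2.0 ** log2_mean - 1.0, 1e-12)
            n_cells = int(mask.sum())
            if np.isinf(spec.dispersion):
                block = rng.poisson(mu, size=(n_cells, len(genes)))
            else:
                # NB via gamma-Poisson mixture: mean mu, var mu + mu^2/size.
                lam = rng.gamma(
                    spec.dispersion,
                    mu / spec.dispersion,
                    size=(n_cells, len(genes)),
                )
                block = rng.poisson(lam)
            counts[mask] = block
        for i in range(spec.n_cells_per_sample):
            obs_rows.append(
                {
                    "cell_id": f"{sample_id}_c{i}",
                    "sample_id": sample_id,
                    "subtype": subtype,
                    "cluster": comp_clusters[assignment[i]],
                }
            )
        X_blocks.append(counts)

    counts = np.vstack(X_blocks)
    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    obs.index.name = None
    adata = ad.AnnData(
        X=lognormalize(counts, spec.library_size),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes)),
    )
    adata.layers["counts"] = counts
    adata.uns["library_size"] = spec.library_size
    return adata


# ---------------------------------------------------------------------------
# Survival generator
# ---------------------------------------------------------------------------


def generate_survival(spec: SyntheticSurvivalSpec) -> pd.DataFrame:
    """Generate a cohort table with exponential event times.

    Returns one row per case: ``case_id, phenotype_high, time_years,
    event``.  ``round(group_fraction_high * n_cases)`` cases are assigned
    to the high-hazard group; times beyond ``censor_time_years`` are
    recorded as censored at the horizon.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n_high = int(round(spec.group_fraction_high * spec.n_cases))
    high = np.zeros(spec.n_cases, bool)
    high[rng.choice(spec.n_cases, size=n_high, replace=False)] = True
    hazard = np.where(high, spec.hazard_low * spec.hazard_ratio, spec.hazard_low)
    raw_times = rng.exponential(1.0 / hazard)
    event = raw_times <= spec.censor_time_years
    times = np.minimum(raw_times, spec.censor_time_years)
    return pd.DataFrame(
        {
            "case_id": [f"case{i:03d}" for i in range(spec.n_cases)],
            "phenotype_high": high,
            "time_years": times,
            "event": event,
        }
    )


def default_phenotype_defs() -> list[PhenotypeDef]:
    """The phenotype definitions matching the generator's ground truth."""
    return list(panels.DEFAULT_PHENOTYPES)
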