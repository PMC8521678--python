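"""Simulation-based calibration and planted-structure recovery checks.

These routines re-run the full analysis chain on freshly generated
synthetic cohorts and report recovery/detection rates.  They back both
the package's self-tests and the reproduction script, and are useful for
re-calibrating after changing generator or analysis defaults.

All rates are estimated over explicit seed ranges derived from a single
base seed, so results are exactly reproducible.
"""

from __future__ import annotations

import numpy as np

from . import sc, synthetic
from .cohort import logrank
from .panels import DEFAULT_LR_PAIRS, DEFAULT_PHENOTYPES
from .phenotyping import assign_phenotypes, gate_cells
from .spatial import SpatialConfig, call_rosettes, compare_between_groups
from .synthetic import (
    SyntheticSurvivalSpec,
    default_expression_spec,
    default_spatial_spec,
    generate_expression,
    generate_spatial,
    generate_survival,
)


def _seed_range(base_seed: int, n: int) -> list[int]:
    return [int(s) for s in (base_seed + np.arange(n)) % (2**31)]


def rosette_recovery_zero_noise(base_seed: int, n_samples: int = 5) -> dict:
    """Gate + phenotype + rosette-call a zero-noise cohort and compare the
    recovered rosette fraction with the planted one (exact recovery is
    expected)."""
    model = {
        m: (3.0, 0.0, 0.0, 0.0) for m in synthetic.DEFAULT_INTENSITY_MODEL
    }
    spec = default_spatial_spec(
        n_samples=n_samples,
        seed=base_seed,
        intensity_model=model,
        ring_jitter_um=0.0,
    )
    cells, truth = generate_spatial(spec)
    gated = assign_phenotypes(gate_cells(cells), DEFAULT_PHENOTYPES)
    _, per_sample = call_rosettes(gated, "HRS", "TFH_CXCL13", SpatialConfig())
    recovered = float(per_sample["rosette_fraction"].mean())
    return {
        "planted_fraction": spec.rosette_fraction,
        "recovered_fraction": recovered,
        "exact": bool(
            (per_sample["rosette_fraction"] == spec.rosette_fraction).all()
        ),
        "n_samples": n_samples,
    }


def rosette_sensitivity_specificity(
    base_seed: int, n_seeds: int = 20, n_samples: int = 3
) -> dict:
    """Rosette detection against planted ground truth under the default
    intensity noise, pooled over seeds."""
    tp = fn = tn = fp = 0
    for seed in _seed_range(base_seed, n_seeds):
        cells, truth = generate_spatial(
            default_spatial_spec(n_samples=n_samples, seed=seed)
        )
        gated = assign_phenotypes(gate_cells(cells), DEFAULT_PHENOTYPES)
        calls, _ = call_rosettes(gated, "HRS", "TFH_CXCL13", SpatialConfig())
        merged = calls.merge(
            truth[truth["true_phenotype"] == "HRS"],
            left_on=["sample_id", "hrs_cell_id"],
            right_on=["sample_id", "cell_id"],
        )
        planted = merged["hrs_is_rosette"].astype(bool).to_numpy()
        called = merged["is_rosette"].to_numpy()
        tp += int((called & planted).sum())
        fn += int((~called & planted).sum())
        tn += int((~called & ~planted).sum())
        fp += int((called & ~planted).sum())
    return {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "n_hrs_cells": tp + fn + tn + fp,
        "n_seeds": n_seeds,
    }


def logrank_type1_rate(
    base_seed: int, n_replicates: int = 1000, n_cases: int = 60,
    alpha: float = 0.05,
) -> dict:
    """Empirical rejection rate of the log-rank test under hazard ratio 1."""
    rejections = 0
    for seed in _seed_range(base_seed, n_replicates):
        df = generate_survival(
            SyntheticSurvivalSpec(n_cases=n_cases, hazard_ratio=1.0, seed=seed)
        )
        res = logrank(df["time_years"], df["event"], df["phenotype_high"])
        rejections += res.p_value < alpha
    return {
        "rate": rejections / n_replicates,
        "alpha": alpha,
        "n_replicates": n_replicates,
    }


def survival_detection_rate(
    base_seed: int, n_replicates: int = 200, n_cases: int = 60,
    hazard_ratio: float = 4.0,
) -> dict:
    """Power of the log-rank test on the planted phenotype-high split."""
    hits = 0
    for seed in _seed_range(base_seed, n_replicates):
        df = generate_survival(
            SyntheticSurvivalSpec(
                n_cases=n_cases, hazard_ratio=hazard_ratio, seed=seed
            )
        )
        res = logrank(df["time_years"], df["event"], df["phenotype_high"])
        hits += res.p_value < 0.05
    return {"rate": hits / n_replicates, "n_replicates": n_replicates}


def treg_depletion_detection_rate(
    base_seed: int, n_replicates: int = 200
) -> dict:
    """How often the planted LR-CHL Treg depletion is detected (Welch t on
    per-sample Treg proportions, p<0.05, with LR < other direction)."""
    hits = 0
    for seed in _seed_range(base_seed, n_replicates):
        adata = generate_expression(default_expression_spec(seed=seed))
        comp = sc.composition(adata)
        treg = comp[comp["cell_type"] == "Treg"].set_index("sample_id")
        res = compare_between_groups(
            treg["proportion"], treg["subtype"].to_dict()
        )
        hits += (
            res.p_value < 0.05
            and res.group_means["LR"] < res.group_means["otherCHL"]
        )
    return {"rate": hits / n_replicates, "n_replicates": n_replicates}


def interaction_rank_rate(base_seed: int, n_replicates: int = 100) -> dict:
    """How often CXCL13->CXCR5 ranks first by interaction delta among the
    built-in 20-pair ligand-receptor panel."""
    hits = 0
    for seed in _seed_range(base_seed, n_replicates):
        adata = generate_expression(default_expression_spec(seed=seed))
        res = sc.interaction_scores(
            adata,
            DEFAULT_LR_PAIRS,
            sender_clusters=["TFH", "CD4_helper"],
            receiver_clusters=["NaiveB", "GCB", "MemB"],
            condition_a=("LR",),
            condition_b=("otherCHL",),
        )
        top = res.sort_values("delta", ascending=False).iloc[0]
        hits += (top["ligand"], top["receptor"]) == ("CXCL13", "CXCR5")
    return {
        "rate": hits / n_replicates,
        "n_pairs": len(DEFAULT_LR_PAIRS),
        "n_replicates": n_replicates,
    }
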