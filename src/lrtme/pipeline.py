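"""End-to-end pipeline: simulate -> gate -> spatial -> composition /
differential expression / interactions -> survival.

Each stage reads the previous stage's outputs, can be skipped, and logs
its outputs into a machine-readable run manifest (inputs, parameters,
seed, SHA-256 of every file written).  One global seed is fanned out to
the stages through ``numpy.random.SeedSequence(seed, stage_index)``, so a
stage's randomness is reproducible even when other stages are skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__, io, panels, sc, synthetic
from .cohort import km_estimate, logrank
from .phenotyping import GatingConfig, gate_cells, assign_phenotypes
from .spatial import SpatialConfig, call_rosettes, mean_nn_distance, neighborhood_proportion

logger = logging.getLogger("lrtme")

STAGES = ("simulate", "gate", "spatial", "composition", "de", "interactions", "survival")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    output_dir: str = "lrtme_out"
    seed: int = 0
    skip: tuple[str, ...] = ()
    n_spatial_samples: int = 6
    n_expression_samples_per_subtype: int = 8
    n_cells_per_sample: int = 400
    n_survival_cases: int = 60
    spatial_config: SpatialConfig = field(default_factory=SpatialConfig)
    gating: GatingConfig | None = None
    de_q_threshold: float = 0.05
    de_lfc_threshold: float = 1.0

    def to_dict(self) -> dict:
        d = {
            "output_dir": self.output_dir,
            "seed": self.seed,
            "skip": list(self.skip),
            "n_spatial_samples": self.n_spatial_samples,
            "n_expression_samples_per_subtype": self.n_expression_samples_per_subtype,
            "n_cells_per_sample": self.n_cells_per_sample,
            "n_survival_cases": self.n_survival_cases,
            "spatial_config": self.spatial_config.to_dict(),
            "gating": self.gating.to_dict() if self.gating else None,
            "de_q_threshold": self.de_q_threshold,
            "de_lfc_threshold": self.de_lfc_threshold,
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "skip" in d:
            d["skip"] = tuple(d["skip"])
        if d.get("spatial_config") is not None:
            d["spatial_config"] = SpatialConfig.from_dict(d["spatial_config"])
        if d.get("gating") is not None:
            d["gating"] = GatingConfig.from_dict(d["gating"])
        return cls(**{k: v for k, v in d.items() if v is not None or k == "gating"})

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    idx = STAGES.index(stage)
    return int(
        np.random.SeedSequence([seed, idx]).generate_state(1, np.uint32)[0]
        % (2**31)
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline stages in dependency order.

    Returns the run manifest (also written to ``manifest.json`` in the
    output directory).  A stage failure aborts with the stage name;
    outputs of completed stages are preserved.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "lrtme",
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": {},
        "outputs": {},
    }
    # Header digests cover analysis parameters only, so identical runs
    # into different directories produce byte-identical outputs.
    params = {k: v for k, v in config.to_dict().items() if k != "output_dir"}

    def record(stage: str, files: Mapping[str, str | Path], **extra) -> None:
        manifest["stages"][stage] = {"status": "completed", **extra}
        for key, p in files.items():
            p = Path(p)
            manifest["outputs"][f"{stage}/{key}"] = {
                "path": str(p),
                "sha256": _sha256(p),
            }

    def skipped(stage: str) -> bool:
        if stage in config.skip:
            manifest["stages"][stage] = {"status": "skipped"}
            logger.info("stage %s: skipped", stage)
            return True
        return False

    cells = truth = adata = None
    try:
        # ---- simulate -------------------------------------------------
        stage = "simulate"
        if not skipped(stage):
            s = stage_seed(config.seed, stage)
            sp_spec = synthetic.default_spatial_spec(
                n_samples=config.n_spatial_samples, seed=s
            )
            cells, truth = synthetic.generate_spatial(sp_spec)
            ex_spec = synthetic.default_expression_spec(
                n_samples_per_subtype=config.n_expression_samples_per_subtype,
                n_cells_per_sample=config.n_cells_per_sample,
                seed=s + 1,
            )
            adata = synthetic.generate_expression(ex_spec)
            sv_spec = synthetic.default_survival_spec(
                n_cases=config.n_survival_cases, seed=s + 2
            )
            survival_df = synthetic.generate_survival(sv_spec)
            io.write_cell_table(cells, out / "cells.tsv", params)
            io.write_table(truth, out / "cells_truth.tsv", params)
            expr_files = io.write_expression(adata, out / "expression", params)
            io.write_table(survival_df, out / "cohort.tsv", params)
            record(
                stage,
                {
                    "cells": out / "cells.tsv",
                    "truth": out / "cells_truth.tsv",
                    "cohort": out / "cohort.tsv",
                    **{f"expression_{k}": v for k, v in expr_files.items()},
                },
            )

        # ---- gate -----------------------------------------------------
        stage = "gate"
        if not skipped(stage):
            if cells is None:
                cells = io.read_cell_table(out / "cells.tsv")
            gated = gate_cells(cells, config.gating)
            gated = assign_phenotypes(gated, panels.DEFAULT_PHENOTYPES)
            io.write_cell_table(gated, out / "cells_gated.tsv", params)
            record(stage, {"cells_gated": out / "cells_gated.tsv"})
            cells = gated

        # ---- spatial --------------------------------------------------
        stage = "spatial"
        if not skipped(stage):
            cfg = config.spatial_config
            neigh = neighborhood_proportion(cells, "HRS", "TFH_CXCL13", cfg)
            nn = mean_nn_distance(cells, "HRS", "TFH_CXCL13", cfg)
            _, rosettes = call_rosettes(cells, "HRS", "TFH_CXCL13", cfg)
            io.write_table(neigh, out / "neighborhood.tsv", params)
            io.write_table(nn, out / "nn_distance.tsv", params)
            io.write_table(rosettes, out / "rosettes.tsv", params)
            record(
                stage,
                {
                    "neighborhood": out / "neighborhood.tsv",
                    "nn_distance": out / "nn_distance.tsv",
                    "rosettes": out / "rosettes.tsv",
                },
            )

        # ---- composition ---------------------------------------------
        stage = "composition"
        if not skipped(stage):
            if adata is None:
                adata = io.read_expression(
                    out / "expression.mtx",
                    out / "expression.cells.tsv",
                    out / "expression.genes.tsv",
                )
            comp = sc.composition(adata)
            io.write_table(comp, out / "composition.tsv", params)
            ratio = sc.type_ratio(comp, "NaiveB", "GCB")
            io.write_table(ratio, out / "naiveb_gcb_ratio.tsv", params)
            record(
                stage,
                {
                    "composition": out / "composition.tsv",
                    "naiveb_gcb_ratio": out / "naiveb_gcb_ratio.tsv",
                },
            )

        # ---- differential expression ---------------------------------
        stage = "de"
        if not skipped(stage):
            tfh = (adata.obs["cluster"] == "TFH").to_numpy()
            in_lr = (adata.obs["subtype"] == "LR").to_numpy()
            de = sc.differential_expression(
                adata,
                tfh & in_lr,
                tfh & ~in_lr,
                q_threshold=config.de_q_threshold,
                lfc_threshold=config.de_lfc_threshold,
            )
            io.write_table(de, out / "de_tfh_lr_vs_other.tsv", params)
            record(stage, {"de": out / "de_tfh_lr_vs_other.tsv"})

        # ---- interactions --------------------------------------------
        stage = "interactions"
        if not skipped(stage):
            inter = sc.interaction_scores(
                adata,
                panels.DEFAULT_LR_PAIRS,
                sender_clusters=["TFH", "CD4_helper"],
                receiver_clusters=["NaiveB", "GCB", "MemB"],
                condition_a=("LR",),
                condition_b=("otherCHL", "NS", "MC"),
                seed=stage_seed(config.seed, stage),
            )
            inter = inter.sort_values("delta", ascending=False, ignore_index=True)
            io.write_table(inter, out / "interactions.tsv", params)
            record(stage, {"interactions": out / "interactions.tsv"})

        # ---- survival -------------------------------------------------
        stage = "survival"
        if not skipped(stage):
            cohort_df = pd.read_csv(out / "cohort.tsv", sep="\t", comment="#")
            high = cohort_df["phenotype_high"].astype(bool).to_numpy()
            times = cohort_df["time_years"].to_numpy(float)
            events = cohort_df["event"].astype(bool).to_numpy()
            km_frames = []
            for label, mask in (("high", high), ("low", ~high)):
                km = km_estimate(times[mask], events[mask]).to_frame()
                km.insert(0, "group", label)
                km_frames.append(km)
            io.write_table(
                pd.concat(km_frames, ignore_index=True),
                out / "km_curves.tsv",
                params,
            )
            lr = logrank(times, events, high)
            io.write_table(
                pd.DataFrame(
                    [
                        {
                            "chi_square": lr.chi_square,
                            "degrees_freedom": lr.degrees_freedom,
                            "p_value": lr.p_value,
                            # np.unique orders False before True
                            "observed_low": lr.observed[0],
                            "observed_high": lr.observed[1],
                            "expected_low": lr.expected[0],
                            "expected_high": lr.expected[1],
                        }
                    ]
                ),
                out / "logrank.tsv",
                params,
            )
            record(
                stage,
                {"km_curves": out / "km_curves.tsv", "logrank": out / "logrank.tsv"},
            )
    except Exception as exc:  # noqa: BLE001 - reported with stage context
        manifest["stages"].setdefault(stage, {})["status"] = "failed"
        manifest["stages"][stage]["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
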