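"""End-to-end orchestration: simulate -> gate -> behavior -> integrate.

A :class:`PipelineConfig` either points at existing input tables (foci,
flow, clinical CSVs) or embeds a :class:`~zfpdx.synthdata.StudyConfig`
to simulate them.  :func:`run_pipeline` executes every stage in order,
writes each artifact together with a manifest of input hashes and seeds,
and returns a :class:`StudyReport`.  Fixed seeds give hash-identical
reports.  Stage warnings (gate-product mismatches, separation, unstable
gates) are collected, never fatal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as zio
from .atlas import REGION_NAMES, RegionAtlas, default_atlas, load_atlas
from .behavior import BehaviorSummary, summarize_cohort
from .integrate import (
    build_feature_matrix, pls_da_fit, predict_outcome, variable_weights,
)
from .lsc_flow import GateResult, gate_sample, product_identity_mismatch
from .synthdata import SampleProfile, StudyConfig, SyntheticStudy, gen_study

log = logging.getLogger("zfpdx")


@dataclass
class PipelineConfig:
    """Everything a run needs; fully serializable to YAML/JSON."""

    outdir: str = "results/run"
    seed: int = 0
    # simulation (used when input paths are absent)
    study: StudyConfig | None = None
    # or existing inputs
    foci_csv: str | None = None
    embryos_csv: str | None = None
    clinical_csv: str | None = None
    flow_csvs: dict[str, dict[str, str]] = field(default_factory=dict)
    # options
    atlas_path: str | None = None
    bootstrap_reps: int = 9999
    gamma_prior: tuple[float, float] = (1.0, 1.0)
    deab_quantile: float = 0.999
    ssc_cutoff: float | None = None
    cd34_cutoff: float | None = None
    threshold_numerous: float = 1.9
    n_components: int = 2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.study is not None:
            d["study"]["profiles"] = [
                {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in p.items()}
                for p in d["study"]["profiles"]
            ]
        return d


def load_pipeline_config(path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    study = raw.pop("study", None)
    cfg = PipelineConfig(**raw)
    if study is not None:
        profiles = [SampleProfile(**{**p, "tropism_weights": np.asarray(
            p.get("tropism_weights", np.full(len(REGION_NAMES), 0.1)), dtype=float)})
            for p in study.pop("profiles")]
        cfg.study = StudyConfig(profiles=profiles, **study)
    return cfg


@dataclass
class StudyReport:
    gates: dict[str, GateResult]
    behavior: dict[str, BehaviorSummary]
    tropism_table: pd.DataFrame  # samples x regions, posterior-mean probability (%)
    integration: dict | None
    warnings: list[str]

    def to_dict(self) -> dict:
        return {
            "gates": {k: zio._jsonable(v) for k, v in self.gates.items()},
            "behavior": {k: zio.behavior_summary_to_dict(v) for k, v in self.behavior.items()},
            "tropism_table": self.tropism_table.round(6).to_dict(orient="index"),
            "integration": zio._jsonable(self.integration),
            "warnings": list(self.warnings),
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    if cfg.study is not None:
        study = gen_study(cfg.study, _atlas(cfg))
        write_study(study, outdir / "study")
        return study.cohorts, study.flow, study.clinical
    if not (cfg.foci_csv and cfg.clinical_csv and cfg.flow_csvs):
        raise ValueError("pipeline needs either a study config or foci/clinical/flow inputs")
    cohorts = {c.sample_id: c for c in zio.read_foci_csv(cfg.foci_csv, cfg.embryos_csv)}
    clinical = zio.read_clinical_csv(cfg.clinical_csv)
    flow = {}
    for sid, tubes in cfg.flow_csvs.items():
        flow[sid] = (
            zio.read_flow_csv(tubes["control"], sample_id=sid, tube="DEAB+"),
            zio.read_flow_csv(tubes["test"], sample_id=sid, tube="DEAB-"),
        )
    return cohorts, flow, clinical


def _atlas(cfg: PipelineConfig) -> RegionAtlas:
    if cfg.atlas_path is None:
        return default_atlas()
    return load_atlas(cfg.atlas_path)


def write_study(study: SyntheticStudy, outdir) -> None:
    """Persist a synthetic study: foci/embryo/clinical CSVs, one flow CSV
    per tube, and the ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    zio.write_foci_csv(list(study.cohorts.values()), outdir / "foci.csv", outdir / "embryos.csv")
    zio.write_clinical_csv(study.clinical, outdir / "clinical.csv")
    for sid, (control, test) in study.flow.items():
        zio.write_flow_csv(control, outdir / f"flow_{sid}_DEABpos.csv")
        zio.write_flow_csv(test, outdir / f"flow_{sid}_DEABneg.csv")
    zio.write_json(study.ground_truth, outdir / "ground_truth.json")


def run_pipeline(cfg: PipelineConfig) -> StudyReport:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    atlas = _atlas(cfg)
    notes: list[str] = []
    cohorts, flow, clinical = _load_inputs(cfg, outdir)

    # --- gating -----------------------------------------------------------
    gates: dict[str, GateResult] = {}
    for sid, (control, test) in sorted(flow.items()):
        try:
            g = gate_sample(
                control, test, deab_quantile=cfg.deab_quantile,
                ssc_cutoff=cfg.ssc_cutoff, cd34_cutoff=cfg.cd34_cutoff,
                threshold_numerous=cfg.threshold_numerous,
            )
        except Exception as exc:
            raise RuntimeError(f"gate stage failed for sample {sid!r}: {exc}") from exc
        log.info("gate sample=%s aldh=%.2f%% cd34=%.2f%% combined=%.2f%% pattern=%s",
                 sid, g.pct_aldh_bright_ssclow, g.pct_cd34_within,
                 g.pct_lsc_combined, g.pattern)
        notes.extend(g.warnings)
        gates[sid] = g

    # --- behavior ---------------------------------------------------------
    rng = np.random.default_rng(cfg.seed)
    behavior: dict[str, BehaviorSummary] = {}
    for sid, cohort in sorted(cohorts.items()):
        try:
            behavior[sid] = summarize_cohort(
                cohort, atlas, n_boot=cfg.bootstrap_reps,
                seed=int(rng.integers(2**31)), gamma_prior=cfg.gamma_prior,
            )
        except Exception as exc:
            raise RuntimeError(f"behavior stage failed for sample {sid!r}: {exc}") from exc
        log.info("behavior sample=%s engraftment=%.1f%%", sid, behavior[sid].engraftment_pct)

    tropism_rows = {
        sid: dict(zip(REGION_NAMES, 100.0 * b.tropism.prob_mean))
        for sid, b in behavior.items() if b.tropism is not None
    }
    tropism_table = pd.DataFrame.from_dict(tropism_rows, orient="index")

    # --- integration ------------------------------------------------------
    integration = None
    labeled = [c for c in clinical if c.remission.lower() in ("yes", "no")
               and c.sample_id in gates and c.sample_id in behavior]
    classes = {c.remission.lower() for c in labeled}
    if len(labeled) >= 3 and classes == {"yes", "no"}:
        try:
            fm = build_feature_matrix(labeled, gates, behavior)
            ncomp = min(cfg.n_components, int(np.linalg.matrix_rank(fm.X)))
            model = pls_da_fit(fm.X, fm.y, n_components=ncomp,
                               feature_names=fm.feature_names)
            weights = variable_weights(model)
            pred = predict_outcome(model, fm.X)
            integration = {
                "n_patients": len(fm.sample_ids),
                "sample_ids": fm.sample_ids,
                "n_components": ncomp,
                "explained_y_variance": model.explained_y_variance,
                "scores_component1": model.T[:, 0],
                "variable_weights": weights.to_dict(orient="records"),
                "resubstitution_accuracy": float((pred == fm.y).mean()),
                "dropped_constant_features": fm.dropped,
            }
        except Exception as exc:
            raise RuntimeError(f"integrate stage failed: {exc}") from exc
    else:
        notes.append("integration skipped: need >=3 labeled patients in both outcome classes")

    report = StudyReport(gates=gates, behavior=behavior, tropism_table=tropism_table,
                         integration=integration, warnings=notes)

    # --- artifacts --------------------------------------------------------
    zio.gate_results_to_frame(list(gates.values())).to_csv(outdir / "gates.csv", index=False)
    tropism_table.to_csv(outdir / "tropism_probabilities.csv")
    zio.write_json(report.to_dict(), outdir / "report.json")
    manifest = {
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "inputs": {
            str(p): _sha256(Path(p))
            for p in [cfg.foci_csv, cfg.embryos_csv, cfg.clinical_csv]
            if p is not None
        },
    }
    zio.write_json(manifest, outdir / "manifest.json")
    return report


def check_reference_products(gate_table: dict[str, tuple[float, float, float, str]]):
    """Audit a table of printed gate percentages: recompute each combined
    LSC % as the product of the two gate percentages and flag rows whose
    reported value disagrees beyond rounding."""
    from .lsc_flow import classify_aldh_pattern, combined_lsc_fraction

    rows = []
    for sid, (aldh, cd34, reported, pattern) in gate_table.items():
        product = combined_lsc_fraction(aldh, cd34)
        rows.append(
            dict(sample_id=sid, pct_aldh=aldh, pct_cd34_within=cd34,
                 combined_product=product, combined_reported=reported,
                 product_mismatch=product_identity_mismatch(aldh, cd34, reported),
                 pattern_call=classify_aldh_pattern(aldh), pattern_reported=pattern)
        )
    return pd.DataFrame(rows)
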