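"""End-to-end driver: simulate -> quantify -> score -> evaluate -> triage.

Mirrors the study flow: generate a TMA cohort, drop over-fixed cores at
QC, quantify the digitized subset (tabular shortcut or full image
rendering), compute per-core minimum scores, select a cutoff by ROC on a
test split, validate it on the held-out split and against the
whole-slide ground truth, and emit a triage worklist.  Every stage draws
from substreams of one run seed, so a (config, seed) pair reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .config import CohortConfig, NoiseConfig
from .evaluation import (
    EvalReport,
    auc_from_roc,
    confusion_eval,
    delong_compare,
    per_protein_sensitivity,
    random_split,
    roc_curve,
    select_cutoff,
)
from .imaging import CoreGeometry, StainModel, measure_core_image, render_core
from .scoring import apply_cutoff, score_cores
from .triage import TriageWorklist, build_worklist

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    test_fraction: float = 146.0 / 323.0
    ci_level: float = 0.95
    image_mode: bool = False
    geometry: CoreGeometry = field(default_factory=CoreGeometry)
    stain_model: StainModel = field(default_factory=StainModel)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "cohort": self.cohort.to_dict(),
                "noise": vars(self.noise),
                "test_fraction": self.test_fraction,
                "ci_level": self.ci_level,
                "image_mode": self.image_mode,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Everything one run produces."""

    counts: dict
    cohort: cohort_mod.CohortTable
    measurements: pd.DataFrame
    core_scores: pd.DataFrame
    sections_scored: pd.DataFrame
    cutoff_sis: float
    cutoff_histoscore: float
    reports: dict[str, EvalReport]
    delong: dict
    worklist: TriageWorklist
    seed: int
    config_hash: str

    def eval_json(self) -> str:
        payload = {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "counts": self.counts,
            "cutoff_sis": round(self.cutoff_sis, 4),
            "cutoff_histoscore": round(self.cutoff_histoscore, 4),
            "delong": {k: round(v, 6) for k, v in self.delong.items()},
            "reports": {k: r.to_dict() for k, r in self.reports.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        ff = "%.8g"
        self.cohort.patients.to_csv(out / "patients.csv", index=False)
        self.cohort.cores.to_csv(out / "cores.csv", index=False)
        self.cohort.sections.to_csv(out / "sections.csv", index=False, float_format=ff)
        self.measurements.to_csv(out / "measurements.csv", index=False, float_format=ff)
        self.core_scores.to_csv(out / "core_scores.csv", index=False, float_format=ff)
        for name, rep in self.reports.items():
            if rep.roc is not None:
                rep.roc.to_csv(out / f"roc_{name}.csv", index=False, float_format=ff)
        (out / "eval_report.json").write_text(self.eval_json())
        self.worklist.entries.to_csv(out / "worklist.csv", index=False, float_format=ff)
        (out / "worklist.json").write_text(
            json.dumps(self.worklist.to_dict(), indent=2, default=str)
        )
        logger.info("wrote pipeline artifacts to %s", out)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def _image_measurements(
    cohort: cohort_mod.CohortTable,
    geometry: CoreGeometry,
    model: StainModel,
    seed: int,
) -> pd.DataFrame:
    """Render each core section and quantify it (slow path; use small
    rasters for large cohorts)."""
    rows = []
    base = np.random.SeedSequence([seed, 7]).generate_state(1)[0]
    for i, sec in enumerate(cohort.sections.itertuples()):
        img = render_core(
            latent_W=float(sec.latent_W),
            latent_B=float(sec.latent_B) if sec.stained else 0.0,
            geometry=geometry,
            model=model,
            seed=int((base + i) % (2**31)),
        )
        m = measure_core_image(img, model=model, core_id=sec.core_id, protein=sec.protein)
        rows.append((m.core_id, m.protein, m.B, m.W, m.histoscore))
    return pd.DataFrame(rows, columns=["core_id", "protein", "B", "W", "histoscore"])


def run_pipeline(
    config: PipelineConfig | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full triage pipeline; optionally write all artifacts."""
    config = config or PipelineConfig()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    s_cohort, s_measure, s_quant, s_split = seeds

    full = _stage("simulate")(cohort_mod.generate_cohort)(config.cohort, s_cohort)
    qc = _stage("qc_filter")(cohort_mod.apply_qc_filter)(full)
    scored_cohort = _stage("select_quantified")(cohort_mod.select_quantified)(
        qc, config.cohort.n_quantified, s_quant
    )

    if config.image_mode:
        measurements = _stage("quantify")(_image_measurements)(
            scored_cohort, config.geometry, config.stain_model, s_measure
        )
    else:
        measurements = _stage("emit_measurements")(cohort_mod.emit_measurements)(
            scored_cohort, config.noise, s_measure
        )

    core_scores = _stage("score")(score_cores)(measurements, scored_cohort.sections)
    core_scores = core_scores.merge(
        scored_cohort.cores[["core_id", "patient_id", "tissue_type"]], on="core_id"
    )
    # Whole-slide ground truth: the patient-level status applied to
    # tumor cores; normal mucosa is always normal.
    status = scored_cohort.patients.set_index("patient_id")["mmr_status"]
    core_scores["whole_slide_call"] = np.where(
        (core_scores["tissue_type"] == "tumor")
        & (status.reindex(core_scores["patient_id"]).to_numpy() == "deficient"),
        "pathological",
        "normal",
    )

    sections_scored = measurements.merge(
        scored_cohort.sections[["core_id", "protein", "stained"]],
        on=["core_id", "protein"],
    )
    sections_scored["sis"] = sections_scored["B"] * sections_scored["W"]

    # --- evaluation ---------------------------------------------------
    test_ids, val_ids = _stage("split")(random_split)(
        core_scores["core_id"].to_numpy(), config.test_fraction, s_split
    )
    is_test = core_scores["core_id"].isin(test_ids)
    test, val = core_scores[is_test], core_scores[~is_test]

    def evaluate(frame, score_col, cutoff, dataset, truth_col, with_roc=False):
        truth = frame[truth_col].map(
            lambda c: c if c in ("pathological", "normal") else "normal"
        )
        labels = (truth == "pathological").to_numpy()
        rep = confusion_eval(
            apply_cutoff(frame, cutoff, score_col)["predicted_call"],
            truth,
            dataset=dataset,
            ground_truth=truth_col.replace("_call", ""),
            level=config.ci_level,
        )
        rep.cutoff = cutoff
        if with_roc and labels.any() and not labels.all():
            rep.roc = roc_curve(frame[score_col], labels)
            rep.auc = auc_from_roc(rep.roc)
        return rep

    reports: dict[str, EvalReport] = {}
    delong: dict[str, float] = {}
    try:
        test_labels = (test["pathologist_call"] == "pathological").to_numpy()
        roc_sis = roc_curve(test["min_sis"], test_labels)
        cutoff_sis, _ = select_cutoff(roc_sis)
        roc_h = roc_curve(test["min_histoscore"], test_labels)
        cutoff_h, _ = select_cutoff(roc_h)

        rep_test = evaluate(test, "min_sis", cutoff_sis, "test", "pathologist_call", True)
        rep_test.roc, rep_test.auc = roc_sis, auc_from_roc(roc_sis)
        reports["test_sis"] = rep_test
        reports["test_histoscore"] = evaluate(
            test, "min_histoscore", cutoff_h, "test", "pathologist_call", True
        )
        reports["validation_sis"] = evaluate(
            val, "min_sis", cutoff_sis, "validation", "pathologist_call"
        )
        reports["validation_histoscore"] = evaluate(
            val, "min_histoscore", cutoff_h, "validation", "pathologist_call"
        )
        reports["whole_sis"] = evaluate(
            core_scores, "min_sis", cutoff_sis, "whole", "whole_slide_call"
        )
        reports["whole_histoscore"] = evaluate(
            core_scores, "min_histoscore", cutoff_h, "whole", "whole_slide_call"
        )
        reports["validation_sis"].per_protein_sensitivity = per_protein_sensitivity(
            sections_scored[sections_scored["core_id"].isin(val["core_id"])],
            cutoff_sis,
        )
        auc_a, auc_b, z, p = delong_compare(
            test["min_sis"].to_numpy(), test["min_histoscore"].to_numpy(), test_labels
        )
        delong = {"auc_sis": auc_a, "auc_histoscore": auc_b, "z": z, "p": p}
    except Exception as exc:
        raise PipelineError(f"stage 'evaluate' failed: {exc}") from exc

    worklist = _stage("triage")(build_worklist)(core_scores, cutoff_sis)

    counts = {
        "n_patients": len(full.patients),
        "n_deficient": int((full.patients["mmr_status"] == "deficient").sum()),
        "n_cores_generated": len(full.cores),
        "n_cores_routine": int((full.cores["fixation_class"] == "routine").sum()),
        "n_qc_excluded": qc.n_qc_excluded,
        "n_qc_passed": len(qc.cores),
        "n_scored": len(core_scores),
        "n_test": len(test),
        "n_validation": len(val),
        "n_flagged": worklist.n_flagged,
    }
    logger.info("pipeline counts: %s", counts)

    result = PipelineResult(
        counts=counts,
        cohort=scored_cohort,
        measurements=measurements,
        core_scores=core_scores,
        sections_scored=sections_scored,
        cutoff_sis=cutoff_sis,
        cutoff_histoscore=cutoff_h,
        reports=reports,
        delong=delong,
        worklist=worklist,
        seed=seed,
        config_hash=config.config_hash(),
    )
    if outdir is not None:
        result.write(outdir)
    return result
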