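"""Model/Results facade over the detection pipeline.

``MPCaDModel`` is constructed from a cohort of patient cases;
:meth:`MPCaDModel.fit` runs the full leave-one-patient-out study and returns
an :class:`MPCaDResults` carrying stage-wise detection metrics with Wilson
confidence intervals, the patient-level decision metrics, the per-patient
detections, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .phantom import PatientCase, PhantomSpec, generate_phantom
from .pipeline import STAGES, StudyResult, run_lopo_study


class MPCaDModel:
    """Three-stage multi-scale detector for a cohort of MP-MRI cases."""

    def __init__(self, cases: list[PatientCase], config: PipelineConfig | None = None):
        if len(cases) < 2:
            raise ValueError("a LOPO study needs at least two patients")
        self.cases = cases
        self.config = config or PipelineConfig()

    @classmethod
    def from_phantom_specs(cls, specs: list[PhantomSpec],
                           config: PipelineConfig | None = None) -> "MPCaDModel":
        cfg = config or PipelineConfig()
        return cls([generate_phantom(s, cfg.derived) for s in specs], cfg)

    def fit(self, seed: int = 0) -> "MPCaDResults":
        study = run_lopo_study(self.cases, self.config, seed)
        return MPCaDResults(model=self, study=study, seed=seed)


@dataclass
class MPCaDResults:
    model: MPCaDModel
    study: StudyResult
    seed: int

    @property
    def stage_reports(self):
        return self.study.stage_reports

    @property
    def patient_report(self):
        return self.study.patient_report

    def detections(self, stage: str = "radc_crf"):
        return self.study.detections[stage]

    def metrics_frame(self):
        """Stage-wise region metrics as a tidy DataFrame."""
        import pandas as pd
        rows = []
        for stage in STAGES:
            rep = self.stage_reports[stage]
            rows.append({"stage": stage, **rep.as_dict(),
                         "sens_ci_lo": rep.sensitivity_ci[0],
                         "sens_ci_hi": rep.sensitivity_ci[1],
                         "spec_ci_lo": rep.specificity_ci[0],
                         "spec_ci_hi": rep.specificity_ci[1]})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["MPCaD leave-one-patient-out study",
                 f"  patients: {len(self.model.cases)}    seed: {self.seed}",
                 f"  selection criterion: {self.model.config.rd_fm.criterion}",
                 "",
                 "  region-level metrics (95% Wilson CI)",
                 "  stage      sens               spec               acc     TP/FP/TN/FN"]
        for stage in STAGES:
            rep = self.stage_reports[stage]
            c = rep.counts

            def fmt(v, ci):
                if np.isnan(v):
                    return "   n/a          "
                return f"{v:5.2f} [{ci[0]:4.2f} {ci[1]:4.2f}]"

            lines.append(f"  {stage:<9} {fmt(rep.sensitivity, rep.sensitivity_ci)}  "
                         f"{fmt(rep.specificity, rep.specificity_ci)}  "
                         f"{rep.accuracy:5.2f}   {c.tp}/{c.fp}/{c.tn}/{c.fn}")
        pr = self.patient_report
        k = self.model.config.evaluation.patient_k_regions
        lines += ["",
                  f"  patient-level (k = {k}): "
                  f"sens {pr.sensitivity:.2f}  spec {pr.specificity:.2f}  "
                  f"acc {pr.accuracy:.2f}  (TP/FP/TN/FN {pr.counts.tp}/{pr.counts.fp}/"
                  f"{pr.counts.tn}/{pr.counts.fn})"]
        return "\n".join(lines)

    def plot_stage_metrics(self, ax=None):
        """Bar chart of sensitivity/specificity/accuracy per stage."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        width = 0.25
        x = np.arange(len(STAGES))
        for k, metric in enumerate(("sensitivity", "specificity", "accuracy")):
            vals = [getattr(self.stage_reports[s], metric) for s in STAGES]
            ax.bar(x + (k - 1) * width, vals, width, label=metric)
        ax.set_xticks(x)
        ax.set_xticklabels(STAGES)
        ax.set_ylim(0, 1.05)
        ax.legend()
        ax.set_ylabel("rate")
        return ax
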