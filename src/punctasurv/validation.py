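"""Canned validation experiments for the synthetic assay.

Each function runs one self-contained reproduction experiment at the study's
default calibration and returns plain numbers: the classifier operating
point on a labeled validation set, the false-call rate of a diffuse-only
control cohort through the full imaging pipeline, and recovery of a planted
aggregate-bearing fraction. They are the package's reproducibility
harness: everything is generated and measured at run time from a seed.
"""

from __future__ import annotations

import numpy as np

from .aggregation import confusion_metrics, roc_curve, youden_threshold
from .config import GeneratorConfig, GroupSpec
from .pipeline import PipelineConfig, run_pipeline
from .synthetic import generate_labeled_roiset

__all__ = [
    "classifier_operating_point",
    "cohort_aggregate_fraction",
]


def classifier_operating_point(
    seed: int, n_per_class: int = 50, threshold: float = 1.0
) -> dict:
    """Calibrate the CV classifier on a synthetic labeled validation set.

    Renders ``n_per_class`` aggregated and ``n_per_class`` diffuse ROIs at
    the default calibration, computes per-ROI CVs, and reports the operating
    metrics of the ``CV >= threshold`` rule plus the ROC-derived
    Youden-optimal threshold.

    Returns a dict with sensitivity_pct, specificity_pct, youden_threshold,
    auc and n (total ROIs).
    """
    cfg = GeneratorConfig(seed=seed)
    labeled = generate_labeled_roiset(cfg, n_per_class)
    roc = roc_curve(labeled["cv"], labeled["true_label"])
    sens, spec = confusion_metrics(
        labeled["cv"] >= threshold, labeled["true_label"]
    )
    return {
        "sensitivity_pct": 100.0 * sens,
        "specificity_pct": 100.0 * spec,
        "youden_threshold": youden_threshold(roc),
        "auc": roc.auc,
        "n": len(labeled),
    }


def cohort_aggregate_fraction(
    seed: int,
    aggregate_probability: float,
    n_neurons: int,
    baseline_hazard: float = 0.03,
    aggregate_hazard_multiplier: float = 2.0,
    group_name: str = "cohort",
) -> dict:
    """Run one synthetic cohort through the full pipeline and report the
    percentage of analyzed neurons called aggregate-bearing.

    The cohort is simulated (10 timepoints, default imaging calibration),
    segmented, tracked, death-called, and classified per neuron with the
    any-live-timepoint CV >= 1.0 rule. With ``aggregate_probability = 0``
    this measures the control false-call rate; with a planted positive
    fraction it measures end-to-end recovery of that fraction.

    Returns a dict with aggregate_bearing_pct, planted_pct, n (analyzed
    neurons) and n_tracked.
    """
    cfg = PipelineConfig(
        generator=GeneratorConfig(
            seed=seed,
            n_neurons_per_group=n_neurons,
            groups=(
                GroupSpec(
                    group_name,
                    aggregate_probability=aggregate_probability,
                    baseline_hazard_per_interval=baseline_hazard,
                    aggregate_hazard_multiplier=aggregate_hazard_multiplier,
                ),
            ),
        )
    )
    report = run_pipeline(cfg)
    block = report.groups[group_name]
    return {
        "aggregate_bearing_pct": block["aggregate_bearing_pct"],
        "planted_pct": 100.0 * aggregate_probability,
        "n": block["n_analyzed"],
        "n_tracked": block["n_tracked"],
    }
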