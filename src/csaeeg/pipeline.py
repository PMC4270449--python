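"""End-to-end analysis pipeline.

One recording flows through: epoching -> amplitude-threshold artifact
rejection -> selection of the first ``n_epochs`` clean epochs -> per-epoch
FFT spectra -> regional averaging -> CSA -> descriptors -> pattern label ->
abnormality flag -> outcome prediction.  ``run_pipeline`` applies this to a
set of recordings and returns a report table plus a machine-readable
manifest echoing the effective configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import spectral
from .classify import ClassificationResult, OutcomePrediction, classify, is_abnormal, predict_outcome
from .config import PipelineConfig
from .descriptors import CSADescriptors, describe
from .io import read_recording
from .recording import EEGRecording

logger = logging.getLogger("csaeeg")


@dataclass
class SubjectReport:
    subject_id: str
    descriptors: CSADescriptors
    classification: ClassificationResult
    prediction: OutcomePrediction
    n_rejected: int
    config: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {"subject_id": self.subject_id}
        row.update(self.descriptors.as_row())
        row["pattern"] = self.classification.label.value
        row["fallback_rule"] = self.classification.fallback
        row["abnormal"] = self.prediction.abnormal
        row["predicted_group"] = self.prediction.predicted_group
        row["n_rejected"] = self.n_rejected
        return row


def analyze_recording(recording: EEGRecording, config: PipelineConfig | None = None,
                      subject_id: str = "") -> SubjectReport:
    """Full single-subject analysis of an in-memory recording."""
    config = config or PipelineConfig()
    epochs = spectral.epoch_signal(recording, config.epoch_length)
    epochs = spectral.reject_artifacts(epochs, config.artifact_limit_uv)
    n_rejected = int(epochs.artifact_flags.sum())
    selected = spectral.select_epochs(epochs, config.n_epochs)
    csa = spectral.build_csa(selected, config.region_channels,
                             region_label=config.region)
    desc = describe(csa, config.bands, config.dfv_estimator)
    result = classify(desc)
    if result.fallback:
        logger.warning("subject %s labelled by fallback rule: %s",
                       subject_id or "<anon>", result.rule_trace[-1][0])
    abnormal = is_abnormal(desc, result.label)
    pred = predict_outcome(result.label, abnormal)
    return SubjectReport(
        subject_id=subject_id or recording.meta.get("subject_id", ""),
        descriptors=desc,
        classification=result,
        prediction=pred,
        n_rejected=n_rejected,
        config=config.echo(),
    )


def run_pipeline(config: PipelineConfig, inputs) -> tuple:
    """Analyze a set of recordings (paths or EEGRecording objects).

    Returns ``(report_df, manifest)``.  Per-subject failures are logged and
    skipped; the manifest lists them and carries the effective config, so
    callers can exit non-zero when ``manifest["failures"]`` is non-empty.
    """
    inputs = list(inputs)
    if not inputs:
        raise ValueError("no input recordings")
    rows, failures = [], []
    for item in inputs:
        if isinstance(item, EEGRecording):
            rec, name = item, item.meta.get("subject_id", f"rec{len(rows)}")
        else:
            name = str(item)
            try:
                rec = read_recording(item)
            except Exception as exc:  # noqa: BLE001 - per-subject isolation
                logger.error("failed to read %s: %s", name, exc)
                failures.append({"input": name, "error": str(exc)})
                continue
        try:
            report = analyze_recording(rec, config, subject_id=name)
        except Exception as exc:  # noqa: BLE001
            logger.error("failed to analyze %s: %s", name, exc)
            failures.append({"input": name, "error": str(exc)})
            continue
        rows.append(report.as_row())
    manifest = {
        "config": config.echo(),
        "n_inputs": len(inputs),
        "n_analyzed": len(rows),
        "failures": failures,
    }
    return pd.DataFrame(rows), manifest
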