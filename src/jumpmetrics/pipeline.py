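"""Manifest-driven batch analysis: recordings -> metrics -> best trials -> 1RM.

Mirrors the study flow: analyze every listed trial, keep the highest jump
per participant and jump type, estimate 1RM from the published equations,
and (when measured 1RM values are present) report estimated-vs-measured
agreement.  Trials that fail event detection are excluded and listed in a
QC table; the run fails only if nothing survives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import AnalysisConfig
from .errors import JumpMetricsError
from .io import TrialManifest, read_force_recording, write_metrics_table
from .stats import AgreementReport, paired_comparison
from .strength import PUBLISHED_EQUATIONS, estimate_1rm_published

log = logging.getLogger("jumpmetrics")


@dataclass
class PipelineResult:
    metrics: pd.DataFrame                    # one row per analyzed trial
    best_trials: pd.DataFrame                # one row per participant x jump type
    estimates: pd.DataFrame                  # published-equation 1RM estimates
    qc: pd.DataFrame                         # excluded trials with reasons
    agreement: dict[str, AgreementReport] = field(default_factory=dict)

    @property
    def n_failed(self) -> int:
        return len(self.qc)


def run_pipeline(
    manifest: TrialManifest,
    config: AnalysisConfig | None = None,
    *,
    base_dir=None,
    out_dir=None,
) -> PipelineResult:
    """Analyze every manifest trial and assemble the study tables.

    ``base_dir`` resolves relative recording paths; when ``out_dir`` is
    given, metrics/best-trial/estimate/QC CSVs and the resolved config are
    written there.
    """
    config = config or AnalysisConfig()
    analyzer = config.analyzer()
    base = Path(base_dir) if base_dir is not None else Path(".")
    log.info("analysis thresholds: %s", config.to_dict())

    rows, qc_rows = [], []
    for entry in manifest:
        path = Path(entry["path"])
        if not path.is_absolute():
            path = base / path
        label = (entry["participant"], entry["jump_type"], entry["trial"])
        try:
            rec = read_force_recording(
                path,
                participant=str(entry["participant"]),
                jump_type=entry["jump_type"],
                trial=int(entry["trial"]),
            )
            analysis = analyzer.analyze(rec)
        except (JumpMetricsError, ValueError, OSError) as exc:
            log.warning("trial %s excluded: %s", label, exc)
            qc_rows.append(
                {
                    "participant": entry["participant"],
                    "jump_type": entry["jump_type"],
                    "trial": entry["trial"],
                    "path": str(path),
                    "reason": str(exc),
                }
            )
            continue
        row = {
            "participant": entry["participant"],
            "jump_type": entry["jump_type"],
            "trial": int(entry["trial"]),
        }
        if "measured_1rm_kg" in entry and pd.notna(entry.get("measured_1rm_kg")):
            row["measured_1rm_kg"] = float(entry["measured_1rm_kg"])
        row.update(analysis.metrics.as_row())
        rows.append(row)

    if not rows:
        raise JumpMetricsError("pipeline failed: every trial failed analysis")
    metrics = pd.DataFrame(rows)

    qc_cols = ["participant", "jump_type", "trial", "path", "reason"]
    qc = pd.DataFrame(qc_rows, columns=qc_cols)

    # best trial per participant x jump type: highest jump, earliest on ties
    best_rows = []
    for (pid, jt), grp in metrics.groupby(["participant", "jump_type"], sort=True):
        grp = grp.sort_values("trial")
        best = grp.loc[grp["jump_height_m"].idxmax()]
        best_rows.append(best)
    best = pd.DataFrame(best_rows).reset_index(drop=True)

    # published-equation estimates from the best trials
    est_rows = []
    for _, row in best.iterrows():
        eq = PUBLISHED_EQUATIONS[row["jump_type"]]
        value = row[eq["predictor"]]
        est = {
            "participant": row["participant"],
            "jump_type": row["jump_type"],
            "predictor": eq["predictor"],
            "predictor_value": value,
            "estimated_1rm_kg": estimate_1rm_published(value, row["jump_type"]),
        }
        if "measured_1rm_kg" in row and pd.notna(row.get("measured_1rm_kg")):
            est["measured_1rm_kg"] = row["measured_1rm_kg"]
        est_rows.append(est)
    estimates = pd.DataFrame(est_rows)

    agreement = {}
    if "measured_1rm_kg" in estimates.columns:
        for jt, grp in estimates.dropna(subset=["measured_1rm_kg"]).groupby("jump_type"):
            if len(grp) >= 3:
                agreement[jt] = paired_comparison(
                    grp["estimated_1rm_kg"].to_numpy(),
                    grp["measured_1rm_kg"].to_numpy(),
                )

    result = PipelineResult(
        metrics=metrics, best_trials=best, estimates=estimates, qc=qc,
        agreement=agreement,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_metrics_table(metrics.to_dict("records"), out / "trial_metrics.csv")
        best.to_csv(out / "best_trials.csv", index=False)
        estimates.to_csv(out / "estimates_1rm.csv", index=False)
        qc.to_csv(out / "qc_report.csv", index=False)
        config.write(out / "config_resolved.yaml")
    return result
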