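"""End-to-end virtual-surgery pipeline.

Stages: build the tree → tune the Windkessel resistances → transient
simulation of the stenosed and the repaired (non-stenosed) morphology →
parametric constant-flow analysis of both → metric comparison → report
files. Every stage is logged with its wall-clock timing; any failure
aborts with the stage name and cause. For a fixed configuration the run
is fully deterministic.
"""

from __future__ import annotations

import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

from .config import PipelineConfig
from .metrics import PrePostComparison
from .model import PulmonaryHemodynamicsModel, PulmonaryHemodynamicsResults
from .parametric import parametric_error_metrics

__all__ = ["run_pipeline", "write_report", "PipelineError", "PipelineResult"]

log = logging.getLogger("pulmoflow")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    log.info("stage %s: started", name)
    try:
        yield
    except Exception as exc:
        log.error("stage %s: FAILED (%s)", name, exc)
        raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    log.info("stage %s: done in %.2f s", name, time.perf_counter() - t0)


@dataclass
class PipelineResult:
    """Everything the pipeline produced, plus the paths it wrote."""

    stenosed: PulmonaryHemodynamicsResults
    repaired: PulmonaryHemodynamicsResults
    comparison: PrePostComparison
    parametric_errors: dict
    artifacts: dict[str, Path] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages and write every artifact under ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def save(key: str, filename: str, writer) -> None:
        path = out / filename
        writer(path)
        artifacts[key] = path

    with _stage("build"):
        model = PulmonaryHemodynamicsModel.from_config(config)
        save("tree", "tree.json", model.tree.to_json)
        save("waveform", "waveform.csv", model.waveform.to_csv)

    with _stage("tune+simulate stenosed"):
        tc = config.tuning
        stenosed = model.fit(
            target_flow_ratio=tc.target_flow_ratio,
            tune=tc.enabled and model.tree.stenosed_segments() != (),
            tolerance=tc.tolerance,
            tuning_mode=tc.mode,
            size_ratio_method=tc.size_ratio_method,
        )
        if stenosed.tuning_report is not None:
            save("tuning_report", "tuning_report.json", stenosed.tuning_report.to_json)
        save("solution_stenosed", "solution_stenosed.csv", stenosed.solution.to_csv)
        save("metrics_stenosed", "metrics_stenosed.json", stenosed.metrics.to_json)

    with _stage("simulate non-stenosed"):
        repaired = stenosed.virtual_surgery()
        save("tree_nonstenosed", "tree_nonstenosed.json", repaired.model.tree.to_json)
        save(
            "solution_nonstenosed", "solution_nonstenosed.csv",
            repaired.solution.to_csv,
        )
        save(
            "metrics_nonstenosed", "metrics_nonstenosed.json",
            repaired.metrics.to_json,
        )

    with _stage("parametric"):
        parametric_errors = {}
        for label, res in (("stenosed", stenosed), ("nonstenosed", repaired)):
            fit = res.parametric_fit()
            pred = res.predict_pressure_gradient(fit)
            err = parametric_error_metrics(pred, res.pressure_gradient())
            parametric_errors[label] = {
                "max_abs_error_mmHg": err.max_abs_error_mmhg,
                "mean_abs_error_mmHg": err.mean_abs_error_mmhg,
                "peak_relative_error": err.peak_relative_error,
            }
            save(f"parametric_fit_{label}", f"parametric_fit_{label}.json", fit.to_json)
            save(
                f"parametric_prediction_{label}",
                f"parametric_prediction_{label}.csv",
                pred.to_csv,
            )
        save(
            "parametric_errors", "parametric_errors.json",
            lambda p: Path(p).write_text(
                json.dumps(parametric_errors, indent=2) + "\n"
            ),
        )

    with _stage("compare+report"):
        comparison = stenosed.compare_with(repaired)
        save("comparison_json", "comparison.json", comparison.to_json)
        save("comparison_csv", "comparison.csv", comparison.to_csv)
        save("report", "report.txt", lambda p: write_report(comparison, p))

    return PipelineResult(
        stenosed=stenosed,
        repaired=repaired,
        comparison=comparison,
        parametric_errors=parametric_errors,
        artifacts=artifacts,
    )


def write_report(comparison: PrePostComparison, path: str | Path) -> None:
    """Write a human-readable pre/post summary table (deterministic format)."""
    if comparison.pre is None or comparison.post is None:  # defensive
        raise ValueError("comparison must contain both metric sets")
    lines = []
    lines.append("Virtual surgery: stenosed vs non-stenosed morphology")
    lines.append("=" * 64)
    header = (
        f"{'model':14s} {'DPG':>8s} {'peak sys PG':>12s} "
        f"{'mean PG':>9s} {'flow ratio':>11s}"
    )
    lines.append(header)
    lines.append(f"{'':14s} {'mmHg':>8s} {'mmHg':>12s} {'mmHg':>9s} {'':>11s}")
    lines.append("-" * 64)
    for label, m in (("stenosed", comparison.pre), ("non-stenosed", comparison.post)):
        lines.append(
            f"{label:14s} {m.dpg:8.2f} {m.peak_systolic_pg:12.2f} "
            f"{m.mean_pg:9.2f} {m.flow_ratio:11.2f}"
        )
    pc = comparison.percent_changes
    lines.append(
        f"{'change (%)':14s} {pc['dpg']:8.1f} {pc['peak_systolic_pg']:12.1f} "
        f"{pc['mean_pg']:9.1f} {pc['flow_ratio']:11.1f}"
    )
    lines.append("-" * 64)
    if comparison.pre.dpg_above_remodeling_threshold:
        lines.append("note: stenosed-model DPG exceeds the 7 mmHg remodeling flag")
    Path(path).write_text("\n".join(lines) + "\n")
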