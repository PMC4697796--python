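"""Machine- and human-readable run summaries.

A report bundles the numeric outputs of whichever pipeline stages ran,
cross-referenced to the files and configuration values that produced
them.  The JSON structure is validated against ``REPORT_SCHEMA`` (a
minimal required-keys/type schema checked in-process).
"""

from __future__ import annotations

import json
from typing import Any

__all__ = ["REPORT_SCHEMA", "make_report", "validate_report", "render_text_report"]

REPORT_SCHEMA: dict[str, Any] = {
    "type": "object",
    "required": ["stages", "config", "seed"],
    "properties": {
        "stages": {"type": "object"},
        "config": {"type": "object"},
        "seed": {"type": ["integer", "null"]},
    },
}


def make_report(
    stage_outputs: dict[str, dict], config: dict, seed: int | None
) -> dict:
    """Assemble the summary document from per-stage output dicts.

    Stages that produced nothing are listed as absent rather than
    failing the report.
    """
    stages: dict[str, Any] = {}
    for name in ("simulate", "nn", "cofocus", "vde", "storm"):
        if name in stage_outputs and stage_outputs[name]:
            stages[name] = stage_outputs[name]
        elif name in config:
            stages[name] = {"status": "absent"}
    report = {"stages": stages, "config": config, "seed": seed}
    validate_report(report)
    return report


def validate_report(report: dict) -> None:
    """Check the report against REPORT_SCHEMA; raises ValueError."""
    for key in REPORT_SCHEMA["required"]:
        if key not in report:
            raise ValueError(f"report is missing required key {key!r}")
    if not isinstance(report["stages"], dict):
        raise ValueError("report['stages'] must be an object")
    if not isinstance(report["config"], dict):
        raise ValueError("report['config'] must be an object")
    if report["seed"] is not None and not isinstance(report["seed"], int):
        raise ValueError("report['seed'] must be an integer or null")
    json.dumps(report)  # must be serializable


def render_text_report(report: dict) -> str:
    """Plain-text rendering of a report for terminal consumption."""
    lines = ["focipair run summary", "=" * 20]
    lines.append(f"seed: {report['seed']}")
    if not report["stages"]:
        lines.append("no stages run")
    for name, payload in report["stages"].items():
        lines.append("")
        lines.append(f"[{name}]")
        for key, value in payload.items():
            if isinstance(value, float):
                lines.append(f"  {key}: {value:.6g}")
            else:
                lines.append(f"  {key}: {value}")
    return "\n".join(lines) + "\n"
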