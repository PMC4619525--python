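"""Report serialization and structural validation of the summary JSON.

The ``compare`` summary follows the JSON Schema document shipped at
``samplesim/schemas/summary.schema.json``. :func:`validate_summary` is a
small structural checker covering the subset of JSON Schema that document
uses (required keys, types, numeric bounds, a const tag), so reports can be
validated without an external schema engine.
"""

from __future__ import annotations

import hashlib
import json
import platform
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .evaluation import METRICS, ExperimentReport

SCHEMA_TAG = "samplesim-summary-v1"


def schema_document() -> dict:
    """The published summary schema shipped with the package."""
    with resources.files("samplesim.schemas").joinpath("summary.schema.json").open() as fh:
        return json.load(fh)


def _check_stats(stats, where: str) -> None:
    for key in ("median", "mean", "centile_2.5", "centile_97.5"):
        if key not in stats:
            raise ValidationError(f"{where}: missing statistic {key!r}")
        v = stats[key]
        if not isinstance(v, (int, float)) or isinstance(v, bool) or v < 0:
            raise ValidationError(f"{where}.{key}: expected a number >= 0, got {v!r}")


def validate_summary(obj: dict) -> None:
    """Raise :class:`ValidationError` unless ``obj`` matches the summary schema."""
    if not isinstance(obj, dict):
        raise ValidationError("summary report must be a JSON object")
    for key in ("schema", "summary", "head_to_head"):
        if key not in obj:
            raise ValidationError(f"summary report: missing key {key!r}")
    if obj["schema"] != SCHEMA_TAG:
        raise ValidationError(f"summary report: schema tag must be {SCHEMA_TAG!r}")
    for scen, per_strategy in obj["summary"].items():
        for s, cell in per_strategy.items():
            where = f"summary[{scen}][{s}]"
            if "failed_replicates" not in cell or not isinstance(
                cell["failed_replicates"], int
            ):
                raise ValidationError(f"{where}: missing integer failed_replicates")
            for p, metrics in cell.items():
                if p == "failed_replicates":
                    continue
                for metric in METRICS:
                    if metric not in metrics:
                        raise ValidationError(f"{where}[{p}]: missing {metric!r}")
                    _check_stats(metrics[metric], f"{where}[{p}][{metric}]")
    for scen, per_rs in obj["head_to_head"].items():
        for rs, per_ps in per_rs.items():
            for ps, per_product in per_ps.items():
                for p, metrics in per_product.items():
                    for metric, v in metrics.items():
                        if not isinstance(v, (int, float)) or not 0 <= v <= 100:
                            raise ValidationError(
                                f"head_to_head[{scen}][{rs}][{ps}][{p}][{metric}]: "
                                f"expected a percentage, got {v!r}"
                            )


def config_hash(config: dict) -> str:
    """Stable hash of a run configuration for the run log."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_run_log(path: Path, config: dict) -> None:
    from . import __version__

    log = {
        "config": config,
        "config_hash": config_hash(config),
        "versions": {
            "samplesim": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path.write_text(json.dumps(log, indent=2, default=str) + "\n")


def round_percent(x: float) -> int:
    """Presentation rounding to whole percent (half away from zero)."""
    return int(np.floor(x + 0.5))


def format_summary_table(report: ExperimentReport) -> str:
    """Human-readable comparison table, errors rounded to whole percent."""
    lines = []
    for scen, per_strategy in report.summary.items():
        lines.append(f"Scenario {scen}")
        header = f"  {'strategy':<8}" + "".join(
            f"{p + ' ' + m[:4]:>10}"
            for m in METRICS
            for p in next(iter(per_strategy.values())).keys()
            if p != "failed_replicates"
        )
        lines.append(header)
        for s, cell in per_strategy.items():
            vals = []
            for metric in METRICS:
                for p, metrics in cell.items():
                    if p == "failed_replicates":
                        continue
                    vals.append(f"{round_percent(metrics[metric]['median']):>9}%")
            lines.append(f"  {s:<8}" + "".join(vals))
        lines.append("")
    return "\n".join(lines)
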