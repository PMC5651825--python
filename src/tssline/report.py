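"""Report assembly and small formatting helpers.

The JSON report mirrors a genome-announcement style summary table:
genome size and composition, TSS class counts, promoter motif consensus
and conservation, spacer and UTR statistics, RBS statistics and
pan-genome category counts.  ``percent`` reproduces the rounding used in
such tables (one decimal place) so published count ratios can be
re-derived exactly from their printed numerators and denominators.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional


def percent(numerator: float, denominator: float, digits: int = 1) -> float:
    """Percentage of ``numerator/denominator`` rounded to ``digits`` places."""
    if denominator == 0:
        raise ZeroDivisionError("denominator must be non-zero")
    return round(100.0 * numerator / denominator, digits)


def build_report(
    genome_summary: dict,
    class_summary: Optional[dict] = None,
    motif_summary: Optional[dict] = None,
    utr_summary: Optional[dict] = None,
    rbs_summary: Optional[dict] = None,
    pangenome_summary: Optional[dict] = None,
) -> dict:
    report: Dict[str, dict] = {"genome": genome_summary}
    if class_summary is not None:
        report["tss_classes"] = class_summary
    if motif_summary is not None:
        report["promoters"] = motif_summary
    if utr_summary is not None:
        report["utr"] = utr_summary
    if rbs_summary is not None:
        report["rbs"] = rbs_summary
    if pangenome_summary is not None:
        report["pangenome"] = pangenome_summary
    _validate_report(report)
    return report


def _validate_report(report: dict, path: str = "") -> None:
    """Fractions must be in [0,1]; counts non-negative."""
    for key, value in report.items():
        where = f"{path}.{key}" if path else key
        if isinstance(value, dict):
            _validate_report(value, where)
        elif isinstance(value, bool):
            continue
        elif isinstance(value, float):
            if ("fraction" in key or key.startswith("p_")) and not 0.0 <= value <= 1.0:
                raise ValueError(f"fraction {where}={value} outside [0,1]")
        elif isinstance(value, int):
            if ("count" in key or key.startswith("n_")) and value < 0:
                raise ValueError(f"count {where}={value} negative")


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    _validate_report(report)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return path


def _jsonable(obj):
    import numpy as np
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
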