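"""Assemble the final summary report and its printed-percentage arithmetic."""

from __future__ import annotations

import json
import logging
from decimal import ROUND_HALF_UP, Decimal

from .containers import HomeotripError

logger = logging.getLogger(__name__)


def percentage(numerator: int | float, denominator: int | float, decimals: int = 1) -> float:
    """100 * numerator / denominator with half-up rounding to ``decimals``.

    Half-up (not banker's) rounding reproduces how percentages are
    conventionally printed in reports.
    """
    if denominator == 0:
        raise HomeotripError("percentage with zero denominator")
    value = Decimal(numerator) / Decimal(denominator) * 100
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def build_report(
    presence_summary: dict | None = None,
    type_summary: dict | None = None,
    de_summary: dict | None = None,
    module_summary=None,
    triplet_member_up: int | None = None,
    parameters: dict | None = None,
) -> dict:
    """Merge stage summaries into one provenance-carrying report dict.

    Missing stages leave explicit ``None`` gaps (with a logged warning)
    rather than failing, so partial runs still produce a report.
    """
    report: dict = {"parameters": parameters or {}}
    for key, value in (
        ("presence_and_classes", presence_summary),
        ("cold_response_types", type_summary),
        ("differential_expression", de_summary),
    ):
        if value is None:
            logger.warning("report: stage %r missing", key)
        report[key] = value
    if module_summary is not None:
        report["modules"] = [
            {"module": int(m), "size": int(r["size"]), "n_up": int(r["n_up"]), "n_down": int(r["n_down"])}
            for m, r in module_summary.iterrows()
        ]
    else:
        report["modules"] = None
    if de_summary and triplet_member_up is not None and de_summary.get("n_up"):
        report["percent_up_in_triplets"] = percentage(triplet_member_up, de_summary["n_up"], 1)
    return report


def write_report(report: dict, path) -> None:
    """Serialize deterministically (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
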