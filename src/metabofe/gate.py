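"""Four-criterion biomarker gate for feed-efficiency metabolites.

A metabolite qualifies as a candidate selection biomarker when

1. it is differential between the lean (high-FE) and fat (low-FE) lines
   (VIP > 1 and P < 0.05 upstream);
2. its genetic correlation with at least one FE index (FCR or RFI) is high:
   max over the available indices of |r_g| >= 0.30 (inclusive; missing
   estimates are ignored, not treated as zero);
3. its line means run the right way: positive qualifying r_g requires a lower
   concentration in the lean line, negative r_g the reverse (equality or an
   exactly zero r_g fails, flagged as undefined);
4. its heritability is moderate to high: h2 >= 0.20 (inclusive).

The qualifying correlation of criterion 2 is the one with the larger absolute
value among the available FCR/RFI estimates (ties resolved toward FCR); its
sign drives criterion 3 and the positive/negative classification of the
candidate.  Criteria are evaluated in order but all evaluable flags are
recorded.  A user-supplied exclusion list supports the final manual
literature-function curation step; it is never computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ConfigurationError, InputError

__all__ = [
    "GateThresholds",
    "GateDecision",
    "classify_qualifying_rg",
    "check_direction",
    "apply_gate",
    "summarize_gate",
    "BiomarkerGate",
    "run_gate",
]


@dataclass(frozen=True)
class GateThresholds:
    """Inclusive thresholds for criteria 2 and 4."""

    rg_threshold: float = 0.30
    h2_threshold: float = 0.20

    def __post_init__(self):
        for name in ("rg_threshold", "h2_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")


@dataclass
class GateDecision:
    """Per-metabolite verdict with stage bookkeeping."""

    metabolite_id: str
    common_name: str = ""
    ion_mode: str = ""
    c1_differential: bool = False
    c2_rg: bool = False
    c2_status: str = "evaluated"  # or "missing" when both r_g absent
    qualifying_rg: float = math.nan
    qualifying_index: str = ""  # "FCR" or "RFI" when c2 holds
    c3_direction: bool = False
    c3_status: str = "evaluated"  # "missing" (no means) or "undefined" (rg == 0)
    c4_h2: bool = False
    c4_status: str = "evaluated"  # "missing" when h2 absent
    pass_all: bool = False


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def classify_qualifying_rg(rg_fcr, rg_rfi, thresholds: GateThresholds = GateThresholds()):
    """Criterion 2: does either |r_g| reach the threshold, and which one?

    Returns (passes, qualifying_rg, qualifying_index, status).  Missing values
    (None/NaN) are ignored; with both missing the criterion fails with status
    ``"missing"``.  Among available values the qualifying coefficient is the
    larger in absolute value, ties resolved toward FCR.
    """
    candidates = []
    if not _is_missing(rg_fcr):
        candidates.append((abs(float(rg_fcr)), "FCR", float(rg_fcr)))
    if not _is_missing(rg_rfi):
        candidates.append((abs(float(rg_rfi)), "RFI", float(rg_rfi)))
    if not candidates:
        return False, math.nan, "", "missing"
    # stable max: FCR listed first wins ties
    best = max(candidates, key=lambda c: c[0])
    passes = best[0] >= thresholds.rg_threshold
    if not passes:
        return False, math.nan, "", "evaluated"
    return True, best[2], best[1], "evaluated"


def check_direction(qualifying_rg: float, mean_lean: float, mean_fat: float):
    """Criterion 3: the lean (high-FE) line must sit on the right side.

    r_g > 0 requires mean_lean < mean_fat; r_g < 0 requires mean_lean >
    mean_fat; equality fails, and r_g == 0 exactly is an undefined-direction
    outcome (fails, flagged).  Returns (passes, status).
    """
    if _is_missing(qualifying_rg):
        return False, "missing"
    if qualifying_rg == 0:
        return False, "undefined"
    if _is_missing(mean_lean) or _is_missing(mean_fat):
        return False, "missing"
    if qualifying_rg > 0:
        return bool(mean_lean < mean_fat), "evaluated"
    return bool(mean_lean > mean_fat), "evaluated"


def apply_gate(
    metabolite_id: str,
    differential: bool,
    rg_fcr,
    rg_rfi,
    h2,
    mean_fat=None,
    mean_lean=None,
    thresholds: GateThresholds = GateThresholds(),
    common_name: str = "",
    ion_mode: str = "",
) -> GateDecision:
    """Evaluate the four criteria for one metabolite.

    All evaluable flags are recorded even when an earlier criterion fails;
    ``pass_all`` is the conjunction of the four.
    """
    decision = GateDecision(
        metabolite_id=str(metabolite_id), common_name=common_name, ion_mode=ion_mode
    )
    decision.c1_differential = bool(differential)
    passes, qrg, qindex, status = classify_qualifying_rg(rg_fcr, rg_rfi, thresholds)
    decision.c2_rg = passes
    decision.c2_status = status
    if passes:
        decision.qualifying_rg = qrg
        decision.qualifying_index = qindex
        decision.c3_direction, decision.c3_status = check_direction(qrg, mean_lean, mean_fat)
    else:
        decision.c3_direction, decision.c3_status = False, "missing"
    if _is_missing(h2):
        decision.c4_h2, decision.c4_status = False, "missing"
    else:
        decision.c4_h2 = bool(float(h2) >= thresholds.h2_threshold)
        decision.c4_status = "evaluated"
    decision.pass_all = (
        decision.c1_differential and decision.c2_rg and decision.c3_direction and decision.c4_h2
    )
    return decision


def summarize_gate(decisions) -> dict:
    """Stage counts per ion mode and overall.

    Reports the differential count, the criterion-2 pass count split by the
    sign of the qualifying correlation, the criterion-4 pass count among
    criterion-2 passers, and the full-gate pass list.
    """
    decisions = list(decisions)
    modes = sorted({d.ion_mode for d in decisions})
    out = {"per_mode": {}, "overall": {}}

    def _stage_counts(ds):
        c2 = [d for d in ds if d.c2_rg]
        return {
            "n": len(ds),
            "n_differential": sum(d.c1_differential for d in ds),
            "c2_pass": len(c2),
            "c2_positive": sum(d.qualifying_rg > 0 for d in c2),
            "c2_negative": sum(d.qualifying_rg < 0 for d in c2),
            "c4_among_c2": sum(d.c4_h2 for d in c2),
            "pass_all": sorted(d.metabolite_id for d in ds if d.pass_all),
        }

    for mode in modes:
        out["per_mode"][mode] = _stage_counts([d for d in decisions if d.ion_mode == mode])
    out["overall"] = _stage_counts(decisions)
    return out


class BiomarkerGate:
    """Table-level gate: parameters + line means -> decision frame.

    Parameters
    ----------
    thresholds : GateThresholds
    exclude : iterable, optional
        Metabolite ids to drop from the final pass list (the manual
        literature-function curation step, supplied by the user).
    """

    def __init__(self, thresholds: GateThresholds = GateThresholds(), exclude=None):
        self.thresholds = thresholds
        self.exclude = {str(e) for e in exclude} if exclude else set()

    def transform(
        self,
        parameters: pd.DataFrame,
        means: pd.DataFrame | None = None,
        differential: pd.Series | None = None,
        id_col: str = "hmdb_id",
    ) -> pd.DataFrame:
        """Evaluate the gate row-wise.

        ``parameters`` needs columns ``h2, rg_fcr, rg_rfi`` plus ``id_col``
        (optionally ``common_name`` and ``ion_mode``); ``means`` needs
        ``id_col, mean_fat, mean_lean``.  ``differential`` is a boolean series
        aligned with ``parameters`` (all True when omitted: the parameter
        table is assumed to already be the differential set).
        """
        if id_col not in parameters.columns:
            raise InputError(f"parameter table lacks id column {id_col!r}")
        if differential is not None and len(differential) != len(parameters):
            raise AlignmentError("differential flags do not align with the parameter table")
        mean_map = {}
        if means is not None:
            if id_col not in means.columns:
                raise InputError(f"means table lacks id column {id_col!r}")
            mean_map = {
                str(r[id_col]): (float(r["mean_fat"]), float(r["mean_lean"]))
                for _, r in means.iterrows()
            }
        decisions = []
        for pos, (_, row) in enumerate(parameters.iterrows()):
            mid = str(row[id_col])
            fat, lean = mean_map.get(mid, (math.nan, math.nan))
            diff = True if differential is None else bool(differential.iloc[pos])
            decision = apply_gate(
                mid,
                diff,
                row.get("rg_fcr", math.nan),
                row.get("rg_rfi", math.nan),
                row.get("h2", math.nan),
                mean_fat=fat,
                mean_lean=lean,
                thresholds=self.thresholds,
                common_name=str(row.get("common_name", "")),
                ion_mode=str(row.get("ion_mode", "")),
            )
            if decision.pass_all and mid in self.exclude:
                decision.pass_all = False
            decisions.append(decision)
        self.decisions_ = decisions
        self.summary_ = summarize_gate(decisions)
        return pd.DataFrame([vars(d) for d in decisions])


def run_gate(
    parameters: pd.DataFrame,
    means: pd.DataFrame | None = None,
    thresholds: GateThresholds = GateThresholds(),
    exclude=None,
):
    """Convenience wrapper returning (decision frame, stage-count summary)."""
    gate = BiomarkerGate(thresholds=thresholds, exclude=exclude)
    table = gate.transform(parameters, means=means)
    return table, gate.summary_


def format_summary(summary: dict) -> str:
    """Plain-text stage-count report."""
    lines = []
    for scope, counts in [("overall", summary["overall"])] + sorted(
        summary["per_mode"].items()
    ):
        lines.append(f"[{scope}]")
        lines.append(f"  metabolites:            {counts['n']}")
        lines.append(f"  differential (c1):      {counts['n_differential']}")
        lines.append(
            f"  |rg| >= threshold (c2): {counts['c2_pass']} "
            f"({counts['c2_positive']} positive, {counts['c2_negative']} negative)"
        )
        lines.append(f"  h2 pass among c2 (c4):  {counts['c4_among_c2']}")
        lines.append(f"  full-gate passes:       {len(counts['pass_all'])}")
        if counts["pass_all"]:
            lines.append("    " + ", ".join(counts["pass_all"]))
    return "\n".join(lines)
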