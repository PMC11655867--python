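"""Treatment-target vs dominant-module matching.

Each targeted therapy blocks one immune module (anti-IL-4RA/IL-13 →
Th2, anti-IL-17A and anti-IL-23 → Th17, JAK1/2 inhibition → Th1).  A
patient's profile is *matched* when the dominant module of the biopsy
equals the treatment's target module.  Dominance here uses the argmax
of the module scores: the published non-responder table bolds dominant
scores below 0.5, so the activation gate is optional (``rule="gated"``
flags such rows as weak-dominant instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError, MappingError

DEFAULT_TREATMENT_TARGETS = {
    "dupilumab": "Th2",
    "tralokinumab": "Th2",
    "secukinumab": "Th17",
    "ixekizumab": "Th17",
    "bimekizumab": "Th17",
    "tildrakizumab": "Th17",
    "guselkumab": "Th17",
    "risankizumab": "Th17",
    "ustekinumab": "Th17",
    "baricitinib": "Th1",
    "upadacitinib": "Th1",
}


class TreatmentTargetMap:
    """Case-insensitive treatment → target-module lookup.

    Unknown treatments raise :class:`MappingError`; there is no silent
    default.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None,
                 known_modules: Iterable[str] | None = None):
        source = mapping if mapping is not None else DEFAULT_TREATMENT_TARGETS
        self._map = {k.strip().lower(): v for k, v in source.items()}
        if known_modules is not None:
            bad = set(self._map.values()) - set(known_modules)
            if bad:
                raise ConfigurationError(f"targets reference unknown modules: {sorted(bad)}")

    def __contains__(self, treatment: str) -> bool:
        return treatment.strip().lower() in self._map

    def target(self, treatment: str) -> str:
        key = str(treatment).strip().lower()
        if key not in self._map:
            raise MappingError(f"unknown treatment {treatment!r}")
        return self._map[key]


def treatment_target(treatment: str, mapping: TreatmentTargetMap | None = None) -> str:
    """Target module of a treatment under the (default) map."""
    return (mapping or TreatmentTargetMap()).target(treatment)


@dataclass
class MatchResult:
    patient_id: str
    dominant: str | None
    treatment: str
    target: str
    status: str                     # "matched" | "non matched" | "indeterminate"
    weak_dominant: bool = False     # argmax score <= 0.5 under the gated rule
    response: str | None = None


def match_profile(
    scores: Mapping[str, float] | pd.Series,
    treatment: str,
    mapping: TreatmentTargetMap | None = None,
    patient_id: str = "",
    rule: str = "argmax",
    response: str | None = None,
) -> MatchResult:
    """Match one patient's module scores against the treatment target.

    The dominant module is the argmax of the provided scores; exact ties
    give status ``indeterminate``.  Under ``rule="gated"`` an argmax
    score <= 0.5 is flagged ``weak_dominant``.
    """
    if rule not in ("argmax", "gated"):
        raise ConfigurationError(f"unknown matching rule {rule!r}")
    s = pd.Series(scores, dtype=float)
    if len(s) < 2:
        raise DataError("need at least 2 module scores to determine dominance")
    if s.isna().any():
        raise DataError(f"NaN module scores for patient {patient_id!r}")
    target = (mapping or TreatmentTargetMap()).target(treatment)
    top = s.max()
    argmax = s.index[s == top]
    if len(argmax) > 1:
        return MatchResult(patient_id, None, treatment, target, "indeterminate",
                           response=response)
    dominant = str(argmax[0])
    status = "matched" if dominant == target else "non matched"
    weak = rule == "gated" and top <= 0.5
    return MatchResult(patient_id, dominant, treatment, target, status,
                       weak_dominant=weak, response=response)


def match_table(
    scores: pd.DataFrame,
    treatments: pd.Series,
    mapping: TreatmentTargetMap | None = None,
    rule: str = "argmax",
    responses: pd.Series | None = None,
) -> list[MatchResult]:
    """Match every row of a samples × modules score table."""
    results = []
    for sid in scores.index:
        resp = None if responses is None else responses.get(sid)
        results.append(
            match_profile(
                scores.loc[sid], treatments[sid], mapping,
                patient_id=str(sid), rule=rule, response=resp,
            )
        )
    return results


def cohort_match_summary(results: Iterable[MatchResult]) -> dict:
    """Matched/non-matched counts split by responder status, the observed
    response rate, and the hypothetical rate after excluding non-matched
    patients (responders among matched ÷ matched total)."""
    results = list(results)
    n = len(results)
    matched = [r for r in results if r.status == "matched"]
    non_matched = [r for r in results if r.status == "non matched"]
    is_resp = lambda r: (r.response or "").strip().lower() in ("responder", "yes", "1", "true")
    has_resp = any(r.response not in (None, "") for r in results)
    summary = {
        "n": n,
        "matched": len(matched),
        "non_matched": len(non_matched),
        "indeterminate": n - len(matched) - len(non_matched),
    }
    if has_resp:
        responders = [r for r in results if is_resp(r)]
        summary["matched_responders"] = sum(is_resp(r) for r in matched)
        summary["matched_non_responders"] = len(matched) - summary["matched_responders"]
        summary["non_matched_responders"] = sum(is_resp(r) for r in non_matched)
        summary["observed_response_rate"] = len(responders) / n if n else float("nan")
        summary["matched_only_response_rate"] = (
            summary["matched_responders"] / len(matched) if matched else float("nan")
        )
    return summary


def detect_module_switch(
    pre_scores: Mapping[str, float] | pd.Series,
    post_scores: Mapping[str, float] | pd.Series,
) -> dict:
    """Pre/post dominant modules and whether the dominant module switched."""
    pre = pd.Series(pre_scores, dtype=float).idxmax()
    post = pd.Series(post_scores, dtype=float).idxmax()
    return {"pre_dominant": str(pre), "post_dominant": str(post),
            "switched": bool(pre != post)}
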