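"""Assessment rendering: machine-readable JSON and fixed-width text reports."""

from __future__ import annotations

import json
from typing import Dict, List, Optional

from .criteria import Rulebase
from .engine import Assessment, ClauseEvidence, EvidenceBinding
from .fhx import Pedigree

__all__ = ["render", "parse_assessment"]


def _pedigree_rows(pedigree: Pedigree) -> List[Dict[str, object]]:
    rows = []
    for p in pedigree.persons():
        rows.append(
            {
                "id": p.id,
                "relation": p.relation,
                "sex": p.sex,
                "age": p.current_age,
                "cancers": [
                    f"{dx.cancer_type}@{dx.age_at_dx if dx.age_at_dx is not None else '?'}"
                    for dx in p.cancers
                ],
            }
        )
    return rows


_RECOMMEND_SENTENCE = (
    "Based on the family health history provided, a cancer genetic "
    "consultation is recommended."
)
_NO_CRITERIA_SENTENCE = (
    "No guideline criteria were met by the family health history provided."
)


def render(
    assessment: Assessment,
    fmt: str = "text",
    rulebase: Optional[Rulebase] = None,
    pedigree: Optional[Pedigree] = None,
) -> str:
    """Render an assessment as a ``json`` or ``text`` document.

    The JSON document embeds the full assessment schema (recoverable with
    :func:`parse_assessment`) plus printed criterion labels and a pedigree
    echo.  The text format is a deterministic fixed-width summary.
    """
    labels = rulebase.labels() if rulebase is not None else {}
    if fmt == "json":
        doc = assessment.to_json()
        doc["labels"] = {cid: labels.get(cid, "") for cid in assessment.met_ids}
        if pedigree is not None:
            doc["pedigree"] = _pedigree_rows(pedigree)
        doc["summary"] = _RECOMMEND_SENTENCE if assessment.recommendation else _NO_CRITERIA_SENTENCE
        return json.dumps(doc, indent=2, ensure_ascii=False) + "\n"
    if fmt != "text":
        raise ValueError(f"unknown report format {fmt!r}")

    lines: List[str] = []
    lines.append("=" * 72)
    lines.append("FHx hereditary-cancer screening report")
    lines.append("=" * 72)
    lines.append(f"Proband: {assessment.proband_id}")
    if pedigree is not None:
        lines.append("")
        lines.append(f"{'relation':<22}{'sex':<9}{'age':>4}  cancers")
        lines.append("-" * 72)
        for row in _pedigree_rows(pedigree):
            age = "" if row["age"] is None else str(row["age"])
            lines.append(
                f"{row['relation']:<22}{row['sex']:<9}{age:>4}  {', '.join(row['cancers'])}"
            )
    lines.append("")
    if assessment.met:
        lines.append(f"Criteria met ({len(assessment.met)}):")
        for b in assessment.met:
            label = labels.get(b.criterion_id, "")
            lines.append(f"  [{b.criterion_id}] {label}")
            for ce in b.clauses:
                units = ", ".join(
                    pid if key is None else f"{pid} ({key})" for pid, key in ce.units
                )
                lines.append(f"      clause {ce.clause_ref} ({b.side}): {units}")
        lines.append("")
        lines.append(_RECOMMEND_SENTENCE)
    else:
        lines.append(_NO_CRITERIA_SENTENCE)
    lines.append("")
    lines.append(
        f"rulebase {assessment.rulebase_version} | engine {assessment.engine_version}"
        f" | {assessment.timestamp}"
    )
    return "\n".join(lines) + "\n"


def parse_assessment(text: str) -> Assessment:
    """Reconstruct an :class:`Assessment` from a rendered JSON report."""
    doc = json.loads(text)
    met = []
    for b in doc["met"]:
        clauses = tuple(
            ClauseEvidence(
                ce["clause"],
                tuple((u["person"], u.get("case")) for u in ce["units"]),
            )
            for ce in b["evidence"]
        )
        met.append(EvidenceBinding(b["criterion"], b["side"], clauses))
    return Assessment(
        proband_id=doc["proband"],
        met=met,
        rulebase_version=doc["rulebase_version"],
        engine_version=doc["engine_version"],
        timestamp=doc["timestamp"],
    )
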