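"""Consensus worrisome-feature classification of cystic lesions.

Six positivity-triggering flags are modeled: main-duct involvement,
cyst size > 3 cm, mural nodules, main pancreatic duct diameter > 5 mm,
positive cytology and neoplasm-related symptoms.  Size thresholds are
strict inequalities.  Because every lesion in a resected cohort is
classifier-positive, cohort "false positive rate" is reported as the
benign (low-grade) fraction among positives.
"""

from __future__ import annotations

from dataclasses import dataclass

from .synthetic import FUKUOKA_CRITERIA, FukuokaRecord

_PCT = lambda num, den: int((100.0 * num / den) + 0.5)  # round half up


@dataclass(frozen=True)
class FukuokaResult:
    subject_id: str
    positive: bool
    triggered_criteria: frozenset[str]


def classify_fukuoka(record: FukuokaRecord) -> FukuokaResult:
    """Flag each worrisome criterion; positive iff any flag is set."""
    if record.cyst_size_cm < 0 or record.mpd_diameter_mm < 0:
        raise ValueError("sizes must be nonnegative")
    triggered = set()
    if record.main_duct_involvement:
        triggered.add("main_duct_involvement")
    if record.cyst_size_cm > 3.0:
        triggered.add("cyst_gt_3cm")
    if record.mural_nodule:
        triggered.add("mural_nodule")
    if record.mpd_diameter_mm > 5.0:
        triggered.add("mpd_gt_5mm")
    if record.positive_cytology:
        triggered.add("positive_cytology")
    if record.symptomatic:
        triggered.add("symptomatic")
    return FukuokaResult(
        subject_id=record.subject_id,
        positive=bool(triggered),
        triggered_criteria=frozenset(triggered),
    )


def fukuoka_cohort_summary(records: list[FukuokaRecord]) -> dict:
    """Cohort-level criterion counts by grade and the benign-positive rate.

    Returns a dict with:

    - ``criteria``: {criterion: {"total": (count, pct), "HG": ..., "LG": ...}}
      with percentages relative to the stratum size, rounded to integers;
    - ``n``, ``n_hg``, ``n_lg``, ``n_positive``;
    - ``benign_among_positives_pct``: 100 * (#LG positive) / (#positive)
      rounded to the nearest integer, or None when nothing is positive.
    """
    if not records:
        raise ValueError("cohort must be nonempty")
    results = {r.subject_id: classify_fukuoka(r) for r in records}
    strata = {
        "total": records,
        "HG": [r for r in records if r.grade == "HG"],
        "LG": [r for r in records if r.grade == "LG"],
    }
    criteria = {}
    for criterion in FUKUOKA_CRITERIA:
        entry = {}
        for stratum, members in strata.items():
            count = sum(
                criterion in results[r.subject_id].triggered_criteria for r in members
            )
            entry[stratum] = (count, _PCT(count, len(members)) if members else None)
        criteria[criterion] = entry
    positives = [r for r in records if results[r.subject_id].positive]
    lg_positive = sum(r.grade == "LG" for r in positives)
    return {
        "criteria": criteria,
        "n": len(records),
        "n_hg": len(strata["HG"]),
        "n_lg": len(strata["LG"]),
        "n_positive": len(positives),
        "benign_among_positives_pct": _PCT(lg_positive, len(positives))
        if positives
        else None,
    }
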