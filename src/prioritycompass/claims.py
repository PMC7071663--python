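"""ICD-10 inpatient claims aggregation and the hospitalization criterion.

The fourth prioritization criterion scores each intervention by the yearly
inpatient admissions it could plausibly prevent.  Claims records (ICD-10
diagnostic code + admission count) are aggregated into the four main NCD
disease groups — cardiovascular, cancer, diabetes, chronic respiratory —
using a fixed code->group reference map (33 codes drawn from the 200 codes
with the most admissions nationally).  The "4 diseases, 4 modifiable shared
risk factors" model then links each risk factor to the disease groups it
drives: tobacco to all four, while unhealthy diet, physical inactivity and
harmful alcohol use each link to cardiovascular disease, diabetes and
cancer (chronic respiratory disease is attributed to tobacco only).

A risk-factor intervention scores the summed admissions of its linked
groups; a clinical intervention scores its own disease group's total.
Scores are raw admission counts; normalization happens downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .catalog import Intervention, InterventionCatalog

__all__ = [
    "ClaimsError",
    "AdmissionSummary",
    "DISEASE_GROUPS",
    "RISK_FACTOR_LINKS",
    "AREA_RISK_FACTOR",
    "normalize_icd_code",
    "map_code_to_group",
    "aggregate_admissions",
    "criterion4_scores",
    "reference_disease_map",
    "reference_claims",
]

DISEASE_GROUPS = ("cardiovascular", "cancer", "diabetes", "chronic_respiratory")

#: The 4x4 model: risk factor -> disease groups it is linked to.
RISK_FACTOR_LINKS: dict[str, frozenset[str]] = {
    "tobacco": frozenset(DISEASE_GROUPS),
    "unhealthy_diet": frozenset({"cardiovascular", "diabetes", "cancer"}),
    "physical_inactivity": frozenset({"cardiovascular", "diabetes", "cancer"}),
    "harmful_alcohol": frozenset({"cardiovascular", "diabetes", "cancer"}),
}

#: Catalog area tag -> canonical risk-factor name.
AREA_RISK_FACTOR = {
    "tobacco": "tobacco",
    "diet": "unhealthy_diet",
    "physical_inactivity": "physical_inactivity",
    "alcohol": "harmful_alcohol",
}


class ClaimsError(ValueError):
    """Invalid claims input."""


def normalize_icd_code(raw: str) -> str:
    """Canonicalize an ICD-10 code: trim, uppercase, insert the dot.

    ``"I200"`` and ``"I20.0"`` both normalize to ``"I20.0"``; three-character
    codes (``"I10"``) are left as is.
    """
    text = str(raw).strip().upper()
    if not text:
        raise ClaimsError("empty ICD-10 code")
    if "." not in text and len(text) > 3:
        text = text[:3] + "." + text[3:]
    return text


def map_code_to_group(
    code: str, mapping: Optional[Mapping[str, str]] = None
) -> Optional[str]:
    """Disease group for a normalized code, or None when unmapped."""
    if mapping is None:
        mapping = reference_disease_map()
    return mapping.get(code)


@dataclass(frozen=True)
class AdmissionSummary:
    """Per-disease-group admission totals.

    Conservation holds by construction: mapped + unmapped = grand total.
    """

    by_group: dict[str, int]
    unmapped: int = 0

    @property
    def mapped_total(self) -> int:
        return sum(self.by_group.values())

    @property
    def grand_total(self) -> int:
        return self.mapped_total + self.unmapped

    def group_total(self, group: str) -> int:
        return self.by_group.get(group, 0)

    def to_dict(self) -> dict:
        return {
            "by_group": {g: self.by_group.get(g, 0) for g in DISEASE_GROUPS},
            "unmapped": self.unmapped,
            "mapped_total": self.mapped_total,
            "grand_total": self.grand_total,
        }


def _iter_records(
    records: Union[pd.DataFrame, Iterable],
) -> Iterable[tuple[str, int]]:
    if isinstance(records, pd.DataFrame):
        for _, row in records.iterrows():
            yield row["icd10_code"], row["admissions"]
        return
    for rec in records:
        if isinstance(rec, Mapping):
            yield rec["icd10_code"], rec["admissions"]
        else:
            code, n = rec
            yield code, n


def aggregate_admissions(
    records: Union[pd.DataFrame, Iterable],
    mapping: Optional[Mapping[str, str]] = None,
) -> AdmissionSummary:
    """Sum admissions per disease group.

    ``records`` is a DataFrame with columns ``icd10_code``/``admissions`` or
    an iterable of ``(code, admissions)`` pairs / mappings.  Duplicate codes
    are summed (extracts from different insurers overlap).  Codes absent
    from the map count toward the unmapped total, never toward an error;
    negative admission counts are rejected.
    """
    if mapping is None:
        mapping = reference_disease_map()
    by_group: dict[str, int] = {}
    unmapped = 0
    for code, n in _iter_records(records):
        value = float(n)
        if value != int(value):
            raise ClaimsError(f"non-integer admission count {n!r} for {code!r}")
        count = int(value)
        if count < 0:
            raise ClaimsError(f"negative admission count {n!r} for {code!r}")
        group = mapping.get(normalize_icd_code(code))
        if group is None:
            unmapped += count
        else:
            by_group[group] = by_group.get(group, 0) + count
    return AdmissionSummary(by_group=by_group, unmapped=unmapped)


def criterion4_scores(
    summary: AdmissionSummary,
    interventions: Union[InterventionCatalog, Iterable[Intervention]],
    model: Optional[Mapping[str, frozenset[str]]] = None,
) -> dict[str, int]:
    """Hospitalization-prevention score per intervention (raw admissions).

    Risk-factor interventions (areas tobacco/diet/alcohol/physical
    inactivity) score the summed admissions of the disease groups their
    risk factor links to under the 4x4 model; clinical interventions
    (disease-group areas) score their group's total.  Interventions with
    ``area="general"`` are not scoreable and are rejected.
    """
    if model is None:
        model = RISK_FACTOR_LINKS
    scores: dict[str, int] = {}
    for it in interventions:
        if it.area in AREA_RISK_FACTOR:
            factor = AREA_RISK_FACTOR[it.area]
            groups = model[factor]
            scores[it.code] = sum(summary.group_total(g) for g in groups)
        elif it.area in DISEASE_GROUPS:
            scores[it.code] = summary.group_total(it.area)
        else:
            raise ClaimsError(
                f"{it.code}: area {it.area!r} cannot be scored against the "
                "4x4 hospitalization model"
            )
    return scores


# --------------------------------------------------------------------------
# Packaged reference data
# --------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("prioritycompass.data").joinpath(name)


def reference_disease_map() -> dict[str, str]:
    """The packaged 33-code ICD-10 -> disease-group map
    (15 cardiovascular, 4 cancer, 6 diabetes, 8 chronic respiratory)."""
    with _data_path("icd10_groups.csv").open("r", encoding="utf-8") as fh:
        frame = pd.read_csv(fh, dtype=str)
    return {
        normalize_icd_code(code): group
        for code, group in zip(frame["icd10_code"], frame["group"])
    }


def reference_claims() -> pd.DataFrame:
    """Packaged national inpatient admission counts for the 33 mapped codes
    (one record per code, 2017 insurer extracts)."""
    with _data_path("inpatient_claims.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, dtype={"icd10_code": str, "admissions": int})
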