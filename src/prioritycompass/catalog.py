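"""WHO NCD intervention catalog, policy-gap labelling and prioritizable subsets.

The WHO menu of policy options for the prevention and control of
non-communicable diseases (NCDs) comprises 105 numbered items across six
objectives: 88 concrete interventions plus 17 overarching/enabling actions.
Each item is identified by a dotted code ``"o.k"`` (objective 1-6, item
index within the objective).

This module models that catalog, compares it against a national policy
mention index to label every item

* ``green``  - reflected in the national NCD action plan,
* ``blue``   - mentioned only in other national documents,
* ``red``    - mentioned nowhere (a policy gap),

and selects the quantifiable subset that enters numerical prioritization
(objective-3 risk-factor interventions and objective-4 clinical
interventions, minus the overarching actions).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "CatalogError",
    "Intervention",
    "InterventionCatalog",
    "GapReport",
    "build_catalog",
    "label_interventions",
    "gap_report",
    "filter_prioritizable",
    "parse_code",
    "who_reference_catalog",
    "iran_mention_fixture",
    "reference_exclusions",
]

CATEGORIES = ("overarching_action", "intervention")
AREAS = (
    "tobacco",
    "alcohol",
    "diet",
    "physical_inactivity",
    "cardiovascular",
    "diabetes",
    "cancer",
    "chronic_respiratory",
    "general",
)
CE_TIERS = ("best_buy", "effective_gt_100", "no_cea", "not_applicable")
LABELS = ("green", "blue", "red")
DOCUMENT_CLASSES = ("national_action_plan", "other_national_document")

#: Objectives whose items are general (non-quantifiable) policy options.
NON_QUANTIFIABLE_OBJECTIVES = frozenset({1, 2, 5, 6})

#: Expected per-objective sizes of the WHO reference catalog.
REFERENCE_OBJECTIVE_SIZES = {1: 4, 2: 4, 3: 49, 4: 38, 5: 5, 6: 5}


class CatalogError(ValueError):
    """Invalid catalog, mention or label input."""


def parse_code(code: str) -> tuple[int, int]:
    """Split a dotted item code into (objective, item index).

    Codes are kept as strings throughout (``"3.4" != "3.40"``); this is the
    only place their numeric structure is interpreted.
    """
    text = str(code).strip()
    parts = text.split(".")
    if len(parts) != 2 or not parts[0].isdigit() or not parts[1].isdigit():
        raise CatalogError(f"malformed intervention code {text!r}: expected 'o.k'")
    objective, item = int(parts[0]), int(parts[1])
    if objective < 1:
        raise CatalogError(f"malformed intervention code {text!r}: objective < 1")
    return objective, item


@dataclass(frozen=True)
class Intervention:
    """One numbered item of the WHO menu."""

    code: str
    title: str = ""
    category: str = "intervention"
    area: str = "general"
    ce_tier: str = "not_applicable"
    note: str = ""

    def __post_init__(self) -> None:
        parse_code(self.code)  # validates
        if self.category not in CATEGORIES:
            raise CatalogError(f"{self.code}: unknown category {self.category!r}")
        if self.area not in AREAS:
            raise CatalogError(f"{self.code}: unknown area {self.area!r}")
        if self.ce_tier not in CE_TIERS:
            raise CatalogError(f"{self.code}: unknown ce_tier {self.ce_tier!r}")

    @property
    def objective(self) -> int:
        return parse_code(self.code)[0]

    @property
    def sort_key(self) -> tuple[int, int]:
        return parse_code(self.code)


class InterventionCatalog(Sequence):
    """Ordered, code-unique collection of :class:`Intervention` items.

    Items are stored sorted by (objective, item index).
    """

    def __init__(self, items: Iterable[Intervention]):
        ordered = sorted(items, key=lambda it: it.sort_key)
        self._items: tuple[Intervention, ...] = tuple(ordered)
        by_code: dict[str, Intervention] = {}
        for it in self._items:
            if it.code in by_code:
                raise CatalogError(f"duplicate intervention code {it.code!r}")
            by_code[it.code] = it
        self._by_code = by_code

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self) -> Iterator[Intervention]:
        return iter(self._items)

    def __getitem__(self, key):  # code lookup or positional
        if isinstance(key, str):
            try:
                return self._by_code[key]
            except KeyError:
                raise KeyError(f"code {key!r} not in catalog") from None
        return self._items[key]

    def __contains__(self, code: object) -> bool:
        return code in self._by_code

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, InterventionCatalog) and self._items == other._items
        )

    def __repr__(self) -> str:
        return f"InterventionCatalog({len(self)} items)"

    # -- views --------------------------------------------------------------
    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(it.code for it in self._items)

    def restrict(self, objective: int) -> "InterventionCatalog":
        return InterventionCatalog(
            it for it in self._items if it.objective == objective
        )

    def drop(self, codes: Iterable[str]) -> "InterventionCatalog":
        dropped = set(codes)
        return InterventionCatalog(
            it for it in self._items if it.code not in dropped
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": [it.code for it in self._items],
                "title": [it.title for it in self._items],
                "objective": [it.objective for it in self._items],
                "category": [it.category for it in self._items],
                "area": [it.area for it in self._items],
                "ce_tier": [it.ce_tier for it in self._items],
                "note": [it.note for it in self._items],
            }
        )

    def validate_who_structure(self) -> None:
        """Assert the structural counts of the WHO reference menu.

        105 items in total (88 interventions + 17 overarching actions),
        per-objective sizes 4/4/49/38/5/5, with 9 overarching actions in
        objective 3 and 8 in objective 4.  Raises :class:`CatalogError`
        when any count deviates; arbitrary user catalogs need not satisfy
        this.
        """
        sizes = Counter(it.objective for it in self._items)
        if dict(sizes) != REFERENCE_OBJECTIVE_SIZES:
            raise CatalogError(
                f"per-objective sizes {dict(sizes)} != {REFERENCE_OBJECTIVE_SIZES}"
            )
        n_actions = Counter(
            it.objective
            for it in self._items
            if it.category == "overarching_action"
        )
        if n_actions.get(3) != 9 or n_actions.get(4) != 8:
            raise CatalogError(
                f"overarching actions per objective {dict(n_actions)}, expected 9/8"
            )
        for it in self._items:
            expect_na = (
                it.category == "overarching_action"
                or it.objective in NON_QUANTIFIABLE_OBJECTIVES
            )
            if (it.ce_tier == "not_applicable") != expect_na:
                raise CatalogError(
                    f"{it.code}: ce_tier {it.ce_tier!r} inconsistent with "
                    f"category/objective"
                )


def build_catalog(
    rows: Union[pd.DataFrame, Iterable[Mapping[str, object]]],
) -> InterventionCatalog:
    """Build a catalog from tabular records.

    ``rows`` needs at least a ``code`` column; ``title``, ``category``,
    ``area``, ``ce_tier`` and ``note`` are optional.  Codes must be unique
    and of the dotted ``"o.k"`` form; an explicit ``objective`` column, if
    present, must agree with the code.
    """
    if isinstance(rows, pd.DataFrame):
        records = rows.to_dict("records")
    else:
        records = [dict(r) for r in rows]
    items = []
    for rec in records:
        if "code" not in rec or pd.isna(rec["code"]):
            raise CatalogError("catalog row without a code")
        code = str(rec["code"]).strip()
        objective, _ = parse_code(code)
        if "objective" in rec and not pd.isna(rec["objective"]):
            stated = int(rec["objective"])
            if stated != objective:
                raise CatalogError(
                    f"{code}: stated objective {stated} != code objective {objective}"
                )

        def _get(key: str, default: str) -> str:
            val = rec.get(key, default)
            if val is None or (isinstance(val, float) and pd.isna(val)):
                return default
            text = str(val).strip()
            return text if text else default

        items.append(
            Intervention(
                code=code,
                title=_get("title", ""),
                category=_get("category", "intervention"),
                area=_get("area", "general"),
                ce_tier=_get("ce_tier", "not_applicable"),
                note=_get("note", ""),
            )
        )
    return InterventionCatalog(items)


# --------------------------------------------------------------------------
# Policy-gap labelling
# --------------------------------------------------------------------------

def label_interventions(
    catalog: InterventionCatalog,
    mentions: Union[pd.DataFrame, Iterable[Mapping[str, object]]],
) -> dict[str, str]:
    """Label every catalog item green/blue/red from a policy mention index.

    An item is ``green`` when at least one mention has document class
    ``national_action_plan``, ``blue`` when it is mentioned only in other
    national documents, and ``red`` when it is mentioned nowhere.  Green
    takes precedence over blue.

    Returns a mapping code -> label covering the whole catalog.
    """
    if isinstance(mentions, pd.DataFrame):
        records = mentions.to_dict("records")
    else:
        records = [dict(r) for r in mentions]
    labels = {code: "red" for code in catalog.codes}
    for i, rec in enumerate(records):
        code = str(rec.get("code", "")).strip()
        if code not in catalog:
            raise CatalogError(f"mention row {i}: unknown code {code!r}")
        doc_class = str(rec.get("document_class", "")).strip()
        if doc_class not in DOCUMENT_CLASSES:
            raise CatalogError(
                f"mention row {i} ({code}): unknown document class {doc_class!r}"
            )
        if doc_class == "national_action_plan":
            labels[code] = "green"
        elif labels[code] != "green":
            labels[code] = "blue"
    return labels


@dataclass(frozen=True)
class GapReport:
    """Counts of policy labels by objective and cost-effectiveness tier."""

    total: int
    by_label: dict[str, int]
    by_objective: dict[int, dict[str, int]]
    by_ce_tier: dict[str, dict[str, int]]
    red: tuple[str, ...] = field(default_factory=tuple)

    def red_count_by_ce_tier(self) -> dict[str, int]:
        return {
            tier: counts.get("red", 0) for tier, counts in self.by_ce_tier.items()
        }

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "by_label": dict(self.by_label),
            "by_objective": {
                str(k): dict(v) for k, v in sorted(self.by_objective.items())
            },
            "by_ce_tier": {k: dict(v) for k, v in self.by_ce_tier.items()},
            "red": list(self.red),
        }


def gap_report(
    labels: Mapping[str, str], catalog: InterventionCatalog
) -> GapReport:
    """Summarize a labelling: counts by label x objective x ce_tier.

    Requires exactly one label per catalog code; the red list is returned
    in catalog (code) order.
    """
    missing = [c for c in catalog.codes if c not in labels]
    if missing:
        raise CatalogError(f"missing label for codes: {missing[:5]}")
    unknown = [c for c in labels if c not in catalog]
    if unknown:
        raise CatalogError(f"label for unknown codes: {unknown[:5]}")
    by_label: Counter = Counter()
    by_objective: dict[int, Counter] = {}
    by_ce_tier: dict[str, Counter] = {}
    red = []
    for it in catalog:
        lab = labels[it.code]
        if lab not in LABELS:
            raise CatalogError(f"{it.code}: unknown label {lab!r}")
        by_label[lab] += 1
        by_objective.setdefault(it.objective, Counter())[lab] += 1
        by_ce_tier.setdefault(it.ce_tier, Counter())[lab] += 1
        if lab == "red":
            red.append(it.code)
    return GapReport(
        total=len(catalog),
        by_label=dict(by_label),
        by_objective={k: dict(v) for k, v in by_objective.items()},
        by_ce_tier={k: dict(v) for k, v in by_ce_tier.items()},
        red=tuple(red),
    )


def filter_prioritizable(
    catalog: InterventionCatalog,
    exclusions: Optional[Iterable[str]] = None,
    objective: Optional[int] = None,
) -> InterventionCatalog:
    """Drop excluded codes (default: the packaged exclusion list) and
    optionally restrict to one objective.

    With the WHO reference catalog and packaged exclusions this yields the
    40 objective-3 and 30 objective-4 interventions that enter numerical
    prioritization.  Idempotent and order-preserving.
    """
    excl = set(reference_exclusions() if exclusions is None else exclusions)
    unknown = sorted(c for c in excl if c not in catalog)
    if unknown:
        raise CatalogError(f"exclusion codes not in catalog: {unknown}")
    out = catalog.drop(excl)
    if objective is not None:
        out = out.restrict(objective)
    return out


# --------------------------------------------------------------------------
# Packaged reference data
# --------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("prioritycompass.data").joinpath(name)


def who_reference_catalog() -> InterventionCatalog:
    """The packaged 105-item WHO reference menu.

    Titles of the prioritizable interventions and of the twelve gap items
    are transcribed from the published menu; titles of the remaining
    overarching actions and general policy options, and cost-effectiveness
    tiers outside the gap list, are editorial reconstructions of the WHO
    menu (the original per-item tier table is not redistributed here).
    """
    with _data_path("who_catalog.csv").open("r", encoding="utf-8") as fh:
        frame = pd.read_csv(fh, dtype=str)
    catalog = build_catalog(frame)
    catalog.validate_who_structure()
    return catalog


def iran_mention_fixture() -> pd.DataFrame:
    """Reconstructed Iran policy mention index.

    The study's per-document mention table is unpublished; this fixture is
    a reconstruction that pins the published facts: the twelve gap items
    receive no mention, 49 interventions are mentioned in the national
    action plan, the remainder (including item 3.9, whose cost coverage was
    left open) only in other national documents.
    """
    with _data_path("iran_mentions.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, dtype=str)


def reference_exclusions() -> frozenset[str]:
    """Codes excluded from prioritization: the 9 objective-3 and 8
    objective-4 overarching actions."""
    with _data_path("exclusions.csv").open("r", encoding="utf-8") as fh:
        frame = pd.read_csv(fh, dtype=str)
    return frozenset(frame["code"].str.strip())
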