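"""Domain model for rule-based clinical guidelines.

A guideline is modelled as a catalogue of *conditions* and a list of
production rules over them.  Conditions come in two kinds:

* **clinical** conditions (diagnoses, symptoms, histories) are unknown at the
  start of a medication review and must be asked to the clinician through the
  questionnaire;
* **non-clinical** conditions (drug prescriptions, lab results) are assumed to
  be already known and coded — e.g. extracted from the prescription record.

Each rule is a conjunction of conditions that must be *present*, negated
conditions that must be *absent*, and disjunctive *unions* (at least one
member true), concluding an opaque action such as ``start(fibre)``.  A rule is
therefore a 6-element tuple

    (present_clinical, present_nonclinical,
     absent_clinical,  absent_nonclinical,
     unions = [(clinical, nonclinical), ...],
     action)

Terminology codes (ICD10/ATC/LOINC) attached to conditions are opaque display
metadata: rule evaluation matches condition ids only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Iterator, Mapping

import yaml

__all__ = [
    "DEFAULT_CATEGORIES",
    "Condition",
    "UnionGroup",
    "Premise",
    "ClinicalRule",
    "RuleBase",
    "RuleBaseError",
    "MalformedDocumentError",
    "UnknownConditionError",
    "KindMismatchError",
    "DuplicateRoleError",
    "EmptyPremiseError",
    "parse_rulebase",
    "serialize_rulebase",
    "load_rulebase",
    "save_rulebase",
]

#: Default anatomical/etiological grouping of checkboxes on the questionnaire.
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "cardiology",
    "vascular",
    "pulmonology",
    "neurology",
    "psychiatry",
    "digestive system",
    "urogenital",
    "endocrinology",
    "rheumatology",
    "infectious diseases",
    "hematology",
    "sensory organs",
    "general",
)

CLINICAL = "clinical"
NONCLINICAL = "nonclinical"


class RuleBaseError(ValueError):
    """Base class for rule-base validation failures.

    Carries the offending rule id (when applicable) and a document path so
    errors can be reported precisely.
    """

    def __init__(self, message: str, *, rule_id: str | None = None, path: str = ""):
        self.rule_id = rule_id
        self.path = path
        prefix = f"[rule {rule_id}] " if rule_id else ""
        suffix = f" (at {path})" if path else ""
        super().__init__(f"{prefix}{message}{suffix}")


class MalformedDocumentError(RuleBaseError):
    """The document does not conform to the rule-base schema."""


class UnknownConditionError(RuleBaseError):
    """A rule references a condition id absent from the catalogue."""


class KindMismatchError(RuleBaseError):
    """A clinical id appears in a non-clinical slot, or vice versa."""


class DuplicateRoleError(RuleBaseError):
    """The same condition id appears in more than one role of a rule."""


class EmptyPremiseError(RuleBaseError):
    """A rule has no premise at all, or a union with no members."""


@dataclass(frozen=True)
class Condition:
    """A catalogue entry: one clinical or non-clinical condition.

    ``codes`` is an ordered list of terminology code strings (ICD10 for
    clinical conditions, ATC for drugs, LOINC for labs); ``default_code``
    indexes the most general term, pre-selected in the questionnaire's
    drop-down when a box is checked.
    """

    id: str
    kind: str
    label: str = ""
    category: str = "general"
    codes: tuple[str, ...] = ()
    default_code: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (CLINICAL, NONCLINICAL):
            raise MalformedDocumentError(
                f"condition {self.id!r}: kind must be 'clinical' or 'nonclinical', "
                f"got {self.kind!r}"
            )
        if self.codes and not (0 <= self.default_code < len(self.codes)):
            raise MalformedDocumentError(
                f"condition {self.id!r}: default_code {self.default_code} out of "
                f"range for {len(self.codes)} codes"
            )


@dataclass(frozen=True)
class UnionGroup:
    """One disjunctive union: at least one member (clinical or not) must be true."""

    clinical: frozenset[str] = frozenset()
    nonclinical: frozenset[str] = frozenset()

    def __bool__(self) -> bool:
        return bool(self.clinical or self.nonclinical)


@dataclass(frozen=True)
class Premise:
    """The six premise slots shared by clinical rules and display rules.

    Unions are identified by their index in ``unions``; two unions of one rule
    may in principle carry equal member sets and remain distinct.
    """

    present_clinical: frozenset[str] = frozenset()
    present_nonclinical: frozenset[str] = frozenset()
    absent_clinical: frozenset[str] = frozenset()
    absent_nonclinical: frozenset[str] = frozenset()
    unions: tuple[UnionGroup, ...] = ()

    def is_empty(self) -> bool:
        return not (
            self.present_clinical
            or self.present_nonclinical
            or self.absent_clinical
            or self.absent_nonclinical
            or self.unions
        )

    def referenced_ids(self) -> Iterator[str]:
        yield from self.present_clinical
        yield from self.present_nonclinical
        yield from self.absent_clinical
        yield from self.absent_nonclinical
        for u in self.unions:
            yield from u.clinical
            yield from u.nonclinical

    def clinical_ids(self) -> set[str]:
        out = set(self.present_clinical) | set(self.absent_clinical)
        for u in self.unions:
            out |= u.clinical
        return out


@dataclass(frozen=True)
class ClinicalRule:
    """A guideline recommendation as a 6-element tuple premise -> action."""

    id: str
    premise: Premise
    action: str = ""

    # convenience pass-throughs to the tuple slots
    @property
    def present_clinical(self) -> frozenset[str]:
        return self.premise.present_clinical

    @property
    def present_nonclinical(self) -> frozenset[str]:
        return self.premise.present_nonclinical

    @property
    def absent_clinical(self) -> frozenset[str]:
        return self.premise.absent_clinical

    @property
    def absent_nonclinical(self) -> frozenset[str]:
        return self.premise.absent_nonclinical

    @property
    def unions(self) -> tuple[UnionGroup, ...]:
        return self.premise.unions


@dataclass(frozen=True)
class RuleBase:
    """A condition catalogue plus a list of validated clinical rules."""

    catalogue: tuple[Condition, ...] = ()
    rules: tuple[ClinicalRule, ...] = ()

    @property
    def n(self) -> int:
        """Number of clinical conditions in the catalogue."""
        return sum(1 for c in self.catalogue if c.kind == CLINICAL)

    @property
    def m(self) -> int:
        """Number of clinical rules."""
        return len(self.rules)

    @property
    def conditions_by_id(self) -> dict[str, Condition]:
        return {c.id: c for c in self.catalogue}

    @property
    def clinical_ids(self) -> tuple[str, ...]:
        """Clinical condition ids in catalogue declaration order."""
        return tuple(c.id for c in self.catalogue if c.kind == CLINICAL)

    @property
    def nonclinical_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.catalogue if c.kind == NONCLINICAL)

    def rule(self, rule_id: str) -> ClinicalRule:
        for r in self.rules:
            if r.id == rule_id:
                return r
        raise KeyError(rule_id)


# ---------------------------------------------------------------------------
# Parsing / validation


def _require(cond: bool, exc: type[RuleBaseError], msg: str, **kw: Any) -> None:
    if not cond:
        raise exc(msg, **kw)


def _parse_id_list(raw: Any, path: str, rule_id: str) -> list[str]:
    _require(
        isinstance(raw, (list, tuple)),
        MalformedDocumentError,
        f"expected a list of condition ids, got {type(raw).__name__}",
        rule_id=rule_id,
        path=path,
    )
    out: list[str] = []
    for i, item in enumerate(raw):
        _require(
            isinstance(item, str) and item != "",
            MalformedDocumentError,
            "condition ids must be non-empty strings",
            rule_id=rule_id,
            path=f"{path}[{i}]",
        )
        out.append(item)
    return out


def _check_refs(
    ids: Iterable[str],
    expected_kind: str,
    by_id: Mapping[str, Condition],
    rule_id: str,
    path: str,
) -> frozenset[str]:
    """Resolve a premise slot: every id must exist and have the right kind."""
    out = set()
    for cid in ids:
        cond = by_id.get(cid)
        _require(
            cond is not None,
            UnknownConditionError,
            f"unknown condition {cid!r}",
            rule_id=rule_id,
            path=path,
        )
        _require(
            cond.kind == expected_kind,
            KindMismatchError,
            f"condition {cid!r} is {cond.kind} but appears in a {expected_kind} slot",
            rule_id=rule_id,
            path=path,
        )
        out.add(cid)
    return frozenset(out)


def _parse_condition(entry: Any, idx: int) -> Condition:
    path = f"conditions[{idx}]"
    _require(
        isinstance(entry, Mapping),
        MalformedDocumentError,
        "condition entry must be a mapping",
        path=path,
    )
    unknown = set(entry) - {"id", "kind", "label", "category", "codes", "default_code"}
    _require(
        not unknown,
        MalformedDocumentError,
        f"unknown keys {sorted(unknown)}",
        path=path,
    )
    _require(
        isinstance(entry.get("id"), str) and entry["id"] != "",
        MalformedDocumentError,
        "condition id must be a non-empty string",
        path=path,
    )
    codes = entry.get("codes", [])
    _require(
        isinstance(codes, (list, tuple)) and all(isinstance(c, str) for c in codes),
        MalformedDocumentError,
        "codes must be a list of strings",
        path=f"{path}.codes",
    )
    return Condition(
        id=entry["id"],
        kind=entry.get("kind", CLINICAL),
        label=entry.get("label", ""),
        category=entry.get("category", "general"),
        codes=tuple(codes),
        default_code=int(entry.get("default_code", 0)),
    )


_RULE_KEYS = {
    "id",
    "present_clinical",
    "present_nonclinical",
    "absent_clinical",
    "absent_nonclinical",
    "unions",
    "action",
}


def _parse_rule(entry: Any, idx: int, by_id: Mapping[str, Condition]) -> ClinicalRule:
    path = f"rules[{idx}]"
    _require(
        isinstance(entry, Mapping),
        MalformedDocumentError,
        "rule entry must be a mapping",
        path=path,
    )
    _require(
        isinstance(entry.get("id"), str) and entry["id"] != "",
        MalformedDocumentError,
        "rule id must be a non-empty string",
        path=path,
    )
    rid = entry["id"]
    unknown = set(entry) - _RULE_KEYS
    _require(
        not unknown,
        MalformedDocumentError,
        f"unknown keys {sorted(unknown)}",
        rule_id=rid,
        path=path,
    )

    slots: dict[str, frozenset[str]] = {}
    for key, kind in (
        ("present_clinical", CLINICAL),
        ("present_nonclinical", NONCLINICAL),
        ("absent_clinical", CLINICAL),
        ("absent_nonclinical", NONCLINICAL),
    ):
        ids = _parse_id_list(entry.get(key, []), f"{path}.{key}", rid)
        slots[key] = _check_refs(ids, kind, by_id, rid, f"{path}.{key}")

    unions: list[UnionGroup] = []
    raw_unions = entry.get("unions", [])
    _require(
        isinstance(raw_unions, (list, tuple)),
        MalformedDocumentError,
        "unions must be a list",
        rule_id=rid,
        path=f"{path}.unions",
    )
    for k, u in enumerate(raw_unions):
        upath = f"{path}.unions[{k}]"
        _require(
            isinstance(u, Mapping) and not (set(u) - {"clinical", "nonclinical"}),
            MalformedDocumentError,
            "union must be a mapping with keys 'clinical'/'nonclinical'",
            rule_id=rid,
            path=upath,
        )
        uc = _check_refs(
            _parse_id_list(u.get("clinical", []), f"{upath}.clinical", rid),
            CLINICAL,
            by_id,
            rid,
            f"{upath}.clinical",
        )
        ud = _check_refs(
            _parse_id_list(u.get("nonclinical", []), f"{upath}.nonclinical", rid),
            NONCLINICAL,
            by_id,
            rid,
            f"{upath}.nonclinical",
        )
        _require(
            bool(uc or ud),
            EmptyPremiseError,
            "union has no members",
            rule_id=rid,
            path=upath,
        )
        unions.append(UnionGroup(uc, ud))

    # no id may occupy two roles of the same rule (each union is its own role)
    seen: set[str] = set()
    roles: list[frozenset[str]] = list(slots.values()) + [
        u.clinical | u.nonclinical for u in unions
    ]
    for role in roles:
        dup = seen & role
        _require(
            not dup,
            DuplicateRoleError,
            f"condition(s) {sorted(dup)} appear in more than one role",
            rule_id=rid,
            path=path,
        )
        seen |= role

    premise = Premise(
        present_clinical=slots["present_clinical"],
        present_nonclinical=slots["present_nonclinical"],
        absent_clinical=slots["absent_clinical"],
        absent_nonclinical=slots["absent_nonclinical"],
        unions=tuple(unions),
    )
    _require(
        not premise.is_empty(),
        EmptyPremiseError,
        "rule has an empty premise",
        rule_id=rid,
        path=path,
    )
    return ClinicalRule(id=rid, premise=premise, action=str(entry.get("action", "")))


def parse_rulebase(doc: Mapping[str, Any] | str) -> RuleBase:
    """Parse and validate a rule-base document.

    ``doc`` is either an already-loaded mapping or a YAML/JSON text with
    top-level keys ``conditions`` and ``rules``.  Premise sets are
    de-duplicated; union order is preserved as written.  Raises a subclass of
    :class:`RuleBaseError` identifying the offending rule and document path.
    """
    if isinstance(doc, str):
        try:
            doc = yaml.safe_load(doc)
        except yaml.YAMLError as e:
            raise MalformedDocumentError(f"unparseable document: {e}") from e
    _require(
        isinstance(doc, Mapping),
        MalformedDocumentError,
        "document root must be a mapping",
    )
    unknown = set(doc) - {"conditions", "rules"}
    _require(
        not unknown,
        MalformedDocumentError,
        f"unknown top-level keys {sorted(unknown)}",
    )
    raw_conditions = doc.get("conditions", [])
    raw_rules = doc.get("rules", [])
    _require(
        isinstance(raw_conditions, (list, tuple)),
        MalformedDocumentError,
        "'conditions' must be a list",
        path="conditions",
    )
    _require(
        isinstance(raw_rules, (list, tuple)),
        MalformedDocumentError,
        "'rules' must be a list",
        path="rules",
    )

    catalogue = tuple(_parse_condition(e, i) for i, e in enumerate(raw_conditions))
    by_id: dict[str, Condition] = {}
    for i, c in enumerate(catalogue):
        _require(
            c.id not in by_id,
            MalformedDocumentError,
            f"duplicate condition id {c.id!r}",
            path=f"conditions[{i}]",
        )
        by_id[c.id] = c

    rules = []
    rule_ids: set[str] = set()
    for i, e in enumerate(raw_rules):
        rule = _parse_rule(e, i, by_id)
        _require(
            rule.id not in rule_ids,
            MalformedDocumentError,
            f"duplicate rule id {rule.id!r}",
            path=f"rules[{i}]",
        )
        rule_ids.add(rule.id)
        rules.append(rule)

    return RuleBase(catalogue=catalogue, rules=tuple(rules))


# ---------------------------------------------------------------------------
# Serialization


def _sorted(ids: frozenset[str]) -> list[str]:
    return sorted(ids)


def serialize_rulebase(rb: RuleBase) -> dict[str, Any]:
    """Serialize to the document dialect accepted by :func:`parse_rulebase`.

    Round-trip identity holds up to set ordering: sets are written sorted.
    """
    conditions = []
    for c in rb.catalogue:
        entry: dict[str, Any] = {"id": c.id, "kind": c.kind}
        if c.label:
            entry["label"] = c.label
        if c.category != "general":
            entry["category"] = c.category
        if c.codes:
            entry["codes"] = list(c.codes)
            entry["default_code"] = c.default_code
        conditions.append(entry)
    rules = []
    for r in rb.rules:
        entry = {"id": r.id}
        for key in (
            "present_clinical",
            "present_nonclinical",
            "absent_clinical",
            "absent_nonclinical",
        ):
            ids = getattr(r, key)
            if ids:
                entry[key] = _sorted(ids)
        if r.unions:
            entry["unions"] = [
                {
                    **({"clinical": _sorted(u.clinical)} if u.clinical else {}),
                    **({"nonclinical": _sorted(u.nonclinical)} if u.nonclinical else {}),
                }
                for u in r.unions
            ]
        if r.action:
            entry["action"] = r.action
        rules.append(entry)
    return {"conditions": conditions, "rules": rules}


def load_rulebase(path: str | Path) -> RuleBase:
    """Read a rule base from a YAML or JSON file."""
    text = Path(path).read_text()
    return parse_rulebase(text)


def save_rulebase(rb: RuleBase, path: str | Path) -> None:
    """Write a rule base to ``path``; format chosen by extension (.json else YAML)."""
    doc = serialize_rulebase(rb)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
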