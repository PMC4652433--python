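"""Lifetime-risk rule engine: pedigree → one of four familial CRC risk categories.

The engine encodes New-Zealand-guideline-style familial colorectal cancer
criteria.  The published guideline text is not reproduced verbatim here; the
default :class:`RuleTable` is a reconstruction of the standard criteria
family (one later-onset first-degree relative → slightly increased; an
early-onset or a second first-degree relative → moderately increased;
same-side clusters, early onset, polyposis or Lynch-spectrum signals →
potentially high) and every threshold is config-overridable.

Rule identifiers are fixed:

========  ====================  =============================================
rule id   category              trigger
========  ====================  =============================================
R1        slightly_increased    exactly one affected FDR, diagnosed at or
                                after the primary age cutoff (55), and no
                                higher rule fires
R2a       moderately_increased  any affected FDR diagnosed before the
                                primary cutoff
R2b       moderately_increased  two or more affected FDR
R3a       potentially_high      Amsterdam-style same-side cluster: >=3
                                affected FDR/SDR spanning >=2 generations
                                with at least one diagnosed before the high
                                cutoff (50)
R3b       potentially_high      same-side cluster of >=2 affected FDR/SDR
                                with an early diagnosis, multiple primary
                                CRC, or a Lynch-spectrum cancer
R3c       potentially_high      any relative with multiple polyps
========  ====================  =============================================

Relatives on "your side" (the proband's siblings and children) are blood
relatives of both parental lineages and therefore count toward both sides
for same-side clustering.  A relative whose diagnosis age is unknown is
treated as *not* early-onset.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

from .errors import ConfigError, PedigreeValidationError
from .pedigree import (
    DegreeClass,
    FamilySide,
    Pedigree,
    Relative,
    RelativeRole,
    validate,
)

__all__ = [
    "RiskCategory",
    "RuleTable",
    "TriggeredRule",
    "RiskAssessment",
    "RULE_IDS",
    "assess",
    "generation_of",
    "recommendation_for",
    "load_rule_table",
]


class RiskCategory(enum.Enum):
    """The four familial CRC lifetime-risk categories, strictly ordered."""

    AVERAGE = ("average", 0)
    SLIGHTLY_INCREASED = ("slightly_increased", 1)
    MODERATELY_INCREASED = ("moderately_increased", 2)
    POTENTIALLY_HIGH = ("potentially_high", 3)

    def __init__(self, value: str, rank: int):
        self._value_ = value
        self.rank = rank

    @classmethod
    def parse(cls, value: str) -> "RiskCategory":
        try:
            return cls(value)
        except ValueError:
            raise ConfigError(f"unknown risk category: {value!r}") from None


RULE_IDS = ("R1", "R2a", "R2b", "R3a", "R3b", "R3c")

_RULE_CATEGORY = {
    "R1": RiskCategory.SLIGHTLY_INCREASED,
    "R2a": RiskCategory.MODERATELY_INCREASED,
    "R2b": RiskCategory.MODERATELY_INCREASED,
    "R3a": RiskCategory.POTENTIALLY_HIGH,
    "R3b": RiskCategory.POTENTIALLY_HIGH,
    "R3c": RiskCategory.POTENTIALLY_HIGH,
}

DEFAULT_RECOMMENDATIONS: dict[RiskCategory, str] = {
    RiskCategory.AVERAGE: (
        "Your family history places you at average lifetime risk of bowel "
        "cancer. No surveillance colonoscopy is offered within the programme "
        "at this level of risk. See your general practitioner if you develop "
        "symptoms or your family history changes."
    ),
    RiskCategory.SLIGHTLY_INCREASED: (
        "Your family history places you at slightly increased lifetime risk "
        "of bowel cancer (up to about twice the average). Discuss with your "
        "general practitioner whether surveillance is appropriate for you."
    ),
    RiskCategory.MODERATELY_INCREASED: (
        "Your family history places you at moderately increased lifetime "
        "risk of bowel cancer. Surveillance colonoscopy is usually offered; "
        "please see your general practitioner to arrange a referral."
    ),
    RiskCategory.POTENTIALLY_HIGH: (
        "Your family history suggests a potentially high lifetime risk of "
        "bowel cancer, possibly due to an inherited syndrome. Referral to a "
        "genetic service for assessment and a surveillance plan is "
        "recommended; please see your general practitioner promptly."
    ),
}


@dataclass(frozen=True)
class RuleTable:
    """Tunable parameters of the rule engine.

    ``age_cutoff_primary`` (default 55) separates later-onset from
    early-onset diagnoses for the FDR rules; ``age_cutoff_high`` (default
    50) is the stricter cutoff used by the high-risk cluster rules.  Ages
    are compared with strict ``<`` ("diagnosed before age X").
    """

    age_cutoff_primary: int = 55
    age_cutoff_high: int = 50
    amsterdam_min_relatives: int = 3
    amsterdam_min_generations: int = 2
    high_risk_cluster_min: int = 2
    enabled: Mapping[str, bool] = field(
        default_factory=lambda: {rid: True for rid in RULE_IDS}
    )
    recommendations: Mapping[RiskCategory, str] = field(
        default_factory=lambda: dict(DEFAULT_RECOMMENDATIONS)
    )

    def __post_init__(self):
        if self.age_cutoff_high >= self.age_cutoff_primary:
            raise ConfigError(
                "age_cutoff_high must be below age_cutoff_primary "
                f"({self.age_cutoff_high} >= {self.age_cutoff_primary})"
            )
        for name in ("amsterdam_min_relatives", "amsterdam_min_generations", "high_risk_cluster_min"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        unknown = set(self.enabled) - set(RULE_IDS)
        if unknown:
            raise ConfigError(f"unknown rule id(s) in 'enabled': {sorted(unknown)}")

    def is_enabled(self, rule_id: str) -> bool:
        return self.enabled.get(rule_id, True)


@dataclass(frozen=True)
class TriggeredRule:
    """One fired rule and the relatives that matched it."""

    rule_id: str
    category: RiskCategory
    relatives: tuple[tuple[str, int], ...]  # (role value, member_index), sorted


@dataclass(frozen=True)
class RiskAssessment:
    """Result of the lifetime-risk calculation."""

    category: RiskCategory
    triggered_rules: tuple[TriggeredRule, ...]  # sorted by rule id
    side_counts: Mapping[str, int]  # affected count per family side
    recommendation: str


_GENERATION: dict[RelativeRole, int] = {
    RelativeRole.MATERNAL_GRANDMOTHER: 2,
    RelativeRole.MATERNAL_GRANDFATHER: 2,
    RelativeRole.PATERNAL_GRANDMOTHER: 2,
    RelativeRole.PATERNAL_GRANDFATHER: 2,
    RelativeRole.MOTHER: 1,
    RelativeRole.FATHER: 1,
    RelativeRole.MATERNAL_AUNT_UNCLE: 1,
    RelativeRole.PATERNAL_AUNT_UNCLE: 1,
    RelativeRole.SIBLING: 0,
    RelativeRole.MATERNAL_AUNT_UNCLE_CHILD: 0,
    RelativeRole.PATERNAL_AUNT_UNCLE_CHILD: 0,
    RelativeRole.CHILD: -1,
}


def generation_of(role: RelativeRole) -> int:
    """Generation offset from the proband: grandparents 2, parents/aunts-uncles 1,
    the proband's generation (siblings, cousins) 0, children -1."""
    if not isinstance(role, RelativeRole):
        role = RelativeRole.parse(role)
    return _GENERATION[role]


def recommendation_for(category: RiskCategory, rules: RuleTable) -> str:
    """Plain-language recommendation text configured for a category."""
    if not isinstance(category, RiskCategory):
        category = RiskCategory.parse(category)
    text = rules.recommendations.get(category, "")
    if not text:
        raise ConfigError(f"no recommendation text configured for category {category.value!r}")
    return text


def _early(rel: Relative, cutoff: int) -> bool:
    age = rel.history.age_at_diagnosis
    return age is not None and age < cutoff


def _refs(relatives: Iterable[Relative]) -> tuple[tuple[str, int], ...]:
    return tuple(sorted((r.role.value, r.member_index) for r in relatives))


def _on_side(rel: Relative, side: FamilySide) -> bool:
    # your-side members are blood relatives of both lineages
    return rel.side is side or rel.side is FamilySide.YOUR_SIDE


def assess(pedigree: Pedigree, rules: RuleTable | None = None) -> RiskAssessment:
    """Run the lifetime-risk calculation on a validated pedigree.

    Evaluates all enabled rules and returns the highest-rank category
    (``average`` when none fire), the fired rules sorted by id with their
    matching relatives, and the configured recommendation text.
    Deterministic: identical input yields an identical assessment.
    """
    if rules is None:
        rules = RuleTable()
    report = validate(pedigree)
    if not report.ok:
        raise PedigreeValidationError(report)

    affected = [r for r in pedigree if r.history.affected]
    fdr = [r for r in affected if r.degree is DegreeClass.FDR]
    triggered: list[TriggeredRule] = []

    def fire(rule_id: str, matches: Iterable[Relative]) -> None:
        triggered.append(TriggeredRule(rule_id, _RULE_CATEGORY[rule_id], _refs(matches)))

    # -- potentially high ---------------------------------------------------
    if rules.is_enabled("R3c"):
        polyp = [r for r in pedigree if r.history.multiple_polyps]
        if polyp:
            fire("R3c", polyp)

    for side in (FamilySide.MOTHER_SIDE, FamilySide.FATHER_SIDE):
        members = [r for r in affected if _on_side(r, side)]
        if rules.is_enabled("R3a") and len(members) >= rules.amsterdam_min_relatives:
            generations = {generation_of(r.role) for r in members}
            if len(generations) >= rules.amsterdam_min_generations and any(
                _early(r, rules.age_cutoff_high) for r in members
            ):
                fire("R3a", members)
        if rules.is_enabled("R3b") and len(members) >= rules.high_risk_cluster_min:
            if any(
                _early(r, rules.age_cutoff_high)
                or r.history.multiple_primary_crc
                or r.history.other_related_cancers
                for r in members
            ):
                fire("R3b", members)

    # one cluster rule firing on both sides is reported once
    dedup: dict[str, TriggeredRule] = {}
    for t in triggered:
        if t.rule_id in dedup:
            merged = tuple(sorted(set(dedup[t.rule_id].relatives) | set(t.relatives)))
            dedup[t.rule_id] = TriggeredRule(t.rule_id, t.category, merged)
        else:
            dedup[t.rule_id] = t
    triggered = list(dedup.values())

    # -- moderately increased ----------------------------------------------
    if rules.is_enabled("R2a"):
        early_fdr = [r for r in fdr if _early(r, rules.age_cutoff_primary)]
        if early_fdr:
            fire("R2a", early_fdr)
    if rules.is_enabled("R2b") and len(fdr) >= 2:
        fire("R2b", fdr)

    # -- slightly increased (only if nothing higher fired) ------------------
    higher_fired = any(t.category.rank > RiskCategory.SLIGHTLY_INCREASED.rank for t in triggered)
    if (
        rules.is_enabled("R1")
        and not higher_fired
        and len(fdr) == 1
        and not _early(fdr[0], rules.age_cutoff_primary)
    ):
        fire("R1", fdr)

    triggered.sort(key=lambda t: t.rule_id)
    category = max(
        (t.category for t in triggered),
        key=lambda c: c.rank,
        default=RiskCategory.AVERAGE,
    )
    side_counts = {
        side.value: sum(1 for r in affected if r.side is side) for side in FamilySide
    }
    return RiskAssessment(
        category=category,
        triggered_rules=tuple(triggered),
        side_counts=side_counts,
        recommendation=recommendation_for(category, rules),
    )


# ---------------------------------------------------------------------------
# Rule-table configuration files (YAML; JSON is a subset of YAML)

_INT_FIELDS = (
    "age_cutoff_primary",
    "age_cutoff_high",
    "amsterdam_min_relatives",
    "amsterdam_min_generations",
    "high_risk_cluster_min",
)


def load_rule_table(source) -> RuleTable:
    """Load a :class:`RuleTable` from a YAML/JSON config file.

    Absent fields take their defaults; invariant violations raise
    :class:`ConfigError` naming the field.  Recognised keys:
    the five integer thresholds, ``enabled`` (mapping rule id → bool) and
    ``recommendations`` (mapping category name → text).
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("rule-table config must be a mapping")
    known = set(_INT_FIELDS) | {"enabled", "recommendations"}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"unknown rule-table field(s): {sorted(unknown)}")
    kwargs: dict = {}
    for name in _INT_FIELDS:
        if name in doc:
            try:
                kwargs[name] = int(doc[name])
            except (TypeError, ValueError):
                raise ConfigError(f"field {name!r} must be an integer") from None
    if "enabled" in doc:
        if not isinstance(doc["enabled"], dict):
            raise ConfigError("field 'enabled' must be a mapping of rule id to bool")
        kwargs["enabled"] = {str(k): bool(v) for k, v in doc["enabled"].items()}
    if "recommendations" in doc:
        if not isinstance(doc["recommendations"], dict):
            raise ConfigError("field 'recommendations' must be a mapping")
        recs = dict(DEFAULT_RECOMMENDATIONS)
        for key, text in doc["recommendations"].items():
            recs[RiskCategory.parse(key)] = str(text)
        kwargs["recommendations"] = recs
    return RuleTable(**kwargs)
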