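"""The two intake modes and the summary report.

The sequential questionnaire presents one question per page.  The base
traversal is fixed: six yes/no screening pages for the named relatives
(mother, father, four grandparents), four count pages for the pooled group
relatives (mother-side aunts/uncles and their children, father-side ditto,
the proband's siblings, the proband's children) and a final confirm page —
eleven pages when every answer is negative.  Each affirmative screening
answer inserts one detail page (diagnosis age and history flags) and a
group count of *k* inserts *k* detail pages, so with every group at its cap
of 7 the longest traversal is 11 + 6 + 4x7 = 45 pages.

The diagram intake accepts the same information as a single form covering
all role slots and produces an identical :class:`~famrisk.pedigree.Pedigree`;
:func:`render_summary` is byte-identical across the two modes for equal
pedigrees.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Sequence

from .errors import IncompleteFlowError, IntakeError
from .pedigree import (
    DEFAULT_GROUP_CAP,
    GROUP_POOLS,
    CancerHistory,
    Pedigree,
    Relative,
    RelativeRole,
    UNIQUE_ROLES,
    validate,
)
from .risk import RiskAssessment, RuleTable, assess

__all__ = [
    "PageKind",
    "QuestionPage",
    "FlowState",
    "SummaryReport",
    "start_flow",
    "answer",
    "run_flow",
    "flow_to_pedigree",
    "diagram_intake",
    "blank_form",
    "reset_form",
    "form_for",
    "answers_for",
    "render_summary",
    "NAMED_ROLES",
    "GROUP_KEYS",
]


class PageKind(str, enum.Enum):
    SCREEN_NAMED = "screen_named"
    GROUP_COUNT = "group_count"
    DETAIL = "detail"
    CONFIRM = "confirm"


#: Named relatives screened one per page, in presentation order.
NAMED_ROLES: tuple[RelativeRole, ...] = (
    RelativeRole.MOTHER,
    RelativeRole.FATHER,
    RelativeRole.MATERNAL_GRANDMOTHER,
    RelativeRole.MATERNAL_GRANDFATHER,
    RelativeRole.PATERNAL_GRANDMOTHER,
    RelativeRole.PATERNAL_GRANDFATHER,
)

#: Group pools asked as a single count page each, in presentation order.
GROUP_KEYS: tuple[str, ...] = ("maternal_group", "paternal_group", "siblings", "children")

_HEADINGS = {
    RelativeRole.MOTHER: "Mother's side of the family",
    RelativeRole.MATERNAL_GRANDMOTHER: "Mother's side of the family",
    RelativeRole.MATERNAL_GRANDFATHER: "Mother's side of the family",
    RelativeRole.FATHER: "Father's side of the family",
    RelativeRole.PATERNAL_GRANDMOTHER: "Father's side of the family",
    RelativeRole.PATERNAL_GRANDFATHER: "Father's side of the family",
    "maternal_group": "Mother's side of the family",
    "paternal_group": "Father's side of the family",
    "siblings": "Your side of the family",
    "children": "Your side of the family",
}

#: Group pools whose detail pages ask the relationship (aunt/uncle vs. their child).
_RELATION_GROUPS = ("maternal_group", "paternal_group")

_GROUP_FIXED_ROLE = {
    "siblings": RelativeRole.SIBLING,
    "children": RelativeRole.CHILD,
}


@dataclass(frozen=True)
class QuestionPage:
    """One page of the sequential questionnaire."""

    page_id: str
    heading: str
    kind: PageKind
    target: tuple[str, int] | None = None  # (role value or group key, member slot)
    fields: tuple[str, ...] = ()


def _named_page(role: RelativeRole) -> QuestionPage:
    return QuestionPage(
        page_id=f"screen_{role.value}",
        heading=_HEADINGS[role],
        kind=PageKind.SCREEN_NAMED,
        target=(role.value, 0),
        fields=("affected",),
    )


def _count_page(key: str) -> QuestionPage:
    return QuestionPage(
        page_id=f"count_{key}",
        heading=_HEADINGS[key],
        kind=PageKind.GROUP_COUNT,
        target=(key, 0),
        fields=("count",),
    )


def _detail_page(target_key: str, slot: int, heading: str, with_relation: bool) -> QuestionPage:
    fields = ("age_dx", "multiple_polyps", "other_cancers", "multiple_crc")
    if with_relation:
        fields = ("relation",) + fields
    return QuestionPage(
        page_id=f"detail_{target_key}_{slot}",
        heading=heading,
        kind=PageKind.DETAIL,
        target=(target_key, slot),
        fields=fields,
    )


_CONFIRM_PAGE = QuestionPage(
    page_id="confirm",
    heading="Review and submit",
    kind=PageKind.CONFIRM,
    fields=("action",),
)


def _base_pages() -> tuple[QuestionPage, ...]:
    return tuple(
        [_named_page(r) for r in NAMED_ROLES]
        + [_count_page(k) for k in GROUP_KEYS]
        + [_CONFIRM_PAGE]
    )


@dataclass(frozen=True)
class FlowState:
    """Immutable position in the sequential questionnaire.

    ``answers`` holds ``(page, payload)`` pairs in the order answered;
    ``pages_presented`` counts every page shown, including re-presented
    pages after a restart from the confirm screen.
    """

    current: QuestionPage | None
    upcoming: tuple[QuestionPage, ...]
    answers: tuple[tuple[QuestionPage, Mapping[str, Any]], ...]
    pages_presented: int
    finished: bool
    group_cap: int = DEFAULT_GROUP_CAP


def start_flow(group_cap: int = DEFAULT_GROUP_CAP) -> FlowState:
    """Begin a traversal positioned on the first page (mother screening)."""
    pages = _base_pages()
    return FlowState(
        current=pages[0],
        upcoming=pages[1:],
        answers=(),
        pages_presented=1,
        finished=False,
        group_cap=group_cap,
    )


def _check_bool(payload: Mapping[str, Any], key: str) -> bool:
    v = payload.get(key, False)
    if not isinstance(v, bool):
        raise IntakeError(f"field {key!r} must be a boolean, got {v!r}")
    return v


def _check_detail(payload: Mapping[str, Any], page: QuestionPage) -> None:
    allowed = set(page.fields)
    extra = set(payload) - allowed
    if extra:
        raise IntakeError(f"unexpected field(s) for page {page.page_id}: {sorted(extra)}")
    age = payload.get("age_dx")
    if age is not None and (not isinstance(age, int) or isinstance(age, bool)):
        raise IntakeError(f"field 'age_dx' must be an integer or None, got {age!r}")
    for key in ("multiple_polyps", "other_cancers", "multiple_crc"):
        _check_bool(payload, key)
    if "relation" in page.fields:
        rel = payload.get("relation")
        if rel not in ("aunt_uncle", "child"):
            raise IntakeError(
                f"field 'relation' must be 'aunt_uncle' or 'child', got {rel!r}"
            )


def answer(state: FlowState, payload: Mapping[str, Any]) -> FlowState:
    """Submit the answer to the current page and advance.

    Returns a new state; on a malformed payload an :class:`IntakeError` is
    raised and the input state is unchanged (it is immutable).
    """
    if state.finished or state.current is None:
        raise IncompleteFlowError("flow already finished")
    page = state.current
    enqueue_front: list[QuestionPage] = []

    if page.kind is PageKind.SCREEN_NAMED:
        if _check_bool(payload, "affected"):
            role = page.target[0]
            enqueue_front.append(_detail_page(role, 0, page.heading, with_relation=False))
    elif page.kind is PageKind.GROUP_COUNT:
        k = payload.get("count")
        if not isinstance(k, int) or isinstance(k, bool) or k < 0:
            raise IntakeError(f"field 'count' must be a non-negative integer, got {k!r}")
        if k > state.group_cap:
            raise IntakeError(f"count {k} exceeds the group cap of {state.group_cap}")
        key = page.target[0]
        enqueue_front.extend(
            _detail_page(key, slot, page.heading, with_relation=key in _RELATION_GROUPS)
            for slot in range(k)
        )
    elif page.kind is PageKind.DETAIL:
        _check_detail(payload, page)
    elif page.kind is PageKind.CONFIRM:
        action = payload.get("action")
        if action == "submit":
            return replace(
                state,
                current=None,
                upcoming=(),
                answers=state.answers + ((page, dict(payload)),),
                finished=True,
            )
        if action == "restart":
            pages = _base_pages()
            return replace(
                state,
                current=pages[0],
                upcoming=pages[1:],
                answers=(),
                pages_presented=state.pages_presented + 1,
            )
        raise IntakeError(f"field 'action' must be 'submit' or 'restart', got {action!r}")

    upcoming = tuple(enqueue_front) + state.upcoming
    return replace(
        state,
        current=upcoming[0],
        upcoming=upcoming[1:],
        answers=state.answers + ((page, dict(payload)),),
        pages_presented=state.pages_presented + 1,
    )


def run_flow(
    payloads: Iterable[Mapping[str, Any]], group_cap: int = DEFAULT_GROUP_CAP
) -> FlowState:
    """Drive a whole traversal from a sequence of answer payloads."""
    state = start_flow(group_cap)
    for payload in payloads:
        state = answer(state, payload)
        if state.finished:
            break
    return state


def _history_from_detail(payload: Mapping[str, Any]) -> CancerHistory:
    return CancerHistory(
        affected=True,
        age_at_diagnosis=payload.get("age_dx"),
        multiple_polyps=bool(payload.get("multiple_polyps", False)),
        other_related_cancers=bool(payload.get("other_cancers", False)),
        multiple_primary_crc=bool(payload.get("multiple_crc", False)),
    )


def flow_to_pedigree(state: FlowState) -> Pedigree:
    """Materialise the pedigree from a finished traversal.

    Contains exactly the relatives whose screening/count answers were
    affirmative, with the detail fields copied; group members are indexed
    in the order their detail pages were answered.
    """
    if not state.finished:
        raise IncompleteFlowError("flow has not been submitted yet")
    relatives: list[Relative] = []
    counters: dict[RelativeRole, int] = {}
    for page, payload in state.answers:
        if page.kind is not PageKind.DETAIL:
            continue
        key = page.target[0]
        if key in _RELATION_GROUPS:
            pool = GROUP_POOLS[key]
            role = pool[0] if payload["relation"] == "aunt_uncle" else pool[1]
        elif key in _GROUP_FIXED_ROLE:
            role = _GROUP_FIXED_ROLE[key]
        else:
            role = RelativeRole(key)
        idx = counters.get(role, 0)
        counters[role] = idx + 1
        relatives.append(Relative(role, idx if role not in UNIQUE_ROLES else 0, _history_from_detail(payload)))
    return Pedigree(tuple(sorted(relatives, key=Relative.sort_key)))


# ---------------------------------------------------------------------------
# Diagram (single-form) intake

_NAMED_KEYS = tuple(r.value for r in NAMED_ROLES)
_FORM_KEYS = _NAMED_KEYS + GROUP_KEYS


def blank_form() -> dict[str, Any]:
    """An all-empty diagram form covering every role slot."""
    form: dict[str, Any] = {key: {"affected": False} for key in _NAMED_KEYS}
    for key in GROUP_KEYS:
        form[key] = []
    return form


def reset_form(form: Mapping[str, Any], confirm: bool) -> dict[str, Any]:
    """Reset the form to empty; requires explicit confirmation."""
    if not confirm:
        return dict(form)
    return blank_form()


def diagram_intake(
    form: Mapping[str, Any], group_cap: int = DEFAULT_GROUP_CAP
) -> Pedigree:
    """Build a pedigree from a complete single-page form payload.

    The form must cover all ten blocks: one entry per named relative and
    one (possibly empty) list per group pool.  Produces the same pedigree
    as the equivalent questionnaire traversal.
    """
    missing = [k for k in _FORM_KEYS if k not in form]
    if missing:
        raise IntakeError(f"form is missing block(s): {missing}")
    extra = set(form) - set(_FORM_KEYS)
    if extra:
        raise IntakeError(f"form has unknown block(s): {sorted(extra)}")

    relatives: list[Relative] = []
    for key in _NAMED_KEYS:
        entry = form[key]
        if not isinstance(entry, Mapping):
            raise IntakeError(f"block {key!r} must be a mapping")
        if _check_bool(entry, "affected"):
            relatives.append(Relative(RelativeRole(key), 0, _history_from_detail(entry)))
    for key in GROUP_KEYS:
        entries = form[key]
        if not isinstance(entries, Sequence) or isinstance(entries, (str, bytes)):
            raise IntakeError(f"block {key!r} must be a list of member entries")
        if len(entries) > group_cap:
            raise IntakeError(f"block {key!r} has {len(entries)} members, cap is {group_cap}")
        counters: dict[RelativeRole, int] = {}
        for entry in entries:
            if key in _RELATION_GROUPS:
                relation = entry.get("relation")
                if relation not in ("aunt_uncle", "child"):
                    raise IntakeError(
                        f"block {key!r}: 'relation' must be 'aunt_uncle' or 'child', got {relation!r}"
                    )
                pool = GROUP_POOLS[key]
                role = pool[0] if relation == "aunt_uncle" else pool[1]
            else:
                role = _GROUP_FIXED_ROLE[key]
            idx = counters.get(role, 0)
            counters[role] = idx + 1
            relatives.append(Relative(role, idx, _history_from_detail(entry)))
    return Pedigree(tuple(sorted(relatives, key=Relative.sort_key)))


# ---------------------------------------------------------------------------
# Round-trip helpers (used by the scripted CLI mode and the equivalence tests)


def _detail_payload(rel: Relative, relation: str | None = None) -> dict[str, Any]:
    payload: dict[str, Any] = {
        "age_dx": rel.history.age_at_diagnosis,
        "multiple_polyps": rel.history.multiple_polyps,
        "other_cancers": rel.history.other_related_cancers,
        "multiple_crc": rel.history.multiple_primary_crc,
    }
    if relation is not None:
        payload["relation"] = relation
    return payload


def _pool_members(pedigree: Pedigree, key: str) -> list[Relative]:
    pool = set(GROUP_POOLS[key])
    return sorted((r for r in pedigree if r.role in pool), key=Relative.sort_key)


def answers_for(pedigree: Pedigree) -> list[dict[str, Any]]:
    """The questionnaire payload sequence that reproduces ``pedigree``."""
    by_role = {(r.role, r.member_index): r for r in pedigree}
    payloads: list[dict[str, Any]] = []
    for role in NAMED_ROLES:
        rel = by_role.get((role, 0))
        payloads.append({"affected": rel is not None})
        if rel is not None:
            payloads.append(_detail_payload(rel))
    for key in GROUP_KEYS:
        members = _pool_members(pedigree, key)
        payloads.append({"count": len(members)})
        for rel in members:
            if key in _RELATION_GROUPS:
                relation = "aunt_uncle" if rel.role is GROUP_POOLS[key][0] else "child"
            else:
                relation = None
            payloads.append(_detail_payload(rel, relation))
    payloads.append({"action": "submit"})
    return payloads


def form_for(pedigree: Pedigree) -> dict[str, Any]:
    """The diagram form that reproduces ``pedigree``."""
    form = blank_form()
    for role in NAMED_ROLES:
        for rel in pedigree:
            if rel.role is role:
                entry = _detail_payload(rel)
                entry["affected"] = True
                form[role.value] = entry
    for key in GROUP_KEYS:
        entries = []
        for rel in _pool_members(pedigree, key):
            if key in _RELATION_GROUPS:
                relation = "aunt_uncle" if rel.role is GROUP_POOLS[key][0] else "child"
            else:
                relation = None
            entries.append(_detail_payload(rel, relation))
        form[key] = entries
    return form


# ---------------------------------------------------------------------------
# Summary report

_ROLE_LABEL = {
    RelativeRole.MOTHER: "Mother",
    RelativeRole.FATHER: "Father",
    RelativeRole.MATERNAL_GRANDMOTHER: "Maternal grandmother",
    RelativeRole.MATERNAL_GRANDFATHER: "Maternal grandfather",
    RelativeRole.PATERNAL_GRANDMOTHER: "Paternal grandmother",
    RelativeRole.PATERNAL_GRANDFATHER: "Paternal grandfather",
    RelativeRole.MATERNAL_AUNT_UNCLE: "Mother's sibling",
    RelativeRole.MATERNAL_AUNT_UNCLE_CHILD: "Mother's sibling's child",
    RelativeRole.PATERNAL_AUNT_UNCLE: "Father's sibling",
    RelativeRole.PATERNAL_AUNT_UNCLE_CHILD: "Father's sibling's child",
    RelativeRole.SIBLING: "Sibling",
    RelativeRole.CHILD: "Child",
}

_CATEGORY_LABEL = {
    "average": "Average lifetime risk",
    "slightly_increased": "Slightly increased risk",
    "moderately_increased": "Moderately increased risk",
    "potentially_high": "Potentially high risk",
}

ADVICE_LINE = (
    "Please take this summary to your general practitioner to discuss "
    "whether surveillance is indicated."
)


@dataclass(frozen=True)
class SummaryReport:
    """Summary of the entries, the calculated risk and the advice line."""

    entries: tuple[str, ...]
    assessment: RiskAssessment
    advice: str = ADVICE_LINE

    def text(self) -> str:
        lines = ["Family history summary", "----------------------"]
        if self.entries:
            lines.extend(self.entries)
        else:
            lines.append("No affected relatives entered.")
        lines.append("")
        lines.append(f"Risk category: {_CATEGORY_LABEL[self.assessment.category.value]}")
        lines.append(f"Recommendation: {self.assessment.recommendation}")
        lines.append(self.advice)
        return "\n".join(lines) + "\n"


def _entry_line(rel: Relative) -> str:
    label = _ROLE_LABEL[rel.role]
    if rel.role not in UNIQUE_ROLES:
        label = f"{label} #{rel.member_index + 1}"
    h = rel.history
    parts = ["affected by bowel cancer"]
    if h.age_at_diagnosis is not None:
        parts.append(f"diagnosed at age {h.age_at_diagnosis}")
    if h.multiple_polyps:
        parts.append("multiple polyps")
    if h.other_related_cancers:
        parts.append("other related cancers")
    if h.multiple_primary_crc:
        parts.append("more than one primary bowel cancer")
    return f"{label}: " + "; ".join(parts)


def render_summary(pedigree: Pedigree, rules: RuleTable | None = None) -> SummaryReport:
    """Deterministic summary report, byte-identical across intake modes."""
    assessment = assess(pedigree, rules)
    entries = tuple(
        _entry_line(rel)
        for rel in sorted(pedigree, key=Relative.sort_key)
        if rel.history.affected
    )
    return SummaryReport(entries=entries, assessment=assessment)
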