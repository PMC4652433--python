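"""Pedigree data model for family-history assessment of colorectal cancer (CRC) risk.

The model covers the twelve blood-relative roles a proband is asked about:
parents, the four grandparents, aunts/uncles and their children on each
parental side, and the proband's own siblings and children.  Every role
belongs to exactly one of three family sides (mother's side, father's side,
"your side") and to exactly one degree class (first- or second-degree
relative, FDR/SDR).  A :class:`Pedigree` is the unit of risk assessment.

Two on-disk formats are supported: a versioned JSON document (schema shipped
in ``famrisk/schema/pedigree.schema.json``) and a PED-inspired tab-separated
table.  Both round-trip losslessly for valid pedigrees.
"""

from __future__ import annotations

import enum
import io
import json
import os
from dataclasses import dataclass, field, replace
from typing import Callable, IO, Iterable, Iterator, Union

from .errors import InvalidRoleError, ParseError

__all__ = [
    "RelativeRole",
    "FamilySide",
    "DegreeClass",
    "CancerHistory",
    "Relative",
    "Pedigree",
    "Violation",
    "ValidationReport",
    "side_of",
    "degree_of",
    "validate",
    "count_affected",
    "read_pedigree",
    "write_pedigree",
    "UNIQUE_ROLES",
    "GROUP_ROLES",
    "GROUP_POOLS",
    "DEFAULT_GROUP_CAP",
    "ROLE_ORDER",
]


class RelativeRole(str, enum.Enum):
    """The twelve relative roles collected by the assessment."""

    MOTHER = "mother"
    FATHER = "father"
    MATERNAL_GRANDMOTHER = "maternal_grandmother"
    MATERNAL_GRANDFATHER = "maternal_grandfather"
    PATERNAL_GRANDMOTHER = "paternal_grandmother"
    PATERNAL_GRANDFATHER = "paternal_grandfather"
    MATERNAL_AUNT_UNCLE = "maternal_aunt_uncle"
    MATERNAL_AUNT_UNCLE_CHILD = "maternal_aunt_uncle_child"
    PATERNAL_AUNT_UNCLE = "paternal_aunt_uncle"
    PATERNAL_AUNT_UNCLE_CHILD = "paternal_aunt_uncle_child"
    SIBLING = "sibling"
    CHILD = "child"

    @classmethod
    def parse(cls, value: str) -> "RelativeRole":
        try:
            return cls(value)
        except ValueError:
            raise InvalidRoleError(f"unknown relative role: {value!r}") from None


class FamilySide(str, enum.Enum):
    """Three-way grouping of the family: mother's side, father's side, your side."""

    MOTHER_SIDE = "mother_side"
    FATHER_SIDE = "father_side"
    YOUR_SIDE = "your_side"


class DegreeClass(str, enum.Enum):
    """First- vs second-degree relative classification."""

    FDR = "FDR"
    SDR = "SDR"


# Roles that may appear at most once per pedigree.
UNIQUE_ROLES = frozenset(
    {
        RelativeRole.MOTHER,
        RelativeRole.FATHER,
        RelativeRole.MATERNAL_GRANDMOTHER,
        RelativeRole.MATERNAL_GRANDFATHER,
        RelativeRole.PATERNAL_GRANDMOTHER,
        RelativeRole.PATERNAL_GRANDFATHER,
    }
)

# Roles that may have multiple members, distinguished by member_index.
GROUP_ROLES = frozenset(set(RelativeRole) - UNIQUE_ROLES)

#: Group pools used for cap enforcement and for the intake interfaces:
#: aunts/uncles and their children are pooled per parental side; the
#: proband's siblings and children form their own pools.
GROUP_POOLS: dict[str, tuple[RelativeRole, ...]] = {
    "maternal_group": (
        RelativeRole.MATERNAL_AUNT_UNCLE,
        RelativeRole.MATERNAL_AUNT_UNCLE_CHILD,
    ),
    "paternal_group": (
        RelativeRole.PATERNAL_AUNT_UNCLE,
        RelativeRole.PATERNAL_AUNT_UNCLE_CHILD,
    ),
    "siblings": (RelativeRole.SIBLING,),
    "children": (RelativeRole.CHILD,),
}

#: Maximum number of entered members per group pool.
DEFAULT_GROUP_CAP = 7

#: Canonical display/serialisation order for roles.
ROLE_ORDER: tuple[RelativeRole, ...] = tuple(RelativeRole)

_SIDE_OF: dict[RelativeRole, FamilySide] = {
    RelativeRole.MOTHER: FamilySide.MOTHER_SIDE,
    RelativeRole.MATERNAL_GRANDMOTHER: FamilySide.MOTHER_SIDE,
    RelativeRole.MATERNAL_GRANDFATHER: FamilySide.MOTHER_SIDE,
    RelativeRole.MATERNAL_AUNT_UNCLE: FamilySide.MOTHER_SIDE,
    RelativeRole.MATERNAL_AUNT_UNCLE_CHILD: FamilySide.MOTHER_SIDE,
    RelativeRole.FATHER: FamilySide.FATHER_SIDE,
    RelativeRole.PATERNAL_GRANDMOTHER: FamilySide.FATHER_SIDE,
    RelativeRole.PATERNAL_GRANDFATHER: FamilySide.FATHER_SIDE,
    RelativeRole.PATERNAL_AUNT_UNCLE: FamilySide.FATHER_SIDE,
    RelativeRole.PATERNAL_AUNT_UNCLE_CHILD: FamilySide.FATHER_SIDE,
    RelativeRole.SIBLING: FamilySide.YOUR_SIDE,
    RelativeRole.CHILD: FamilySide.YOUR_SIDE,
}

_DEGREE_OF: dict[RelativeRole, DegreeClass] = {
    role: (
        DegreeClass.FDR
        if role
        in (
            RelativeRole.MOTHER,
            RelativeRole.FATHER,
            RelativeRole.SIBLING,
            RelativeRole.CHILD,
        )
        else DegreeClass.SDR
    )
    for role in RelativeRole
}


def side_of(role: RelativeRole) -> FamilySide:
    """Return the family side a role belongs to.

    Mother's side holds the mother, the maternal grandparents and the
    maternal aunts/uncles and their children; the father's side is
    symmetric; "your side" holds the proband's siblings and children.
    """
    if not isinstance(role, RelativeRole):
        role = RelativeRole.parse(role)
    return _SIDE_OF[role]


def degree_of(role: RelativeRole) -> DegreeClass:
    """Return the degree class of a role.

    Parents, siblings and children are first-degree relatives (FDR);
    grandparents, aunts/uncles and their children are treated as
    second-degree (SDR) for the purposes of this assessment.
    """
    if not isinstance(role, RelativeRole):
        role = RelativeRole.parse(role)
    return _DEGREE_OF[role]


@dataclass(frozen=True)
class CancerHistory:
    """Cancer history of one relative.

    ``age_at_diagnosis`` is in whole years and may be absent (unknown age).
    The three flags capture polyposis and Lynch-spectrum signals at the
    granularity the questionnaire asks for: multiple colorectal polyps,
    other Lynch-spectrum ("related") cancers, and more than one primary
    colorectal cancer.
    """

    affected: bool = False
    age_at_diagnosis: int | None = None
    multiple_polyps: bool = False
    other_related_cancers: bool = False
    multiple_primary_crc: bool = False


@dataclass(frozen=True, order=True)
class Relative:
    """One relative: a role, a member index (for group roles) and a history.

    ``side`` and ``degree`` are derived from the role and can never be
    stored inconsistently.
    """

    role: RelativeRole
    member_index: int = 0
    history: CancerHistory = field(default_factory=CancerHistory, compare=True)

    @property
    def side(self) -> FamilySide:
        return side_of(self.role)

    @property
    def degree(self) -> DegreeClass:
        return degree_of(self.role)

    def sort_key(self) -> tuple[int, int]:
        return (ROLE_ORDER.index(self.role), self.member_index)


@dataclass(frozen=True)
class Pedigree:
    """A validated collection of relatives — the unit of risk assessment."""

    relatives: tuple[Relative, ...] = ()
    proband_note: str = ""

    def __iter__(self) -> Iterator[Relative]:
        return iter(self.relatives)

    def __len__(self) -> int:
        return len(self.relatives)

    def canonical(self) -> "Pedigree":
        """Return an equal pedigree with relatives in canonical role order."""
        return replace(self, relatives=tuple(sorted(self.relatives, key=Relative.sort_key)))

    @staticmethod
    def of(*relatives: Relative, proband_note: str = "") -> "Pedigree":
        return Pedigree(tuple(relatives), proband_note)


@dataclass(frozen=True)
class Violation:
    """One validation finding; ``subject`` names the offending relative."""

    code: str
    message: str
    subject: str = ""


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations


def _subject(rel: Relative) -> str:
    if rel.role in UNIQUE_ROLES:
        return rel.role.value
    return f"{rel.role.value}[{rel.member_index}]"


def validate(pedigree: Pedigree, group_cap: int = DEFAULT_GROUP_CAP) -> ValidationReport:
    """Check a pedigree against the model invariants.

    Violations are returned as data, never raised: duplicate unique roles,
    duplicate (role, member_index) pairs, group-pool caps exceeded,
    diagnosis age without the affected flag, age out of the plausible
    (0, 120] range, and polyp/cancer flags on an unaffected relative.
    The input is never mutated.
    """
    out: list[Violation] = []
    seen: set[tuple[RelativeRole, int]] = set()
    unique_seen: set[RelativeRole] = set()
    pool_counts: dict[str, int] = {k: 0 for k in GROUP_POOLS}
    pool_of_role = {r: k for k, roles in GROUP_POOLS.items() for r in roles}

    for rel in pedigree:
        key = (rel.role, rel.member_index)
        if key in seen:
            out.append(
                Violation("duplicate-entry", f"duplicate relative entry {_subject(rel)}", _subject(rel))
            )
        seen.add(key)
        if rel.role in UNIQUE_ROLES:
            if rel.role in unique_seen:
                out.append(
                    Violation(
                        "duplicate-unique-role",
                        f"duplicate unique role {rel.role.value}",
                        rel.role.value,
                    )
                )
            unique_seen.add(rel.role)
        else:
            pool_counts[pool_of_role[rel.role]] += 1

        h = rel.history
        if h.age_at_diagnosis is not None:
            if not h.affected:
                out.append(
                    Violation(
                        "age-without-affected",
                        f"{_subject(rel)} has a diagnosis age but is not flagged affected",
                        _subject(rel),
                    )
                )
            elif not (0 < h.age_at_diagnosis <= 120):
                out.append(
                    Violation(
                        "age-out-of-range",
                        f"{_subject(rel)} diagnosis age {h.age_at_diagnosis} outside (0, 120]",
                        _subject(rel),
                    )
                )
        if (h.multiple_polyps or h.other_related_cancers or h.multiple_primary_crc) and not h.affected:
            out.append(
                Violation(
                    "flags-without-affected",
                    f"{_subject(rel)} has history flags but is not flagged affected",
                    _subject(rel),
                )
            )

    for pool, n in pool_counts.items():
        if n > group_cap:
            out.append(
                Violation(
                    "group-cap-exceeded",
                    f"group {pool} has {n} members, cap is {group_cap}",
                    pool,
                )
            )
    return ValidationReport(tuple(out))


def count_affected(
    pedigree: Pedigree,
    side: FamilySide | None = None,
    degree: DegreeClass | None = None,
    predicate: Callable[[Relative], bool] | None = None,
) -> int:
    """Count affected relatives matching the (conjunctive) filters.

    ``side``/``degree`` of ``None`` mean "all"; ``predicate`` is an optional
    extra filter on the relative (e.g. an age or flag condition).
    """
    n = 0
    for rel in pedigree:
        if not rel.history.affected:
            continue
        if side is not None and rel.side is not side:
            continue
        if degree is not None and rel.degree is not degree:
            continue
        if predicate is not None and not predicate(rel):
            continue
        n += 1
    return n


# ---------------------------------------------------------------------------
# Serialisation

JSON_FORMAT = "famrisk-pedigree"
JSON_VERSION = 1

TABULAR_HEADER = (
    "role",
    "member_index",
    "affected",
    "age_dx",
    "multiple_polyps",
    "other_cancers",
    "multiple_crc",
)


def _relative_to_dict(rel: Relative) -> dict:
    h = rel.history
    d: dict = {"role": rel.role.value, "member_index": rel.member_index, "affected": h.affected}
    if h.age_at_diagnosis is not None:
        d["age_at_diagnosis"] = h.age_at_diagnosis
    if h.multiple_polyps:
        d["multiple_polyps"] = True
    if h.other_related_cancers:
        d["other_related_cancers"] = True
    if h.multiple_primary_crc:
        d["multiple_primary_crc"] = True
    return d


def _relative_from_dict(d: dict, line: int | None = None) -> Relative:
    if not isinstance(d, dict):
        raise ParseError("relative entry is not an object", line=line)
    try:
        role = RelativeRole.parse(d["role"])
    except KeyError:
        raise ParseError("relative entry missing 'role'", line=line) from None
    member_index = int(d.get("member_index", 0))
    age = d.get("age_at_diagnosis")
    history = CancerHistory(
        affected=bool(d.get("affected", False)),
        age_at_diagnosis=None if age is None else int(age),
        multiple_polyps=bool(d.get("multiple_polyps", False)),
        other_related_cancers=bool(d.get("other_related_cancers", False)),
        multiple_primary_crc=bool(d.get("multiple_primary_crc", False)),
    )
    return Relative(role, member_index, history)


def pedigree_to_dict(pedigree: Pedigree) -> dict:
    return {
        "format": JSON_FORMAT,
        "version": JSON_VERSION,
        "proband_note": pedigree.proband_note,
        "relatives": [_relative_to_dict(r) for r in pedigree.canonical()],
    }


def pedigree_from_dict(doc: dict) -> Pedigree:
    if not isinstance(doc, dict) or doc.get("format") != JSON_FORMAT:
        raise ParseError(f"not a {JSON_FORMAT} document")
    if doc.get("version") != JSON_VERSION:
        raise ParseError(f"unsupported pedigree document version: {doc.get('version')!r}")
    rels = doc.get("relatives", [])
    if not isinstance(rels, list):
        raise ParseError("'relatives' must be a list")
    return Pedigree(
        tuple(_relative_from_dict(d) for d in rels),
        proband_note=str(doc.get("proband_note", "")),
    )


def _parse_bool(token: str, line: int, column: str) -> bool:
    if token == "0":
        return False
    if token == "1":
        return True
    raise ParseError(f"expected 0 or 1, got {token!r}", line=line, column=column)


def _pedigree_to_tabular(pedigree: Pedigree) -> str:
    lines = ["\t".join(TABULAR_HEADER)]
    for rel in pedigree.canonical():
        h = rel.history
        lines.append(
            "\t".join(
                (
                    rel.role.value,
                    str(rel.member_index),
                    "1" if h.affected else "0",
                    "." if h.age_at_diagnosis is None else str(h.age_at_diagnosis),
                    "1" if h.multiple_polyps else "0",
                    "1" if h.other_related_cancers else "0",
                    "1" if h.multiple_primary_crc else "0",
                )
            )
        )
    return "\n".join(lines) + "\n"


def _pedigree_from_tabular(text: str) -> Pedigree:
    lines = text.splitlines()
    if not lines:
        raise ParseError("empty tabular pedigree (missing header)")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != TABULAR_HEADER:
        raise ParseError(
            f"bad header: expected {' '.join(TABULAR_HEADER)}", line=1
        )
    relatives = []
    for i, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != len(TABULAR_HEADER):
            raise ParseError(
                f"expected {len(TABULAR_HEADER)} fields, got {len(fields)}", line=i
            )
        row = dict(zip(TABULAR_HEADER, fields))
        role = RelativeRole.parse(row["role"])
        try:
            member_index = int(row["member_index"])
        except ValueError:
            raise ParseError(
                f"bad member_index {row['member_index']!r}", line=i, column="member_index"
            ) from None
        affected = _parse_bool(row["affected"], i, "affected")
        if row["age_dx"] == ".":
            age = None
        else:
            try:
                age = int(row["age_dx"])
            except ValueError:
                raise ParseError(
                    f"bad age {row['age_dx']!r}", line=i, column="age_dx"
                ) from None
        history = CancerHistory(
            affected=affected,
            age_at_diagnosis=age,
            multiple_polyps=_parse_bool(row["multiple_polyps"], i, "multiple_polyps"),
            other_related_cancers=_parse_bool(row["other_cancers"], i, "other_cancers"),
            multiple_primary_crc=_parse_bool(row["multiple_crc"], i, "multiple_crc"),
        )
        relatives.append(Relative(role, member_index, history))
    return Pedigree(tuple(relatives))


PathOrStream = Union[str, os.PathLike, IO[str]]


def _infer_format(path: str) -> str:
    return "json" if str(path).endswith(".json") else "tabular"


def read_pedigree(source: PathOrStream, format: str | None = None) -> Pedigree:
    """Read a pedigree from a path or text stream in ``json`` or ``tabular`` format.

    With ``format=None`` the format is inferred from the file extension
    (``.json`` → JSON, anything else → tabular).
    """
    if isinstance(source, (str, os.PathLike)):
        fmt = format or _infer_format(str(source))
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    else:
        fmt = format or "json"
        text = source.read()
    if fmt == "json":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid JSON: {exc}", line=exc.lineno) from None
        return pedigree_from_dict(doc)
    if fmt == "tabular":
        return _pedigree_from_tabular(text)
    raise ValueError(f"unknown pedigree format: {format!r}")


def write_pedigree(
    pedigree: Pedigree, dest: PathOrStream | None = None, format: str = "json"
) -> str:
    """Serialise a pedigree; returns the text and optionally writes it to ``dest``."""
    if format == "json":
        text = json.dumps(pedigree_to_dict(pedigree), indent=2) + "\n"
    elif format == "tabular":
        text = _pedigree_to_tabular(pedigree)
    else:
        raise ValueError(f"unknown pedigree format: {format!r}")
    if dest is not None:
        if isinstance(dest, (str, os.PathLike)):
            with open(dest, "w", encoding="utf-8", newline="\n") as fh:
                fh.write(text)
        else:
            dest.write(text)
    return text
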