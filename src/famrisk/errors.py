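"""Exception hierarchy for famrisk."""


class FamriskError(Exception):
    """Base class for all famrisk errors."""


class InvalidRoleError(FamriskError):
    """An unknown relative role was supplied."""


class ParseError(FamriskError):
    """A pedigree file could not be parsed.

    Carries the 1-based line number and the offending column/field name
    so callers can point the user at the exact cell.
    """

    def __init__(self, message: str, line: int | None = None, column: str | None = None):
        loc = []
        if line is not None:
            loc.append(f"line {line}")
        if column is not None:
            loc.append(f"column {column!r}")
        suffix = f" ({', '.join(loc)})" if loc else ""
        super().__init__(message + suffix)
        self.line = line
        self.column = column


class PedigreeValidationError(FamriskError):
    """A pedigree failed validation where a valid one was required."""

    def __init__(self, report):
        self.report = report
        msgs = "; ".join(v.message for v in report.violations)
        super().__init__(f"invalid pedigree: {msgs}")


class ConfigError(FamriskError):
    """A rule table / generator configuration violates its invariants."""


class IntakeError(FamriskError):
    """A questionnaire-flow or diagram-form payload is malformed."""


class IncompleteFlowError(FamriskError):
    """A pedigree was requested from an unfinished questionnaire flow."""


class DataError(FamriskError):
    """Study data violate the documented schema (e.g. Likert response out of 1..7)."""


class StatsError(FamriskError):
    """A statistical routine received degenerate input or failed numerically."""
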