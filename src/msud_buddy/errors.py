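"""Exception hierarchy shared across the package.

Every user-facing failure derives from :class:`MsudBuddyError` so the CLI
can map any library error to a nonzero exit code with a readable message.
"""

from __future__ import annotations


class MsudBuddyError(Exception):
    """Base class for all errors raised by msud_buddy."""


class ConfigurationError(MsudBuddyError):
    """Malformed rule, condition, or configuration value."""


class KBLoadError(MsudBuddyError):
    """Knowledge-base source failed validation; names the row and field."""


class UnknownFormulaError(MsudBuddyError):
    """Formula name not present in the knowledge base."""

    def __init__(self, name: str, available: list[str]):
        self.name = name
        self.available = list(available)
        super().__init__(
            f"Unknown formula {name!r}; available formulas: {', '.join(available)}"
        )


class OutOfRangeError(MsudBuddyError):
    """Input outside the supported clinical span (0-6 months, 0-15 kg)."""


class FieldValidationError(MsudBuddyError):
    """One or more named fields failed validation.

    ``fields`` maps field name -> reason, covering *all* offending fields,
    not just the first.
    """

    def __init__(self, fields: dict[str, str], prefix: str = "Invalid field(s)"):
        self.fields = dict(fields)
        detail = "; ".join(f"{name}: {reason}" for name, reason in self.fields.items())
        super().__init__(f"{prefix}: {detail}")


class SelectionError(MsudBuddyError):
    """Formula selection failure; the empty-selection message is the
    literal string ``Please select formula``."""


class SchemaError(MsudBuddyError):
    """Serialized document violates its schema; names the first invalid path."""

    def __init__(self, path: str, reason: str):
        self.path = path
        super().__init__(f"Schema violation at {path}: {reason}")


class RuleRejectedError(MsudBuddyError):
    """Rule acquisition rejected (condition false on its cornerstone, or a
    stored cornerstone's conclusion would change)."""

    def __init__(self, message: str, conflicting_cornerstone: str | None = None):
        self.conflicting_cornerstone = conflicting_cornerstone
        super().__init__(message)


class InfeasiblePlanError(MsudBuddyError):
    """No safe feeding plan exists for the requested inputs."""


class StageError(MsudBuddyError):
    """Wraps an error from one stage of the recommendation pipeline,
    tagging it with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")
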