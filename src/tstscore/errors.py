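"""Exception hierarchy shared across the package."""

from __future__ import annotations


class TstScoreError(Exception):
    """Base class for all package errors."""


class ValidationError(TstScoreError):
    """A domain object violates one of its invariants.

    Carries the structured ``violations`` list when the failure came from
    table validation, so callers (and the CLI) can report row-level detail.
    """

    def __init__(self, message: str, violations: list | None = None):
        super().__init__(message)
        self.violations = violations or []


class FormatError(TstScoreError):
    """A file does not conform to the expected CSV dialect (missing or
    renamed columns, wrong column count for the manifest mode, ...)."""
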