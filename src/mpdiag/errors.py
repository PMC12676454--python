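"""Exception hierarchy shared across the package."""

from __future__ import annotations


class MpdError(Exception):
    """Base class for all package errors."""


class BnglSyntaxError(MpdError):
    """Malformed BNGL text.

    Carries the 1-based line (and, when known, column) where parsing failed.
    """

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", column {column}" if column is not None else "") + ")"
        super().__init__(message + loc)
        self.line = line
        self.column = column


class UnsupportedConstructError(MpdError):
    """A BNGL construct outside the supported dialect (names the construct)."""

    def __init__(self, construct: str, line: int | None = None):
        loc = f" (line {line})" if line is not None else ""
        super().__init__(f"unsupported construct: {construct}{loc}")
        self.construct = construct
        self.line = line


class ModelValidationError(MpdError):
    """A structurally invalid model, pattern, or rule."""


class UnsupportedRuleError(MpdError):
    """A rule that cannot be concretely expanded (e.g. wildcard-only products)."""


class ExpansionOverflowError(MpdError):
    """Species pool exceeded the configured cap during network expansion."""

    def __init__(self, cap: int):
        super().__init__(f"species pool exceeded cap of {cap}; raise the cap or lower max_iterations")
        self.cap = cap
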