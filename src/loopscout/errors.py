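"""Exception types shared across parsers, analyses, and the CLI."""

from __future__ import annotations


class ParseError(ValueError):
    """Raised when a pathway document cannot be parsed.

    Wraps the underlying XML error; ``line`` carries the 1-based source
    line when the backend reports one.
    """

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class CycleBudgetExceededError(RuntimeError):
    """Cycle enumeration aborted because the budget was exhausted.

    Elementary-circuit counts can grow exponentially with graph size, so
    enumeration is capped; the error names the offending pathway.
    """

    def __init__(self, pathway_id: str, max_cycles: int):
        super().__init__(
            f"cycle budget exceeded for pathway {pathway_id!r} "
            f"(more than {max_cycles} elementary circuits)"
        )
        self.pathway_id = pathway_id
        self.max_cycles = max_cycles
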