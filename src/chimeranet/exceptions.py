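"""Exception hierarchy shared across the package."""


class ChimeranetError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(ChimeranetError):
    """A sequence contains a character outside {A, U, G, C} (after T->U)."""

    def __init__(self, symbol: str, position: int, context: str = ""):
        self.symbol = symbol
        self.position = position  # 1-based, for human-readable messages
        prefix = f"{context}: " if context else ""
        super().__init__(
            f"{prefix}invalid symbol {symbol!r} at position {position}; "
            "sequences must contain only A, C, G, U (or T)"
        )


class FastaParseError(ChimeranetError):
    """Malformed FASTA input."""

    def __init__(self, message: str, line: int):
        self.line = line
        super().__init__(f"line {line}: {message}")


class ValidationError(ChimeranetError):
    """A dataset table row violates the length-110 / binary-label contract."""


class ChimeraTooLong(ChimeranetError):
    """miRNA + site concatenation exceeds the fixed chimera length."""


class PadGenerationFailure(ChimeranetError):
    """Rejection sampling for an anti-complementary pad exceeded the retry cap."""
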