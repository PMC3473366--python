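"""Exception hierarchy shared across the package."""


class LddrError(Exception):
    """Base class for all package-specific errors."""


class ParseError(LddrError):
    """A model document is syntactically or structurally malformed.

    ``path`` names the offending location in the document, e.g.
    ``terms[3].literals[0].threshold``.
    """

    def __init__(self, message: str, path: str = "$"):
        self.path = path
        super().__init__(f"{path}: {message}")


class ModelValidationError(LddrError):
    """A structurally well-formed model violates one or more invariants.

    All failures are collected and reported together.
    """

    def __init__(self, failures):
        self.failures = list(failures)
        super().__init__(
            "model validation failed:\n" + "\n".join(f"  - {f}" for f in self.failures)
        )


class UsageError(LddrError):
    """An operation was called with arguments that make no sense for it."""


class ReductionError(LddrError):
    """A component cannot be removed (input, output, or autoregulated)."""


class StateSpaceOverflowError(LddrError):
    """A state-transition-graph construction exceeded its configured cap."""


class AnalysisBudgetError(LddrError):
    """A combinatorial enumeration exceeded its configured budget."""


class UnsatisfiableConfigError(LddrError):
    """A random-model configuration requests mutually exclusive structure."""


class TranscriptionMissingError(LddrError):
    """An analysis needs the transcribed full curated network, which is not
    bundled and must be supplied by the user."""
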