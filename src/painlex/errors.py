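"""Exception hierarchy shared across the pipeline."""


class PainlexError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PainlexError):
    """A malformed input file; the message names the offending record/line."""


class EmptyCorpusError(PainlexError):
    """A reader produced a corpus with no documents."""


class ZeroTokenCorpusError(PainlexError):
    """A rate was requested against a corpus with zero tokens."""


class MissingSeedError(PainlexError):
    """The seed term is absent from a vector table.

    Carries the nearest orthographic matches to help diagnose typos.
    """

    def __init__(self, seed: str, suggestions: list[str]):
        self.seed = seed
        self.suggestions = suggestions
        hint = f"; nearest matches: {', '.join(suggestions)}" if suggestions else ""
        super().__init__(f"seed term {seed!r} not in vector table{hint}")


class CurveTooShortError(PainlexError):
    """Elbow analysis needs at least three points."""


class ConfigurationError(PainlexError):
    """Inconsistent build configuration (duplicate source ids, bad decisions...)."""


class InfeasibleSpecError(PainlexError):
    """A synthetic-data specification that cannot be realised."""
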