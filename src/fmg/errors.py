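"""Exception hierarchy for the false-memory list generator."""


class FMGError(Exception):
    """Base class for all package errors."""


class FormatError(FMGError):
    """A vector-space file violates the word2vec/GloVe text layout."""


class ValidationError(FMGError):
    """Input data violates a structural invariant (labels, vectors, rates)."""


class ConfigError(FMGError):
    """A generation parameter violates a configuration constraint."""


class GenerationError(FMGError):
    """List generation could not satisfy its geometric criteria."""


class InfeasibleError(GenerationError):
    """Not enough eligible items to fill a requested role or bin."""
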