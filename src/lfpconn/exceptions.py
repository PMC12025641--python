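"""Exception hierarchy shared across the toolkit."""


class LfpconnError(Exception):
    """Base class for all toolkit errors."""


class FormatError(LfpconnError):
    """An on-disk container is missing a required column/dataset."""


class ConsistencyError(LfpconnError):
    """Metadata tables and the data array disagree on dimensions."""


class ValidationError(LfpconnError):
    """A loaded or constructed object violates its invariants."""


class DegenerateInputError(LfpconnError):
    """Input is degenerate for the requested computation (e.g. zero variance)."""


class SingularityError(LfpconnError):
    """A matrix that must be invertible is singular or near-singular."""
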