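"""Exception hierarchy shared by all modules."""


class LabrecError(Exception):
    """Base class for every error raised by this package."""


class InputError(LabrecError):
    """The input stream could not be read at all."""


class FormatError(LabrecError):
    """The input is readable but violates the expected layout."""


class EmptyInputError(LabrecError):
    """An operation received an empty collection it cannot work on."""


class ConsistencyError(LabrecError):
    """Internal cross-references disagree (e.g. a test outside the universe)."""


class TestLookupError(LabrecError, KeyError):
    """A test code is not present in the universe / matrix."""


class ParameterError(LabrecError, ValueError):
    """A numeric parameter is outside its admissible range."""


class DomainError(LabrecError, ValueError):
    """The operation is undefined for these arguments (e.g. no candidates)."""


class DegeneratePriorError(LabrecError, ValueError):
    """Unsmoothed log-odds requested at a probability of exactly 0 or 1."""


class GenerationError(LabrecError, RuntimeError):
    """The synthetic generator exhausted its resampling budget."""
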