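"""Exception hierarchy for tcrars."""


class TcrarsError(Exception):
    """Base class for all tcrars errors."""


class FormatError(TcrarsError):
    """A repertoire or clinical file does not conform to the expected dialect."""


class EmptyRepertoireError(TcrarsError):
    """All clonotypes were removed (or the file contained none)."""


class ParameterError(TcrarsError):
    """An operation was called with an invalid parameter value."""


class StratificationError(TcrarsError):
    """A cohort cannot be split/stratified as requested (e.g. one label only)."""


class VocabularyMismatchError(TcrarsError):
    """Encoded inputs were produced with a different vocabulary than the model's."""


class UndefinedStatisticError(TcrarsError):
    """A statistic is undefined for the given input (e.g. zero-variance correlation)."""
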