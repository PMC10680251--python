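"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`SixmaStackError`, so callers (and the CLI) can distinguish domain
errors from genuine bugs.
"""


class SixmaStackError(Exception):
    """Base class for all package errors."""


class FastaParseError(SixmaStackError):
    """Malformed FASTA input; the message names the offending line."""


class AlphabetError(SixmaStackError):
    """A residue outside the DNA alphabet {A, C, G, T}."""


class EmptyInputError(SixmaStackError):
    """An input that contains no records."""


class DatasetConsistencyError(SixmaStackError):
    """Sequences violate a dataset-level contract (e.g. unequal lengths)."""


class ConfigurationError(SixmaStackError):
    """An invalid parameter value (window size, fold count, threshold...)."""


class StratificationError(ConfigurationError):
    """A class too small to stratify into the requested number of folds."""


class DegenerateFoldError(SixmaStackError):
    """A cross-validation training fold containing a single class."""


class ContractError(SixmaStackError):
    """Inputs incompatible with a fitted model's training-time layout."""


class SerializationError(SixmaStackError):
    """A model archive that cannot be loaded (corrupt or wrong version)."""


class UndefinedMetricError(SixmaStackError):
    """A metric whose defining ratio has a zero denominator."""
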