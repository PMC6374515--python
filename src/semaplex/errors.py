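"""Exception hierarchy.

Everything raised by semaplex derives from :class:`SemaplexError` so callers
can catch package failures with a single except clause.
"""


class SemaplexError(Exception):
    """Base class for all semaplex errors."""


class VocabularyError(SemaplexError, ValueError):
    """A token is not in the controlled domain vocabulary."""


class StructureError(SemaplexError, ValueError):
    """An architecture violates ordering/overlap constraints."""


class TableFormatError(SemaplexError, ValueError):
    """A tabular input file is malformed (missing columns, bad row)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnknownSpeciesError(SemaplexError, KeyError):
    """A species acronym is not part of the study taxon set."""


class TreeError(SemaplexError, ValueError):
    """A gene tree or species tree is invalid or unparseable."""


class ClassificationError(SemaplexError, ValueError):
    """A record cannot enter the classifier (e.g. no Sema domain)."""


class NamingError(SemaplexError, ValueError):
    """Tree-based naming failed (e.g. unclassified leaf)."""


class ParameterError(SemaplexError, ValueError):
    """An invalid parameter value (window size, rate, level...)."""
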