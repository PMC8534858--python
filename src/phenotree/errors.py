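"""Exception hierarchy for phenotree.

All package-specific failures derive from :class:`PhenotreeError` so callers
can catch one base class; subclasses distinguish contract violations
(format, integrity, configuration) from degenerate-data conditions.
"""


class PhenotreeError(Exception):
    """Base class for all phenotree errors."""


class FormatError(PhenotreeError):
    """A file or table does not match the expected layout."""


class EmptyInputError(PhenotreeError):
    """An operation received an empty table where content is required."""


class IntegrityError(PhenotreeError):
    """Cross-table consistency violated (e.g. conflicting labels)."""


class ConfigurationError(PhenotreeError):
    """A parameter is outside its documented range or schema."""


class StratificationError(PhenotreeError):
    """A class is too small to stratify into the requested parts."""


class DegenerateLabelsError(PhenotreeError):
    """An operation requiring both outcome classes saw only one."""


class UnknownCodeError(PhenotreeError, KeyError):
    """A clinical code is absent from the vocabulary."""
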