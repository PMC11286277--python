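"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`FragevoError`
so callers can catch chemistry, configuration and I/O failures uniformly.
"""


class FragevoError(Exception):
    """Base class for all package errors."""


class InputError(FragevoError):
    """Invalid user input, e.g. an unparsable SMILES string."""


class AssemblyError(FragevoError):
    """Fragments cannot be joined: unmatched or odd attachment points."""


class ValidityError(FragevoError):
    """An assembled structure failed chemical sanitization."""

    def __init__(self, message: str, attempted_smiles: str | None = None):
        super().__init__(message)
        self.attempted_smiles = attempted_smiles


class ConfigError(FragevoError):
    """Invalid task or optimizer configuration."""


class FragmentLookupError(FragevoError):
    """A fragment was not found among the leaves of a fragment tree."""


class DegenerateSpaceError(FragevoError):
    """The embedding space is too small to hold the requested population."""
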