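"""Exception hierarchy shared across the package."""


class PhenotripError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(PhenotripError, ValueError):
    """An argument violates an operation's precondition."""


class FormatError(PhenotripError, ValueError):
    """An input file or table does not match the expected format."""


class InvalidDatasetError(PhenotripError, ValueError):
    """A dataset cannot support the requested operation (e.g. one species)."""


class MissingFilesError(FormatError):
    """Metadata rows reference image files that do not exist."""

    def __init__(self, missing_ids):
        self.missing_ids = list(missing_ids)
        super().__init__(
            "missing image files for ids: " + ", ".join(map(str, self.missing_ids))
        )


class UndefinedCorrelationError(PhenotripError, ValueError):
    """A correlation is undefined because one input has zero variance."""


class DegenerateTestError(PhenotripError, ValueError):
    """A statistical test is degenerate (e.g. all observations tied)."""
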