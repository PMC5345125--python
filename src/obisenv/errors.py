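"""Exception hierarchy.

Every error raised by the library derives from :class:`ObisEnvError`, so
callers (and the command-line front end) can distinguish data problems from
programming errors with a single ``except`` clause.
"""


class ObisEnvError(Exception):
    """Base class for all errors raised by this package."""


# ---------------------------------------------------------------- model

class UnknownTermError(ObisEnvError, KeyError):
    """A term label is not present in the Darwin Core / eMoF registry."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return f"unknown term: {self.name!r}"


class MalformedValueError(ObisEnvError, ValueError):
    """A field value fails syntactic or range validation."""


# ------------------------------------------------------------- archives

class DescriptorError(ObisEnvError):
    """The meta.xml archive descriptor is unusable."""


class MalformedXMLError(DescriptorError):
    pass


class UnknownRowTypeError(DescriptorError):
    pass


class DuplicateCoreError(DescriptorError):
    """More than one <core> element: a star schema has a single centre."""


class MissingDescriptorError(ObisEnvError, FileNotFoundError):
    pass


class MissingDataFileError(ObisEnvError, FileNotFoundError):
    pass


class LayoutMismatchError(ObisEnvError):
    """The bundle's content does not fit the requested archive layout."""


# ------------------------------------------------------------ hierarchy

class DuplicateEventIDError(ObisEnvError):
    pass


class CycleError(ObisEnvError):
    """A parentEventID chain loops back on itself."""

    def __init__(self, cycle: list[str]):
        super().__init__(" -> ".join(cycle))
        self.cycle = cycle


class DanglingParentError(ObisEnvError):
    """A non-empty parentEventID names an event absent from the input."""

    def __init__(self, parent_id: str):
        super().__init__(parent_id)
        self.parent_id = parent_id


class UnknownEventError(ObisEnvError, KeyError):
    pass


class SeparatorInLabelError(ObisEnvError, ValueError):
    pass


class DepthExceedsLabelsError(ObisEnvError):
    pass


# -------------------------------------------------------------- options

class OptionMismatchError(ObisEnvError):
    """A conversion was asked for on a bundle in a different layout."""


class AmbiguousDummyError(ObisEnvError):
    """A dummy event wraps more than one occurrence."""


class OrphanEventError(ObisEnvError):
    """An event carries measurements but no occurrence to attach them to."""


class ValidationFailedError(ObisEnvError):
    """An operation requiring a clean bundle found ERROR-severity issues."""

    def __init__(self, issues):
        super().__init__(f"{len(issues)} blocking issue(s)")
        self.issues = list(issues)


# ------------------------------------------------------- vocab/fixtures

class MalformedRowError(ObisEnvError, ValueError):
    """A vocabulary or mapping file row cannot be parsed (carries line no)."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class SizeLimitError(ObisEnvError):
    pass


class InvalidSpecError(ObisEnvError, ValueError):
    pass
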