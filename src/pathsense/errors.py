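"""Exception hierarchy shared by all modules."""


class PathsenseError(Exception):
    """Base class for all package errors."""


class StructureParseError(PathsenseError):
    """Raised when a structure string cannot be parsed in its declared dialect."""

    def __init__(self, text: str, dialect: str, reason: str = "unparsable"):
        self.text = text
        self.dialect = dialect
        self.reason = reason
        super().__init__(f"cannot parse {dialect} structure {text!r}: {reason}")


class NormalizationError(PathsenseError):
    """Raised when normalization fails; carries offending atom indices when known."""

    def __init__(self, message: str, atom_indices: tuple[int, ...] = ()):
        self.atom_indices = atom_indices
        suffix = f" (atoms {list(atom_indices)})" if atom_indices else ""
        super().__init__(message + suffix)


class DiameterMismatchError(PathsenseError):
    """Signatures of different environment diameters were combined."""


class MatchingError(PathsenseError):
    """Raised when signature application is attempted without a valid embedding."""

    def __init__(self, message: str, violated_fragments: tuple[str, ...] = ()):
        self.violated_fragments = violated_fragments
        suffix = f"; violated fragments: {list(violated_fragments)}" if violated_fragments else ""
        super().__init__(message + suffix)


class KnowledgeBaseError(PathsenseError):
    """Raised on unrecoverable knowledge-base loading problems (missing files...)."""
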