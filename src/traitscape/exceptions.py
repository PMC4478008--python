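"""Exception hierarchy."""


class TraitscapeError(Exception):
    """Base class for all package errors."""


class ValidationError(TraitscapeError):
    """An input violates a structural invariant (ids, signs, shapes)."""


class NewickParseError(TraitscapeError):
    """Malformed newick input; carries a character offset when known."""

    def __init__(self, message, offset=None):
        super().__init__(message if offset is None
                         else f"{message} (near character {offset})")
        self.offset = offset


class EstimationError(TraitscapeError):
    """A trait-estimation precondition failed (too few labels, annotated query, ...)."""
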