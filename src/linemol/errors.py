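"""Exception hierarchy for linemol."""


class LinemolError(Exception):
    """Base class for all linemol errors."""


class GraphParseError(LinemolError):
    """Input text could not be parsed in the declared format."""


class GraphValidationError(LinemolError):
    """A graph violates a structural invariant (loop, duplicate edge,
    disconnected input passed to an operation requiring connectivity, ...)."""


class BudgetExceededError(LinemolError):
    """An iterated line-graph level would exceed the vertex budget."""


class InternalConsistencyError(LinemolError):
    """Two routes to the same quantity disagreed.

    This is never a user error: it signals a bug in the package and is
    deliberately loud rather than swallowed.
    """
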