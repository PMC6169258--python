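"""Exception hierarchy.

Every error raised by the library derives from :class:`ProvflowError`, so
callers (and the CLI) can catch one base class.  The subclasses mirror the
failure modes of the domain: invalid input, name conflicts, cycles in a
graph that must stay acyclic, references to unknown objects, illegal state
transitions, and analytics-specific failures.
"""


class ProvflowError(Exception):
    """Base class for all provflow errors."""


class ValidationError(ProvflowError):
    """Input violates a structural precondition (bad value, bad shape)."""


class ConflictError(ProvflowError):
    """A name that must be unique within its scope is already taken."""


class CycleError(ProvflowError):
    """The requested edge or parent link would create a cycle."""


class DomainError(ProvflowError):
    """A referenced object does not exist or belongs to the wrong scope."""


class StateError(ProvflowError):
    """Operation not allowed in the object's current lifecycle state."""


class NoPhaseError(ProvflowError):
    """No window of a growth curve satisfies the exponential-phase criteria."""


class SteadyStateError(ProvflowError):
    """Chemostat samples drift too much to be accepted as steady state."""


class IntegrationError(ProvflowError):
    """Fixed-step integration would be unstable with the requested step."""
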