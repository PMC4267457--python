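"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`FluxKitError`
so callers (and the CLI) can catch one type.
"""


class FluxKitError(Exception):
    """Base class for all fluxkit errors."""


class FormatError(FluxKitError):
    """A file could not be parsed (malformed XML, missing section, bad line)."""


class ModelValidationError(FluxKitError):
    """A model violates a structural invariant (dangling species, lb > ub, ...)."""


class UnknownIdError(FluxKitError, KeyError):
    """A reaction/gene/species/catalyst id is not present in the model."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return Exception.__str__(self)


class ConfigurationError(FluxKitError):
    """An operation was invoked without a required ingredient (e.g. no objective)."""


class SolverError(FluxKitError):
    """The LP backend failed in a way that is not plain infeasibility."""


class SizeCapError(FluxKitError):
    """A combinatorial enumeration was refused because the network is too large."""
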