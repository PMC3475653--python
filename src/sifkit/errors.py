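"""Exception hierarchy.

Integration blow-ups, missing threshold crossings and mutation-mapping
failures are distinct failure modes downstream code needs to tell apart,
so each gets its own class.
"""


class SifkitError(Exception):
    """Base class for all package errors."""


class ValidationError(SifkitError):
    """A model, table or config violates a structural invariant."""


class IntegrationError(SifkitError):
    """The ODE solver produced a non-finite state or failed to advance."""

    def __init__(self, message, species=None, time=None):
        super().__init__(message)
        self.species = species
        self.time = time


class NoCrossingError(SifkitError):
    """A requested threshold crossing does not occur within the horizon.

    Deliberately distinct from :class:`IntegrationError`: the trajectory is
    fine, the event simply never happens.
    """


class ReadoutError(SifkitError):
    """A readout could not be evaluated on a (perturbed) model."""

    def __init__(self, message, label=None):
        super().__init__(message)
        self.label = label


class MappingError(SifkitError):
    """A mutation has no entry in the protein/class -> channel mapping."""
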