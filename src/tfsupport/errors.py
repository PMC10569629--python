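"""Exception hierarchy for the tfsupport package."""


class TFSupportError(Exception):
    """Base class for all package errors."""


class ParameterError(TFSupportError, ValueError):
    """A muscle-tendon parameter violates its physiological/stability invariants."""


class InputError(TFSupportError, ValueError):
    """An input series or argument violates a precondition."""


class ConfigError(TFSupportError, ValueError):
    """A configuration/mapping problem (e.g. missing EMG channel for an MTU)."""


class GeometryError(TFSupportError, ValueError):
    """A geometrically impossible state (e.g. fibre shorter than its pennation height)."""


class EquilibriumError(TFSupportError, RuntimeError):
    """The compliant-tendon equilibrium has no root in the search bracket.

    Carries the frame index (and optionally MTU name / trial id) where the
    solve failed so failures in long batch runs are attributable.
    """

    def __init__(self, message: str, frame: int | None = None, mtu: str | None = None):
        super().__init__(message)
        self.frame = frame
        self.mtu = mtu
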