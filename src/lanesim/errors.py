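"""Exception hierarchy shared across the package."""


class LaneSimError(Exception):
    """Base class for all lanesim errors."""


class ConfigError(LaneSimError):
    """Invalid or inconsistent configuration input."""


class DegeneratePairError(LaneSimError):
    """Two particles coincide after the minimum-image convention.

    The torque between coincident particles is undefined (the
    centre-to-centre direction has no meaning), and the model has no
    excluded volume to prevent it, so we abort rather than regularize.
    """

    def __init__(self, indices=None):
        self.indices = indices
        msg = "coincident particle pair encountered"
        if indices is not None:
            msg += f": {indices}"
        super().__init__(msg)


class ConvergenceError(LaneSimError):
    """A numerical result changed beyond tolerance under step refinement."""

    def __init__(self, msg, estimates=None):
        super().__init__(msg)
        self.estimates = estimates


class NonStationaryError(LaneSimError):
    """A time series does not decorrelate within the available window."""


class LaneStateError(LaneSimError):
    """A measurement is undefined in the phase-separated (lane) state."""


class ClosureValidityError(LaneSimError):
    """Kinetic-theory closure evaluated outside its regime of validity."""


class StabilityError(LaneSimError):
    """Linearized hydrodynamic parameters are unstable on the requested grid."""

    def __init__(self, msg, modes=None):
        super().__init__(msg)
        self.modes = modes


class TransitionNotBracketedError(LaneSimError):
    """A parameter sweep does not straddle the critical point."""
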