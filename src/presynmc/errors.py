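"""Exception hierarchy shared across the package."""


class PresynError(Exception):
    """Base class for all presynmc errors."""


class ConfigurationError(PresynError):
    """A scheme, rate table, or run configuration is invalid."""


class TimestepTooLargeError(ConfigurationError):
    """A row's total exit probability k_ij * dt reached or exceeded 1.

    Carries the offending state and the largest admissible timestep so the
    caller can report something actionable instead of silently renormalizing
    (which would change the stochastic process).
    """

    def __init__(self, state_name: str, dt: float, dt_max: float):
        self.state_name = state_name
        self.dt = dt
        self.dt_max = dt_max
        super().__init__(
            f"timestep {dt:g} s too large for state {state_name!r}: "
            f"total exit probability >= 1; require dt < {dt_max:g} s"
        )


class ContractError(PresynError):
    """An internal contract was violated (e.g. a non-stochastic matrix)."""


class FormatError(PresynError):
    """A text input (voltage trace, config file) could not be parsed."""
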