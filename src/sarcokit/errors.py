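"""Exception types shared across sarcokit modules."""


class InvalidSpecificationError(ValueError):
    """An input value violates a documented precondition (negative
    concentration, fraction outside [0, 1], non-positive scale, ...)."""


class TimestepError(ValueError):
    """The requested Monte-Carlo timestep violates the stability guard.

    Carries the largest admissible step in :attr:`required_dt`.
    """

    def __init__(self, message: str, required_dt: float):
        super().__init__(message)
        self.required_dt = required_dt


class FitError(RuntimeError):
    """A least-squares fit failed or was degenerate.

    ``diagnostics`` holds whatever partial information the fitter could
    salvage (starting points tried, best residual, parameter snapshots).
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class CalibrationError(RuntimeError):
    """An ADP-calibration step in an NADH absorbance record was unusable
    (zero or positive absorbance step)."""
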