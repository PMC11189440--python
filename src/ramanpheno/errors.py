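"""Exception types shared across the package."""


class SpectraFormatError(ValueError):
    """A spectra/band table file violates the expected layout or invariants."""


class CalibrationError(RuntimeError):
    """Axis calibration failed (too few reference peaks, non-monotone map)."""


class ConvergenceError(RuntimeError):
    """The optimizer did not reach the requested tolerance within its cap."""


class LeakageError(RuntimeError):
    """A cell appears on both sides of a train/evaluation boundary."""
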