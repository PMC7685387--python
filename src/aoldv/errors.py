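"""Exception hierarchy shared across the pipeline."""


class AoldvError(Exception):
    """Base class for all package errors."""


class InvalidInputError(AoldvError):
    """An input value violates a precondition (exit code 2 at the CLI)."""


class InvalidGeometryError(InvalidInputError):
    """Optical/geometric parameters are physically inadmissible."""


class InvalidScenarioError(InvalidInputError):
    """A synthetic scenario cannot be realised (e.g. cutoff beyond Nyquist)."""


class NoMeasurementError(AoldvError):
    """Every frame failed quality control; no quantity can be reported (exit code 3)."""
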