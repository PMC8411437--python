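"""Exception hierarchy shared across the package."""


class AddiError(Exception):
    """Base class for all addikit errors."""


class InputError(AddiError, ValueError):
    """Malformed or out-of-domain input (bad measurement, unknown grade...)."""


class ApplicabilityError(InputError):
    """Evidence asserted for an item the case cannot carry (age/sex rules)."""


class InstrumentError(AddiError, ValueError):
    """Instrument definition violates a structural invariant."""


class DegenerateVarianceError(AddiError, ValueError):
    """A reliability statistic is undefined because all scores coincide."""


class GenerationError(AddiError, RuntimeError):
    """Synthetic study constraints could not be satisfied."""


class CalibrationError(AddiError, RuntimeError):
    """Noise calibration failed to bracket or reach the target reliability."""
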