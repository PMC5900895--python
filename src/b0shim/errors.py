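"""Exception hierarchy for the b0shim package."""


class B0ShimError(Exception):
    """Base class for all b0shim errors."""


class ConfigurationError(B0ShimError, ValueError):
    """Invalid configuration (e.g. grid too small to contain the head model)."""


class SingularFitError(B0ShimError, ValueError):
    """Rank-deficient least-squares design.

    Carries the names of the harmonic terms that are unresolvable with the
    given mask, so callers can see *which* shim terms the data cannot
    constrain instead of getting silently truncated coefficients.
    """

    def __init__(self, deficient_terms):
        self.deficient_terms = tuple(deficient_terms)
        super().__init__(
            "singular harmonic fit; unresolvable terms: "
            + ", ".join(self.deficient_terms)
        )


class UnknownTermError(B0ShimError, KeyError):
    """A shim setting refers to harmonic terms absent from the basis."""

    def __init__(self, terms):
        self.terms = tuple(terms)
        super().__init__("unknown shim terms: " + ", ".join(self.terms))


class DegenerateCalibrationError(B0ShimError, ValueError):
    """Shim-coil calibration attempted with no variation in hardware settings."""


class SpaceMismatchError(B0ShimError, ValueError):
    """Affine transforms chained in an order their space labels forbid."""


class RegistrationError(B0ShimError, RuntimeError):
    """Image registration failed to produce a usable transform."""


class FormatError(B0ShimError, ValueError):
    """Malformed input file (NIfTI header, transform text, shim JSON)."""


class LeakageError(B0ShimError, RuntimeError):
    """A cross-validation strategy saw data from the held-out subject."""
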