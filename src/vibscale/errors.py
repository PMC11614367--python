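"""Exception hierarchy for vibscale.

All package-specific failures derive from :class:`VibscaleError` so callers
can catch one base class at the CLI boundary.
"""


class VibscaleError(Exception):
    """Base class for all vibscale errors."""


class InvalidMoleculeError(VibscaleError):
    """A molecule record violates a structural invariant (e.g. n_atoms < 2)."""


class InvalidFrequencyError(VibscaleError):
    """A wavenumber is zero or negative (imaginary harmonic frequency)."""


class ModeCountMismatchError(VibscaleError):
    """Experimental and computed mode counts disagree in a way the
    linear-molecule drop rule cannot resolve."""


class EmptyDatasetError(VibscaleError):
    """No usable frequency pairs were produced."""


class DegenerateInputError(VibscaleError):
    """Least-squares input is unusable (length mismatch, all-zero x, ...)."""


class InvalidScaleError(VibscaleError):
    """A scale factor or threshold is not strictly positive."""


class EmptySpectrumError(VibscaleError):
    """A stick spectrum with no lines was passed to an operation that
    requires at least one."""


class ConfigurationError(VibscaleError):
    """A synthetic-data configuration is invalid or produces pathological
    output (e.g. >1% non-positive frequencies before clipping)."""


class SchemaError(VibscaleError):
    """A dataset file does not conform to the documented JSON layout."""
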