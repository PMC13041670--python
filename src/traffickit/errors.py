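"""Exception types shared across the pipeline."""


class TraffickitError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(TraffickitError):
    """A simulation or analysis configuration violates its invariants."""


class IntegrityError(TraffickitError):
    """Internally inconsistent data (e.g. non-monotone funnel counts)."""


class FitError(TraffickitError):
    """A model fit failed or the target parameter is unidentifiable."""
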