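"""Exception hierarchy shared across the pipeline stages."""


class HarvestomicsError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(HarvestomicsError, ValueError):
    """A caller supplied an argument outside the documented domain."""


class InvalidInputError(HarvestomicsError, ValueError):
    """Input data violate a stage precondition (e.g. missing QC rows)."""


class InsufficientQCError(InvalidInputError):
    """Fewer pooled-QC injections than drift correction requires."""


class NotEstimableError(HarvestomicsError, RuntimeError):
    """A quantity (e.g. IC50) cannot be estimated from the given data."""


class OutOfRangeError(HarvestomicsError, ValueError):
    """A value lies outside the calibrated/interpolable range."""
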