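"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`MrError`,
so callers can catch one type. Validation problems (bad alleles, a
non-positive SE, an asymmetric LD matrix) raise :class:`ValidationError`;
misconfigured inputs (a missing column mapping, an unknown scenario name)
raise :class:`ConfigurationError`; estimators that cannot run on the data
they were given raise :class:`EstimationError` or one of its subclasses.
"""


class MrError(Exception):
    """Base class for all errors raised by twosample_mr."""


class ValidationError(MrError, ValueError):
    """A data object violates one of its invariants."""


class ConfigurationError(MrError, ValueError):
    """User-supplied configuration is inconsistent or incomplete."""


class HarmonizationError(MrError):
    """Exposure and outcome tables cannot be harmonized at all."""


class EstimationError(MrError):
    """An estimator cannot produce an estimate from the given data."""


class InfeasibleEstimatorError(EstimationError):
    """Too few SNPs (or an unsupported LD structure) for the method."""


class EmptyInstrumentSetError(MrError):
    """Every candidate instrument was excluded upstream."""
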