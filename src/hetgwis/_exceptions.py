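"""Exception hierarchy shared across the package."""


class HetgwisError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HetgwisError):
    """A file could not be parsed under the declared dialect."""


class ValidationError(HetgwisError):
    """An in-memory object violates a documented invariant."""


class ConfigError(HetgwisError):
    """Run configuration is missing keys or holds out-of-range values."""


class ScenarioError(HetgwisError):
    """A simulation scenario is internally inconsistent."""


class DesignError(HetgwisError):
    """A model specification cannot be turned into a design matrix."""


class FitError(HetgwisError):
    """Model fitting failed in a way that is not a mere non-convergence."""


class CollinearityError(FitError):
    """Design columns are numerically collinear; offending columns are named."""


class NotPositiveDefiniteError(HetgwisError):
    """A covariance matrix supplied by direct construction is not PD."""


class OptimizationQualityError(HetgwisError):
    """A nested fit attained a higher likelihood than its parent model."""


class PCAError(HetgwisError):
    """Principal-component computation is impossible on the given input."""


class ScreeningError(HetgwisError):
    """A per-SNP screening statistic is undefined (e.g. all calls missing)."""


class TestError(HetgwisError):
    """A hypothesis test cannot be carried out on the given data."""

    __test__ = False  # keep pytest collection away


class SelectionError(HetgwisError):
    """Model selection had no convergent candidate."""


class ContractError(HetgwisError):
    """An API contract was violated by the caller (e.g. SNP terms during selection)."""
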