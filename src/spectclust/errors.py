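"""Exception hierarchy for spectclust.

All errors raised by the library derive from :class:`SpectclustError` so that
pipeline code can catch library failures in one place.
"""


class SpectclustError(Exception):
    """Base class for all spectclust errors."""


class DimensionalityError(SpectclustError):
    """An image or array does not have the expected number of dimensions."""


class MetadataError(SpectclustError):
    """Image metadata (e.g. the energy axis) is missing or inconsistent."""


class BoundsError(SpectclustError):
    """An index range is empty or falls outside the volume extents."""


class EnergyAxisError(SpectclustError):
    """A requested energy level is absent from the volume's energy axis."""


class EmptyDatasetError(SpectclustError):
    """An operation produced or received a dataset with zero voxels."""


class InvariantViolationError(SpectclustError):
    """A domain-type invariant was violated (e.g. duplicate voxel indices)."""


class SingularDesignError(SpectclustError):
    """The (weighted) basis design matrix is rank-deficient."""


class UnderdeterminedBasisError(SpectclustError):
    """More basis functions than energy levels were requested."""


class ParameterError(SpectclustError):
    """A model or configuration parameter is outside its valid range."""


class SPDViolationError(SpectclustError):
    """A covariance matrix is not symmetric positive definite."""


class EmptyClusterError(SpectclustError):
    """A mixture component received zero total responsibility."""


class UndefinedMetricError(SpectclustError):
    """A cluster-validity metric is undefined for the given labeling."""


class NumericalFailureError(SpectclustError):
    """An iterative numerical routine produced non-finite values."""


class SearchError(SpectclustError):
    """A hyper-parameter search had no successful cell."""
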