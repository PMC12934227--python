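"""Exception hierarchy for cranioquant.

Every failure mode of the pipeline maps onto one of these, so callers
(and the CLI) can distinguish bad inputs from degenerate geometry from
statistical underdetermination.
"""


class CranioquantError(Exception):
    """Base class for all package errors."""


class MeshFormatError(CranioquantError):
    """A mesh file parsed but violates structural expectations
    (e.g. non-triangular faces)."""


class TopologyError(CranioquantError):
    """Operation requires a watertight / consistently oriented mesh."""


class DegenerateGeometryError(CranioquantError):
    """Geometry carries no usable signal (e.g. all faces zero-area)."""


class ParameterError(CranioquantError):
    """A parameter is out of its valid range or inconsistent with the data."""


class EmptyAfterFilterError(CranioquantError):
    """A filtering step removed every observation."""


class InsufficientDataError(CranioquantError):
    """Not enough observations to run the requested estimator or test."""
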