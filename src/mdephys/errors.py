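"""Exception hierarchy shared across the package."""


class MdephysError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MdephysError):
    """Sweep-table or sidecar file does not match the expected layout."""


class SamplingError(MdephysError):
    """Time base is non-uniform or inconsistent with the stated rate."""


class ConsistencyError(MdephysError):
    """Sidecar metadata disagrees with the data it describes."""


class ValidationError(MdephysError):
    """A domain-type invariant is violated."""


class DomainError(MdephysError):
    """An operation was called on input outside its domain."""


class AlignmentError(MdephysError):
    """Two sweeps that must share timing do not."""


class WindowError(MdephysError):
    """A requested analysis window extends past the recorded trace."""


class ContaminationError(MdephysError):
    """Spikes detected in a trace that must be spike-free."""


class NumericalError(MdephysError):
    """The integrator or a solver failed to converge."""
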