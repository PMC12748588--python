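"""Exception hierarchy shared across the pipeline."""


class CoevodockError(Exception):
    """Base class for all package errors."""


class InvalidModelError(CoevodockError):
    """A generative model specification is malformed (bad lengths, q < 2, ...)."""


class ConstructiveFailureError(CoevodockError):
    """A requested synthetic geometry cannot be realized."""


class MsaFormatError(CoevodockError):
    """An alignment file violates the format contract (e.g. ragged rows)."""


class EmptyPairingError(CoevodockError):
    """Two alignments share no species, so no paired rows can be built."""


class ParameterError(CoevodockError):
    """A numeric argument is outside its documented domain."""


class CapabilityError(CoevodockError):
    """The input lacks the data an operation needs (e.g. SASA on a bead model)."""


class StructureFormatError(CoevodockError):
    """A coordinate file cannot be parsed."""


class LookupFailure(CoevodockError):
    """A (chain, residue) key is absent from a structure."""


class PlacementError(CoevodockError):
    """No clash-free initial placement could be found."""


class UnstableRunError(CoevodockError):
    """Dynamics diverged; reduce the timestep."""
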