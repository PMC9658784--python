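"""Exception hierarchy shared across the framework."""


class FhenetError(Exception):
    """Base class for all framework errors."""


class UnknownNodeError(FhenetError, KeyError):
    """A node name does not exist in the graph."""


class ReceptorError(FhenetError):
    """A node does not expose the requested receptor."""


class CycleError(FhenetError):
    """A non-self cycle was encountered during traversal."""


class ArityError(FhenetError):
    """A generator output was exhausted before all outbound edges were served."""


class ShapeError(FhenetError, ValueError):
    """Tensor shapes are inconsistent with the requested operation."""


class StateError(FhenetError):
    """An operation was requested in an invalid node/graph state."""


class ConfigError(FhenetError, ValueError):
    """A run or network configuration is inconsistent."""


class ParseError(FhenetError, ValueError):
    """An input file could not be parsed."""


class ConsistencyError(FhenetError):
    """Parameter groups and graph contents disagree."""


class DivergenceError(FhenetError):
    """Training produced a non-finite loss."""


class FHEError(FhenetError):
    """Base class for cyphertext arithmetic errors."""


class CapacityError(FHEError, ValueError):
    """Message longer than the cyphertext slot capacity."""


class DepthExhaustedError(FHEError):
    """The modulus switching chain is spent; rotation or refresh is required."""


class InteroperabilityError(FHEError):
    """Two cyphertexts are not identical containers (key/params mismatch)."""


class KeyMismatchError(InteroperabilityError):
    """Decryption or interoperation attempted with the wrong key."""


class NoiseError(FHEError):
    """Accumulated noise exceeds the garble threshold at decryption."""


class FHEIncompatibilityError(FHEError, TypeError):
    """A plaintext-only operation (softmax, argmax, ...) was fed a cyphertext."""
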