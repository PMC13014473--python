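"""Exception hierarchy for squigseg.

Every error raised by the library derives from :class:`SquigsegError` so
callers can catch the whole family with one clause.
"""


class SquigsegError(Exception):
    """Base class for all squigseg errors."""


class ModelFormatError(SquigsegError):
    """Pore-model file is structurally malformed (ragged k-mers, bad header)."""


class ModelCompletenessError(SquigsegError):
    """Pore-model file does not cover all |alphabet|^k k-mers."""


class ModelValidationError(SquigsegError):
    """Pore-model entries violate invariants (non-positive stdv, non-finite mean)."""


class DegenerateSignalError(SquigsegError):
    """Signal cannot be normalized (e.g. MAD of a constant trace is 0)."""


class InfeasibleReadError(SquigsegError):
    """Signal too short for the HMM topology (T < 2 * number of k-mers)."""


class BandError(SquigsegError):
    """Band excludes the origin/terminal cell or admits no legal path."""


class PairingError(SquigsegError):
    """Signal and basecalled read identifiers do not match."""


class NumericalConsistencyError(SquigsegError):
    """Forward/backward quantities drifted beyond numerical tolerance."""


class InputError(SquigsegError):
    """Invalid user-supplied value (non-finite sample, bad parameter)."""
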