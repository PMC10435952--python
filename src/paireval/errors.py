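"""Exception hierarchy shared across the package."""


class PairedEvalError(Exception):
    """Base class for all paireval errors."""


class ConfigurationError(PairedEvalError):
    """A DeltaSpec / CVPlan / ConfounderSpec is internally inconsistent."""


class InputError(PairedEvalError):
    """Invalid user-supplied data (duplicate ids, too few samples, ...)."""


class UndefinedAUCError(PairedEvalError):
    """AUC requested over an empty set of rankable pairs."""


class UnsupportedModeError(PairedEvalError):
    """Operation not valid for the requested rankability mode."""


class CoverageError(PairedEvalError):
    """A sample required downstream received no out-of-fold prediction."""


class AlignmentError(PairedEvalError):
    """Two verdict lists do not cover the same rankable pairs."""
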