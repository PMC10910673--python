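"""Exception hierarchy for the MR screening pipeline."""


class MRScreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRScreenError):
    """A configuration (column map, YAML, threshold) is unusable."""


class InputError(MRScreenError):
    """An input table violates a structural precondition."""


class ComputationError(MRScreenError):
    """A numeric routine received values outside its domain."""


class InsufficientInstrumentsError(MRScreenError):
    """Fewer instruments than the estimator requires."""


class CollinearityError(MRScreenError):
    """A design matrix is rank deficient."""


class IncompleteEvidenceError(MRScreenError):
    """A ledger is being built without every required diagnostic."""
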