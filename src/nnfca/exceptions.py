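"""Exception hierarchy for nnfca."""


class NNFCAError(Exception):
    """Base class for all nnfca errors."""


class SchemaError(NNFCAError):
    """A column required by the feature specs is absent or malformed."""


class ValidationError(NNFCAError):
    """Input values violate a documented precondition."""


class DegenerateInputError(NNFCAError):
    """An operation received an empty or single-class table it cannot use."""


class TrainingError(NNFCAError):
    """Training diverged (non-finite loss); carries the offending epoch."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch


class ConfigurationError(NNFCAError):
    """A simulation or network configuration is infeasible."""


class StageError(NNFCAError):
    """A stepwise-elimination stage could not be completed."""
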