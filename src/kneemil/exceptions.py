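"""Shared exception types."""


class ConfigurationError(ValueError):
    """A configuration field has an invalid value."""


class ContractError(ValueError):
    """An operation was called with inputs violating its contract."""


class InputError(ValueError):
    """Invalid data input (empty volume, zero vector, missing modality...)."""


class MetricUndefinedError(ValueError):
    """Metric undefined for the given labels (e.g. single-class AUROC)."""


class LeakageError(RuntimeError):
    """Exam identifiers overlap across train/validation/test splits."""


class ProtocolError(ValueError):
    """Multi-seed protocol invariants violated (e.g. mismatched seed sets)."""


class SolverError(RuntimeError):
    """Optimization diverged or produced non-finite values."""
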