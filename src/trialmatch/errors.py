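"""Exception hierarchy for trialmatch."""


class TrialMatchError(Exception):
    """Base class for all trialmatch errors."""


class SchemaError(TrialMatchError):
    """An input table is missing required columns or has unparseable values."""


class IntegrityError(TrialMatchError):
    """Referential integrity between tables is violated."""


class ValidationError(TrialMatchError):
    """A value-level invariant (hierarchy acyclicity, date ordering, ...) fails."""


class ConfigError(TrialMatchError):
    """A run or simulation configuration is inconsistent or incomplete."""
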