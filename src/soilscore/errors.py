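"""Exception hierarchy.

Three error families mirror the three ways a run can go wrong: the
configuration is inconsistent (battery, curves, practices, weights), an
input record violates an invariant, or an evaluation cannot be carried
out for a particular record/stratum.
"""


class SoilScoreError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SoilScoreError):
    """A battery / practice / aggregation config is invalid."""


class InputError(SoilScoreError):
    """An input record or table violates a domain invariant."""


class EvaluationError(SoilScoreError):
    """An indicator could not be evaluated for a given record."""
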