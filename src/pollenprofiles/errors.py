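"""Exception hierarchy for the pipeline.

All validation errors name the offending record (line, field, user, date)
so a failing run can be traced back to its input.
"""


class PollenProfilesError(Exception):
    """Base class for all package errors."""


class ValidationError(PollenProfilesError):
    """An input record violates an invariant (duplicate date, negative
    concentration, unordered phenology dates, ...)."""


class ParseError(PollenProfilesError):
    """A field could not be parsed (malformed date or number)."""


class NoSeasonError(PollenProfilesError):
    """A pollen year carries zero total pollen; no season can be defined."""


class DegeneratePartitionError(PollenProfilesError):
    """A three-way split collapsed (cut1 == cut2, or a cut hit the season
    boundary); the partition would not have three non-empty sections."""


class ConfigError(PollenProfilesError):
    """Run configuration is inconsistent (empty taxon group, bad alpha, ...)."""


class InsufficientDataError(PollenProfilesError):
    """Too few observations for the requested operation (e.g. fewer
    observed days than the imputation neighbourhood size k)."""
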