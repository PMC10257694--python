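"""Exception hierarchy for gpscore.

Every error raised on a user-facing code path derives from :class:`GpsError`
so callers can catch the package's failures with a single except clause.
"""


class GpsError(Exception):
    """Base class for all gpscore errors."""


class MissingColumn(GpsError):
    """A mandatory column is absent from an input table."""


class MalformedValue(GpsError):
    """A cell holds a value the schema forbids (e.g. non-finite subscore)."""


class NotScored(GpsError):
    """An operation requiring discriminant scores got an unscored table."""


class TooFewRecords(GpsError):
    """Fewer records than an algorithm's minimum (folds, density fits...)."""


class DegenerateLabels(GpsError):
    """A training partition contains only one class."""


class SchemaMismatch(GpsError):
    """Feature names differ between a model/table pair or across tables."""


class EmptyInput(GpsError):
    """An aggregation got no records at all."""


class EmptySelection(GpsError):
    """A selection step (e.g. RT anchors) has nothing to select from."""


class ConfigurationError(GpsError):
    """An invalid configuration value (bad enum, threshold outside [0,1]...)."""
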