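"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`VolataxError`
so the CLI can turn any of them into a one-line diagnostic.
"""


class VolataxError(Exception):
    """Base class for all volatax errors."""


class FormatError(VolataxError):
    """Malformed input file (duplicate ids, negative values, bad columns)."""


class ConsistencyError(VolataxError):
    """Metadata is internally inconsistent (e.g. a replicate group spanning
    two a-priori groups, or a peak-table sample missing from the metadata)."""


class ConfigurationError(VolataxError):
    """Unknown metric/transform name or invalid plan parameter."""


class DegenerateInputError(VolataxError):
    """Input is structurally valid but too degenerate to analyse
    (all-zero table, no positive eigenvalues, no feasible axis count)."""


class GroupingError(VolataxError):
    """Invalid a-priori grouping (empty group, single group, ...)."""


class CascadeError(VolataxError):
    """A cascade round cannot run; carries the round id as context."""


class KeyConstructionError(VolataxError):
    """A terminal taxon ended up without any essential biomarker."""


class SchemaVersionError(FormatError):
    """A serialized artifact declares an unsupported schema version."""


class VocabularyError(VolataxError):
    """An unknown profile shares no compounds with the reference."""


class SyntheticSpecError(VolataxError):
    """A synthetic-dataset specification is infeasible."""
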