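"""Exception hierarchy for bacikit."""


class BaciError(Exception):
    """Base class for all package-specific failures."""


class ConfigurationError(BaciError, ValueError):
    """A cohort or analysis configuration is internally inconsistent."""


class SchemaError(BaciError, ValueError):
    """An input table does not conform to the documented CSV schema."""


class MatchingError(BaciError, ValueError):
    """Control matching cannot proceed (e.g. empty candidate pool)."""
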