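"""Exception hierarchy for pvcalib."""


class PvcalibError(Exception):
    """Base class for all pvcalib errors."""


class ConfigError(PvcalibError):
    """A configuration file or object is invalid or unresolvable."""


class CohortSchemaError(PvcalibError):
    """A cohort table is missing mandatory columns or has malformed labels."""


class ScoreParseError(PvcalibError):
    """A score cell could not be parsed as a number."""

    def __init__(self, row: str, column: str, value: str):
        self.row = row
        self.column = column
        self.value = value
        super().__init__(
            f"non-numeric score {value!r} in column {column!r}, row {row!r}"
        )


class ScoreRangeError(PvcalibError):
    """A score lies outside its instrument's declared range (or violates
    integrality on an integer-valued scale)."""

    def __init__(self, row: str, column: str, value: float, reason: str):
        self.row = row
        self.column = column
        self.value = value
        super().__init__(
            f"score {value!r} in column {column!r}, row {row!r}: {reason}"
        )


class UnmappableScoreError(PvcalibError):
    """A raw score falls in a gap between recoding bands."""

    def __init__(self, instrument: str, value: float):
        self.instrument = instrument
        self.value = value
        super().__init__(
            f"score {value!r} on {instrument!r} falls outside every recoding band"
        )
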