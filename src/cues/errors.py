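"""Exception hierarchy for the cues package."""


class CuesError(Exception):
    """Base class for all package-specific errors."""


class TableError(CuesError):
    """A reference table (anchors or gazetteer) is malformed or empty."""


class UnknownPlaceError(CuesError):
    """A "City, State" string could not be resolved against the gazetteer."""

    def __init__(self, place: str):
        self.place = place
        super().__init__(f"unknown place: {place!r}")


class ExclusionError(CuesError):
    """A respondent falls under a study exclusion rule (e.g. diagnosis before 18)."""


class ConvergenceError(CuesError):
    """A model fit failed to converge (e.g. complete separation in a matched set)."""
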