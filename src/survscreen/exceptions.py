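"""Error types shared across the screening pipeline.

Gene-level failures carry a category so the run log can report the same
taxonomy the screen uses everywhere: ``one-group-logrank`` (a cut or median
split left one group empty or event-free), ``one-group-cox`` (a Cox
covariate was constant in the analysis subset), and ``unknown``.
"""

FAILURE_CATEGORIES = ("one-group-logrank", "one-group-cox", "unknown")


class SurvScreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SurvScreenError):
    """Bad user input: missing columns, unreadable files, invalid options."""


class CohortMergeError(SurvScreenError):
    """Clinical and expression patient identifiers do not intersect."""


class IncompleteProfileError(SurvScreenError):
    """A clinical profile is missing a field required for dichotomization."""

    def __init__(self, field: str):
        self.field = field
        super().__init__(f"clinical profile is missing or has an invalid value for {field!r}")


class GeneAnalysisError(SurvScreenError):
    """A single gene could not be analyzed; carries a failure category."""

    def __init__(self, category: str, message: str):
        if category not in FAILURE_CATEGORIES:
            category = "unknown"
        self.category = category
        super().__init__(message)


class OneGroupError(GeneAnalysisError):
    """All observations fell into (or all events occurred in) one group."""

    def __init__(self, category: str, message: str):
        super().__init__(category, message)


class EmptyGridError(SurvScreenError):
    """The requested percentile band contains no candidate cut position."""
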