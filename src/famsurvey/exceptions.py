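"""Exception hierarchy for the survey pipeline."""


class FamSurveyError(Exception):
    """Base class for all package errors."""


class FormatError(FamSurveyError):
    """Malformed on-disk input (FASTA/GFF3/TSV)."""


class ConsistencyError(FamSurveyError):
    """Structurally valid input that violates a semantic contract."""


class AlphabetError(FamSurveyError):
    """Sequence contains characters outside the permitted alphabet."""


class SizingError(FamSurveyError):
    """Synthetic-genome configuration does not fit the stated budgets."""


class ParameterError(FamSurveyError):
    """Out-of-range parameter value."""


class ConfigError(FamSurveyError):
    """Pipeline configuration is incomplete or inconsistent."""


class UndefinedDistanceError(FamSurveyError):
    """A pairwise distance could not be computed (no shared ungapped sites)."""


class ComparisonError(FamSurveyError):
    """Promoter allele comparison refused (alignment degenerate)."""
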