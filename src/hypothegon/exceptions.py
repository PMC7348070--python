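"""Exception hierarchy shared across the package."""


class HypothegonError(Exception):
    """Base class for all package errors."""


class MalformedJudgmentError(HypothegonError):
    """A probability triple fails simplex validation (sum or sign)."""


class OutOfSimplexError(HypothegonError):
    """A plane point lies outside the reference triangle."""


class ConfigurationError(HypothegonError):
    """An invalid parameter value or unknown identifier in a configuration."""


class DegenerateEvidenceError(HypothegonError):
    """All-zero evidence: no hypothesis assigns the observation any likelihood."""


class DataError(HypothegonError):
    """Malformed or inconsistent input data (files, tables, case references)."""


class GeneratorError(HypothegonError):
    """The synthetic-data sampler cannot produce draws (pathological settings)."""
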