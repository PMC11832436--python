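"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """An invalid simulation or analysis configuration."""


class ParseError(ValueError):
    """A malformed input file; the message carries the offending line/id."""


class EmptyOverlapError(ValueError):
    """A gene set shares no members with the ranked universe.

    Distinct from an enrichment score of zero: the statistic is undefined.
    """


class FullCoverageError(ValueError):
    """A gene set covers the entire ranked universe; the miss increment
    1/(N - N_h) is undefined."""
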