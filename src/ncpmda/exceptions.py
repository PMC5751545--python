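"""Exception hierarchy.

All domain errors derive from :class:`NcpmdaError` so callers (and the CLI)
can distinguish bad input from programming mistakes, which raise the usual
``ValueError``/``TypeError``.
"""


class NcpmdaError(Exception):
    """Base class for all domain errors raised by this package."""


class EdgeListParseError(NcpmdaError):
    """An association edge list could not be parsed (empty file, short row)."""


class DegenerateNetworkError(NcpmdaError):
    """The adjacency matrix carries no information (all entries zero).

    A fully empty network has undefined Gaussian-kernel bandwidth (the mean
    squared profile norm is zero) and nothing to project, so every pipeline
    entry point rejects it up front. Individual all-zero rows or columns are
    fine -- they are exactly the cold-start entities the method is designed
    to still score from the opposite space.
    """
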