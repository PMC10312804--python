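"""Typed exceptions used across the package.

Validation problems (bad input files, library/count mismatches) raise
:class:`ValidationError`; statistically degenerate situations (zero-variance
null, constant vectors) raise :class:`DegenerateStatisticError`.  The CLI maps
these to distinct exit codes.
"""


class SortscreenError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SortscreenError):
    """An input violated a contract (bad file, duplicate id, negative count)."""


class DegenerateStatisticError(SortscreenError):
    """A statistic cannot be computed (zero variance, empty null, ...)."""
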