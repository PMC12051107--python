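"""Exception hierarchy.

Input-shaped problems (missing columns, too few points, bad parameters)
raise subclasses of :class:`DensigradError` that the CLI maps to exit
code 2; computation failures (packing, quantification) map to exit 3.
"""


class DensigradError(Exception):
    """Base class for all densigrad errors."""


class DegenerateInputError(DensigradError, ValueError):
    """Too few (or collinear/identical) data points for a fit."""


class InsufficientBaselineError(DensigradError, ValueError):
    """Fewer than two baseline fractions remain after excluding signal windows."""


class ParameterError(DensigradError, ValueError):
    """An argument is outside its documented domain."""


class PackingError(DensigradError, RuntimeError):
    """Non-overlapping interval placement failed after the retry budget."""

    def __init__(self, chrom: str, message: str | None = None):
        self.chrom = chrom
        super().__init__(message or f"cannot place intervals without overlap on chromosome {chrom!r}")


class QuantificationError(DensigradError, RuntimeError):
    """A ratio is undefined (e.g. non-positive total DNA integral)."""
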