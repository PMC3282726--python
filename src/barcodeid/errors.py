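"""Exception hierarchy for barcodeid.

Every error raised deliberately by the package derives from
:class:`BarcodeIdError`, so callers (and the CLI) can distinguish contract
violations from genuine bugs.
"""


class BarcodeIdError(Exception):
    """Base class for all barcodeid errors."""


class FastaParseError(BarcodeIdError):
    """Malformed FASTA input; message names the offending line."""


class HeaderError(BarcodeIdError):
    """FASTA header does not carry an 'ACCESSION-Genus species' label."""


class EncodingError(BarcodeIdError):
    """Sequence contains a symbol outside the A/C/G/T alphabet."""


class MalformedCurveError(BarcodeIdError):
    """A curve violates its structural invariants (step sizes, parity)."""


class DegenerateDescriptorError(BarcodeIdError):
    """A descriptor is undefined for the given input (e.g. empty curve)."""


class DegenerateVarianceError(BarcodeIdError):
    """PCA requested on an all-constant feature matrix."""


class InterpolationError(BarcodeIdError):
    """Exact interpolation impossible: identical feature vectors carry
    conflicting species labels."""


class UndefinedRateError(BarcodeIdError):
    """Success rate requested with a zero denominator."""
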