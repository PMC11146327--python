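"""Exception hierarchy shared across the package."""


class UnbendfishError(Exception):
    """Base class for all package errors."""


class ParseError(UnbendfishError):
    """A landmark file could not be parsed; message names record/line."""


class StructuralError(UnbendfishError):
    """Datasets/configurations with inconsistent structure (mismatched p, ids)."""


class DegenerateConfigurationError(UnbendfishError):
    """All landmarks coincide, or a design matrix is rank-deficient."""


class UnfittableAxisError(UnbendfishError):
    """The body-axis chain cannot support a polynomial fit (folding, too few points)."""


class FoldError(UnbendfishError):
    """A requested bend would make the body self-intersect."""
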