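"""Exception hierarchy shared across the pipeline stages."""


class TriadscreenError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TriadscreenError, ValueError):
    """A configuration or input value violates a stated invariant."""


class DegenerateInputError(TriadscreenError, ValueError):
    """An input is structurally valid but statistically unusable
    (e.g. an all-zero count matrix, a zero library size)."""


class SampleMismatchError(TriadscreenError, ValueError):
    """Two matrices that must share sample columns do not."""
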