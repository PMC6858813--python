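"""Exception hierarchy shared across the package."""


class MirclusterError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MirclusterError, ValueError):
    """A file or table row does not conform to the expected dialect."""


class ValidationError(MirclusterError, ValueError):
    """A sequence, annotation or configuration value violates an invariant."""


class BoundsError(MirclusterError, ValueError):
    """A coordinate falls outside the transcript or alignment window."""
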