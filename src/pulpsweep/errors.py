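"""Exception hierarchy.

Validation errors (bad files, bad labels, bad specs) are distinguished from
geometric failures (degenerate fits, mis-placed anchors) so the CLI can map
them to distinct exit codes.
"""


class PulpSweepError(Exception):
    """Base class for all package errors."""


class ValidationError(PulpSweepError):
    """Input does not satisfy a documented precondition (exit code 2)."""


class GeometryError(PulpSweepError):
    """A geometric operation failed on otherwise valid input (exit code 3)."""


class PhantomSpecError(ValidationError):
    """A phantom specification is internally inconsistent."""
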