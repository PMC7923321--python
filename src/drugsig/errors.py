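"""Exception hierarchy for the signature pipeline."""


class DrugsigError(Exception):
    """Base class for all package errors."""


class FormatError(DrugsigError):
    """A file did not conform to the expected text dialect."""


class ValidationError(DrugsigError):
    """Data violated an invariant (non-positive IC50, duplicate ids, ...)."""


class PipelineError(DrugsigError):
    """A pipeline stage could not run on the supplied inputs."""
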