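"""Exception hierarchy.

``InputError`` covers everything a user can fix by correcting their inputs
(files, annotations, configs); ``PipelineError`` covers internal failures.
The CLI maps InputError to exit code 1 and anything else to 2.
"""


class SkipfinderError(Exception):
    """Base class for all package errors."""


class InputError(SkipfinderError):
    """Malformed or missing user input (file, table, sequence)."""


class AnnotationError(InputError):
    """Exon annotation violates an invariant (overlap, ordering, bounds)."""


class BoundsError(InputError):
    """A coordinate falls outside the transcript."""


class SpecError(InputError):
    """An isoform specification is inconsistent with the transcript model."""


class ConfigError(InputError):
    """A simulation or pipeline configuration violates its invariants."""


class FormatError(InputError):
    """A structured input file does not match its expected format."""


class MotifError(InputError):
    """A motif string contains characters outside the IUPAC alphabet."""


class PipelineError(SkipfinderError):
    """Unexpected failure inside a pipeline stage."""
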