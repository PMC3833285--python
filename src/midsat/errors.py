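"""Exception hierarchy for midsat."""


class MidsatError(Exception):
    """Base class for all midsat errors."""


class FormatError(MidsatError):
    """Malformed input file (FASTA, BED, enzyme table)."""


class ValidationError(MidsatError):
    """Input violates a documented precondition or invariant."""


class PlacementError(MidsatError):
    """Synthetic features cannot be placed without overlap."""


class PipelineError(MidsatError):
    """A pipeline stage failed; message names the stage."""
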