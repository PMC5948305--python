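"""Exception hierarchy for quant16s."""


class Quant16sError(Exception):
    """Base class for all package-specific errors."""


class FormatError(Quant16sError):
    """Raised when an input file violates its format contract."""


class IcDropoutError(Quant16sError):
    """Raised when the internal-calibrator taxon yields zero reads.

    Without calibrator reads the read-to-copy conversion is undefined and
    the replicate cannot be quantified.
    """


class PipelineError(Quant16sError):
    """Raised when a pipeline stage receives inputs violating its contract."""
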