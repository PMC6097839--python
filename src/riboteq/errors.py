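"""Exception types shared across the pipeline."""


class RiboteqError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RiboteqError, ValueError):
    """Invalid scenario / run configuration; message names the offending field."""


class DataFormatError(RiboteqError, ValueError):
    """Malformed input file or inconsistent table."""


class AnalysisError(RiboteqError, ValueError):
    """A statistical operation received input it cannot process."""


class PipelineError(RiboteqError, RuntimeError):
    """A pipeline stage failed; message is tagged with the stage name."""
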