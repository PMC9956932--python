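"""Exception hierarchy shared across the package."""


class DeclustError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DeclustError, ValueError):
    """A file violates the expected tabular layout (e.g. duplicate gene ids)."""


class DesignError(DeclustError, ValueError):
    """The sample-to-strain design is invalid (wrong label count, tiny strain)."""


class PipelineError(DeclustError, RuntimeError):
    """A pipeline stage cannot proceed (e.g. no genes survive the zero filter)."""
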