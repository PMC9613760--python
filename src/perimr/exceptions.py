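"""Exception hierarchy for the perimr pipeline."""


class PerimrError(Exception):
    """Base class for all perimr errors."""


class ConfigurationError(PerimrError):
    """The run configuration or a column mapping is invalid."""


class InputError(PerimrError):
    """An input file is unreadable, malformed, or empty after validation."""


class AnalysisError(PerimrError):
    """An analysis stage cannot produce a result from its inputs."""
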