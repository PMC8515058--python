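"""Exception hierarchy: InputError (bad user input, exit code 1) vs internal errors."""


class PipelineError(Exception):
    """Base class for all package errors."""


class InputError(PipelineError):
    """Invalid user-supplied input (file, manifest row, configuration)."""


class FormatError(InputError):
    """A file could not be parsed in the expected format."""


class ConfigError(InputError):
    """Invalid threshold, window or simulation configuration."""


class UnsupportedAlleleError(InputError):
    """Symbolic or breakend alleles cannot be normalized to a key."""
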