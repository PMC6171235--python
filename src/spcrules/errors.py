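"""Exception hierarchy shared across the package.

Error categories map one-to-one onto CLI exit codes so that callers of the
command-line tool can distinguish bad input data from bad configuration.
"""


class SPCRulesError(Exception):
    """Base class for all package errors."""

    category = "error"
    exit_code = 1


class InvalidSeriesError(SPCRulesError, ValueError):
    """The observation sequence violates an engine precondition
    (empty, non-finite, or non-numeric)."""

    category = "input-error"
    exit_code = 2


class ConfigurationError(SPCRulesError, ValueError):
    """A chart specification, rule set, or study configuration is invalid."""

    category = "config-error"
    exit_code = 3


class InputFileError(SPCRulesError, ValueError):
    """A data or configuration file cannot be read or parsed."""

    category = "file-error"
    exit_code = 4
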