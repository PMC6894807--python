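"""Package-wide exception types (CLI maps these onto exit codes)."""


class ConfigurationError(Exception):
    """A channel mapping, config file or parameter set is unusable (exit 2)."""


class DataQualityError(Exception):
    """A signal segment cannot be analyzed (exit 3)."""
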