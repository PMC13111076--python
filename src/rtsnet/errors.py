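"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration field is missing, malformed or out of range."""


class ShapeError(ValueError):
    """An array has the wrong shape for the requested operation."""


class DatasetError(ValueError):
    """A dataset directory is missing, empty when it must not be, or
    inconsistent (e.g. image stems without matching masks)."""


class UndefinedMetricError(ValueError):
    """A metric is requested on inputs for which it has no value
    (e.g. AUC on a single-class pixel pool)."""
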