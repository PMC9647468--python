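"""Exception hierarchy shared by all modules."""


class NutriscreenError(Exception):
    """Base class for package errors."""


class ValidationError(NutriscreenError, ValueError):
    """Invalid clinical input: out-of-range value, bad token, broken invariant."""


class ConfigurationError(NutriscreenError):
    """Malformed or incomplete scoring / food-composition configuration."""
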